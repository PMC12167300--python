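"""View scoring: analytic vs rendered vs voxel-raytraced metrics."""

import numpy as np
import pytest

from pmaa import (CArmGeometry, Ellipsoid, EllipsoidSet, ValidationError,
                  fit_ellipsoid, generate_scene, make_pose, metric_map,
                  q_atten_analytic, q_atten_rendered, q_atten_summed,
                  q_atten_voxel, read_metric_map, scene_to_ellipsoids, voxelize,
                  write_metric_map)
from pmaa.errors import EmptySceneError
from pmaa.scoring import VoxelMask, counters


def sphere(r, mu=(0.0, 0.0, 0.0)):
    return Ellipsoid(mu=np.array(mu, float), sigma=r * r * np.eye(3))


class TestAnalytic:
    def test_sphere_scores_its_diameter_everywhere(self, geom):
        ell = EllipsoidSet(members=(sphere(9.0, (10, -5, 20)),))
        for theta, delta in [(0, 0), (90, 0), (-100, -30), (45, 17)]:
            pose = make_pose(geom, theta, delta)
            assert q_atten_analytic(ell, pose) == pytest.approx(18.0, rel=1e-12)

    def test_max_over_objects(self, geom):
        ell = EllipsoidSet(members=(sphere(3.0, (-30, 0, 0)), sphere(7.0, (30, 0, 0))))
        pose = make_pose(geom, 25.0, -5.0)
        assert q_atten_analytic(ell, pose) == pytest.approx(14.0)

    def test_screw_viewed_along_axis_scores_full_length(self, geom):
        # screw along y; the theta'=0 central ray is parallel to it
        e = fit_ellipsoid([0.0, -25.0, 0.0], [0.0, 25.0, 0.0])
        pose = make_pose(geom, 0.0, 0.0)
        assert q_atten_analytic(EllipsoidSet(members=(e,)), pose) == pytest.approx(50.0)

    def test_empty_scene_is_an_error(self, geom):
        with pytest.raises(EmptySceneError):
            q_atten_analytic(EllipsoidSet(), make_pose(geom, 0, 0))

    def test_parallel_beam_limit(self, geom):
        """Scaling the geometry 100x leaves sphere scores untouched, and
        for screws the scaled score converges to the closed-form
        parallel-beam chord while matching the rendered oracle."""
        from pmaa import chord_length, q_atten_rendered
        far = CArmGeometry(source_isocenter_distance=62200.0,
                           source_detector_distance=116400.0)
        spheres = EllipsoidSet(members=(sphere(7.0, (40, -20, 10)),
                                        sphere(4.0, (-30, 15, -25))))
        for theta, delta in [(0, 0), (60, 20), (-100, -30)]:
            q_near = q_atten_analytic(spheres, make_pose(geom, theta, delta))
            q_far = q_atten_analytic(spheres, make_pose(far, theta, delta))
            assert abs(q_near - q_far) / q_far < 1e-12
        screws = scene_to_ellipsoids(generate_scene(5, seed=17))
        for theta, delta in [(0, 0), (60, 20), (-100, -30)]:
            pose = make_pose(far, theta, delta)
            n = -pose.source / np.linalg.norm(pose.source)
            q_par = max(chord_length(e, n) for e in screws)
            q_far = q_atten_analytic(screws, pose)
            # convergence is first order in scene radius / SID (~1.6e-3)
            assert abs(q_far - q_par) / q_par < 5e-3
            q_rend = q_atten_rendered(screws, pose, sampling=0.5)
            assert abs(q_far - q_rend) / q_rend < 0.01

    def test_scale_equivariance(self, geom):
        k = 2.5
        scaled_geom = CArmGeometry(
            source_isocenter_distance=geom.source_isocenter_distance * k,
            source_detector_distance=geom.source_detector_distance * k,
            pixel_pitch=geom.pixel_pitch * k)
        ell = scene_to_ellipsoids(generate_scene(4, seed=23))
        scaled = EllipsoidSet(members=tuple(
            Ellipsoid(mu=k * e.mu, sigma=k * k * e.sigma) for e in ell))
        for theta, delta in [(10, 5), (-70, -22)]:
            q1 = q_atten_analytic(ell, make_pose(geom, theta, delta))
            q2 = q_atten_analytic(scaled, make_pose(scaled_geom, theta, delta))
            assert q2 == pytest.approx(k * q1, rel=1e-9)


class TestRendered:
    def test_agrees_with_analytic_on_single_objects(self, geom, rng):
        for seed in range(10):
            scene = generate_scene(1, seed=200 + seed)
            ell = scene_to_ellipsoids(scene)
            pose = make_pose(geom, float(rng.uniform(-100, 100)),
                             float(rng.uniform(-30, 30)))
            qa = q_atten_analytic(ell, pose)
            qr = q_atten_rendered(ell, pose, sampling=0.5)
            assert abs(qa - qr) / qr < 0.02

    def test_sphere_converges_to_diameter(self, geom):
        ell = EllipsoidSet(members=(sphere(10.0),))
        pose = make_pose(geom, 30.0, 10.0)
        coarse = q_atten_rendered(ell, pose, sampling=2.0)
        fine = q_atten_rendered(ell, pose, sampling=0.25)
        assert coarse <= 20.0 + 1e-9
        assert fine <= 20.0 + 1e-9
        assert abs(fine - 20.0) < abs(coarse - 20.0) + 1e-12
        assert fine == pytest.approx(20.0, rel=5e-3)

    def test_out_of_field_object_scores_zero_but_analytic_does_not(self, geom):
        """Documents the field-of-view semantic difference between scorers."""
        e = fit_ellipsoid([250.0, 0.0, -20.0], [250.0, 0.0, 30.0])
        ell = EllipsoidSet(members=(e,))
        pose = make_pose(geom, 0.0, 0.0)
        assert q_atten_rendered(ell, pose, sampling=1.0) == 0.0
        assert q_atten_analytic(ell, pose) > 0.0


class TestSummed:
    def test_equals_rendered_for_disjoint_projections(self, geom):
        ell = EllipsoidSet(members=(sphere(5.0, (-40, 0, 0)), sphere(5.0, (40, 0, 0))))
        pose = make_pose(geom, 0.0, 0.0)
        qs = q_atten_summed(ell, pose, sampling=0.5)
        qr = q_atten_rendered(ell, pose, sampling=0.5)
        assert qs == pytest.approx(qr, rel=1e-12)

    def test_coincident_spheres_double(self, geom):
        ell = EllipsoidSet(members=(sphere(6.0), sphere(6.0)))
        pose = make_pose(geom, 10.0, 0.0)
        assert q_atten_summed(ell, pose, sampling=0.5) == pytest.approx(
            2.0 * q_atten_rendered(ell, pose, sampling=0.5), rel=1e-9)

    def test_dominates_rendered_for_crossing_screws(self, geom):
        a = fit_ellipsoid([-25.0, 0.0, -25.0], [25.0, 0.0, 25.0])
        b = fit_ellipsoid([-25.0, 0.0, 25.0], [25.0, 0.0, -25.0])
        ell = EllipsoidSet(members=(a, b))
        pose = make_pose(geom, 0.0, 0.0)
        assert q_atten_summed(ell, pose, sampling=0.5) >= \
            q_atten_rendered(ell, pose, sampling=0.5) - 1e-12


class TestVoxel:
    def test_sphere_voxel_volume(self):
        mask = voxelize(EllipsoidSet(members=(sphere(10.0),)), voxel_size=1.0)
        vol = mask.occupied_voxel_count() * 1.0
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 1000.0, rel=0.05)

    def test_voxelize_empty_set_is_an_error(self):
        with pytest.raises(EmptySceneError):
            voxelize(EllipsoidSet())

    def test_refinement_improves_volume_estimate(self):
        ell = EllipsoidSet(members=(sphere(10.0),))
        target = ell[0].volume
        coarse = voxelize(ell, 2.0).occupied_voxel_count() * 8.0
        fine = voxelize(ell, 1.0).occupied_voxel_count() * 1.0
        assert abs(fine - target) <= abs(coarse - target)

    def test_cube_path_length(self, geom):
        """20 mm cube, central ray perpendicular to a face -> 20 mm."""
        occ = np.ones((20, 20, 20), bool)
        mask = VoxelMask(origin=np.array([-10.0, -10.0, -10.0]), voxel_size=1.0,
                         occupancy=occ)
        q = q_atten_voxel(mask, make_pose(geom, 0.0, 0.0), sampling=1.0)
        assert abs(q - 20.0) <= 1.0

    def test_all_false_mask_scores_zero(self, geom):
        mask = VoxelMask(origin=np.zeros(3), voxel_size=1.0,
                         occupancy=np.zeros((5, 5, 5), bool))
        assert q_atten_voxel(mask, make_pose(geom, 0.0, 0.0), sampling=1.0) == 0.0

    def test_single_screw_agrees_with_analytic_at_long_paths(self, geom):
        """The raytraced mask and the parametric score agree in the long-
        path regime that drives tilt selection (voxelization error is a
        fixed ~voxel-size offset, so its relative share shrinks as the
        path grows)."""
        # a screw seen end-on (50 mm path) and obliquely (~26 mm path)
        for head, tip, theta in [((0.0, -25.0, 0.0), (0.0, 25.0, 0.0), 0.0),
                                 ((-18.0, -18.0, -10.0), (18.0, 18.0, 10.0), -45.0)]:
            ell = EllipsoidSet(members=(fit_ellipsoid(head, tip),))
            pose = make_pose(geom, theta, 0.0)
            qa = q_atten_analytic(ell, pose)
            qv = q_atten_voxel(voxelize(ell, 1.0), pose, sampling=1.0)
            assert abs(qv - qa) / qa < 0.05


class TestMetricMap:
    def test_sphere_map_is_constant(self, coarse_geom):
        ell = EllipsoidSet(members=(sphere(8.0, (5, 5, -10)),))
        mm = metric_map(ell, coarse_geom, method="analytic")
        assert (mm.values.max() - mm.values.min()) / mm.values.max() < 1e-9

    def test_axial_screw_favors_large_tilt(self, coarse_geom):
        """A screw along the orbit axis is foreshortened only by tilting."""
        ell = EllipsoidSet(members=(fit_ellipsoid([0, 0, -25], [0, 0, 25]),))
        mm = metric_map(ell, coarse_geom, method="analytic")
        deltas = mm.delta_values
        row0 = mm.values[np.argmin(np.abs(deltas))]
        edge = mm.values[np.argmax(np.abs(deltas))]
        # tilting never hurts, and strictly helps except at theta' = +/-90
        # where the tilted view of an axial screw stays equatorial
        assert np.all(row0 <= edge + 1e-12)
        strict = np.abs(np.abs(mm.theta_values) - 90.0) > 1e-9
        assert np.all(row0[strict] < edge[strict])
        # direction confirmed by the rendered oracle at two poses
        for theta in (0.0, 50.0):
            q0 = q_atten_rendered(ell, make_pose(coarse_geom, theta, 0.0), 0.5)
            q30 = q_atten_rendered(ell, make_pose(coarse_geom, theta, 30.0), 0.5)
            assert q30 > q0

    def test_analytic_vs_rendered_map_on_random_scene(self, coarse_geom):
        ell = scene_to_ellipsoids(generate_scene(6, seed=41))
        ma = metric_map(ell, coarse_geom, method="analytic")
        mr = metric_map(ell, coarse_geom, method="rendered", sampling=0.5)
        rel = np.abs(ma.values - mr.values) / np.maximum(mr.values, 1e-12)
        assert rel.max() <= 0.02

    def test_map_file_round_trip_is_byte_identical(self, tmp_path, coarse_geom):
        ell = scene_to_ellipsoids(generate_scene(3, seed=43))
        mm = metric_map(ell, coarse_geom, method="analytic")
        path = tmp_path / "map.txt"
        write_metric_map(mm, path)
        first = path.read_bytes()
        side = (tmp_path / "map.txt.json").read_bytes()
        back = read_metric_map(path)
        assert np.array_equal(back.values, mm.values)
        assert back.method == "analytic"
        write_metric_map(
            type(mm)(back.theta_values, back.delta_values, back.values,
                     back.method, geometry=coarse_geom), path)
        assert path.read_bytes() == first
        assert (tmp_path / "map.txt.json").read_bytes() == side


class TestCostCounters:
    def test_analytic_chord_count_is_objects_times_grid(self, coarse_geom):
        ell = scene_to_ellipsoids(generate_scene(4, seed=47))
        counters.reset()
        metric_map(ell, coarse_geom, method="analytic")
        expected = 4 * len(coarse_geom.theta_values()) * len(coarse_geom.delta_values())
        assert counters.chord_evaluations == expected

    def test_analytic_count_invariant_to_detector_resolution(self):
        ell = scene_to_ellipsoids(generate_scene(3, seed=53))
        counts = []
        for n in (100, 400):
            g = CArmGeometry(detector_rows=n, detector_cols=n,
                             theta_step=20.0, delta_step=15.0)
            counters.reset()
            metric_map(ell, g, method="analytic")
            counts.append(counters.chord_evaluations)
        assert counts[0] == counts[1]

    def test_rendered_ray_count_scales_with_pixel_count(self, geom):
        from pmaa import render_path_length_image
        e = sphere(10.0)
        pose = make_pose(geom, 0.0, 0.0)
        img1 = render_path_length_image(e, pose, row_stride=1, col_stride=1)
        img2 = render_path_length_image(e, pose, row_stride=2, col_stride=2)
        assert img1.size == 4 * img2.size
        # and the scorer's cast-ray counter grows as sampling refines
        ell = EllipsoidSet(members=(e,))
        counters.reset()
        q_atten_rendered(ell, pose, sampling=1.0)
        coarse_rays = counters.rays_cast
        counters.reset()
        q_atten_rendered(ell, pose, sampling=0.5)
        assert counters.rays_cast == pytest.approx(4 * coarse_rays, rel=0.1)


def test_unknown_method_rejected(coarse_geom):
    ell = EllipsoidSet(members=(sphere(5.0),))
    with pytest.raises(ValidationError):
        metric_map(ell, coarse_geom, method="spectral")
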