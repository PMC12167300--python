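"""End-to-end parametric metal artifact avoidance pipeline.

Composes the stages: (optional) two-view triangulation of keypoint
proposals -> ellipsoid fitting -> metric map over candidate tilted
orbits -> trajectory objective -> optimal-tilt selection, producing a
JSON-serializable report.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from pathlib import Path
from typing import Iterator, Sequence

from .config import RunConfig
from .ellipsoids import EllipsoidSet, fit_ellipsoid, write_ellipsoids
from .errors import PmaaError, PmaaIOError, ValidationError
from .geometry import Pose
from .optimization import ObjectiveCurve, TiltSelection, objective_curve, select_tilt
from .scoring import MetricMap, metric_map, per_object_metric_maps, write_metric_map
from .synthetic import ObservationSet, Scene, scene_to_ellipsoids
from .triangulation import KeypointProposal, ScrewEndpoints, match_and_triangulate

__all__ = ["PmaaResult", "run_pmaa"]

logger = logging.getLogger(__name__)


@contextmanager
def _stage(name: str) -> Iterator[None]:
    logger.info("stage %s: start", name)
    try:
        yield
    except PmaaError as exc:
        raise type(exc)(f"[{name}] {exc}") from exc
    logger.info("stage %s: done", name)


class PmaaResult:
    """Pipeline output: ellipsoids, metric map, objective, selection."""

    def __init__(self, ellipsoids: EllipsoidSet, mmap: MetricMap,
                 curve: ObjectiveCurve, selection: TiltSelection,
                 endpoints: list[ScrewEndpoints] | None = None) -> None:
        self.ellipsoids = ellipsoids
        self.metric_map = mmap
        self.objective = curve
        self.selection = selection
        self.endpoints = endpoints

    @property
    def delta_star(self) -> float:
        return self.selection.delta_star

    def report(self) -> dict:
        sel = self.selection
        return {
            "delta_star_deg": sel.delta_star,
            "fraction": sel.fraction,
            "q_min_mm": sel.q_min,
            "q_max_mm": sel.q_max,
            "q_at_star_mm": sel.q_at_star,
            "threshold_mm": sel.threshold,
            "method": self.metric_map.method,
            "n_objects": len(self.ellipsoids),
            "ellipsoids": [{"mu": [float(x) for x in e.mu],
                            "sigma": [[float(x) for x in row] for row in e.sigma]}
                           for e in self.ellipsoids],
            "objective": {"delta": [float(d) for d in self.objective.delta_values],
                          "Q": [float(q) for q in self.objective.q_values]},
        }

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write report.json, metric_map.txt (+sidecar), ellipsoids.json."""
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise PmaaIOError(f"cannot create output directory {out}: {exc}") from exc
        paths = {"report": out / "report.json",
                 "metric_map": out / "metric_map.txt",
                 "ellipsoids": out / "ellipsoids.json"}
        report = self.report()
        report["metric_map_file"] = paths["metric_map"].name
        try:
            paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        except OSError as exc:
            raise PmaaIOError(f"cannot write report: {exc}") from exc
        write_metric_map(self.metric_map, paths["metric_map"])
        write_ellipsoids(self.ellipsoids, paths["ellipsoids"])
        return paths


def _resolve_ellipsoids(config: RunConfig,
                        ellipsoids: EllipsoidSet | None,
                        endpoints: Sequence[ScrewEndpoints | tuple] | None,
                        scene: Scene | None,
                        observations: ObservationSet | None,
                        proposals: tuple[Sequence[KeypointProposal],
                                         Sequence[KeypointProposal]] | None,
                        poses: tuple[Pose, Pose] | None,
                        ) -> tuple[EllipsoidSet, list[ScrewEndpoints] | None]:
    given = [x is not None for x in (ellipsoids, endpoints, scene, observations, proposals)]
    if sum(given) != 1:
        raise ValidationError(
            "provide exactly one of: ellipsoids, endpoints, scene, observations, proposals")
    if ellipsoids is not None:
        return ellipsoids, None
    if scene is not None:
        with _stage("fit"):
            return scene_to_ellipsoids(
                scene, minor_full_axis=config.minor_full_axis_mm), None
    if endpoints is not None:
        with _stage("fit"):
            members = []
            for ep in endpoints:
                head, tip = (ep.head, ep.tip) if isinstance(ep, ScrewEndpoints) else ep
                members.append(fit_ellipsoid(head, tip,
                                             minor_full_axis=config.minor_full_axis_mm))
            return EllipsoidSet(members=tuple(members)), None
    if observations is not None:
        (va, vb), (pa, pb) = zip(*((observations.views[k], observations.poses[k])
                                   for k in sorted(observations.views)))
        proposals, poses = (va, vb), (pa, pb)
    if poses is None:
        raise ValidationError("keypoint proposals require the two scout poses")
    with _stage("triangulate"):
        eps = match_and_triangulate(proposals[0], proposals[1], poses[0], poses[1],
                                    tolerance=config.match_tolerance_mm)
    with _stage("fit"):
        members = tuple(fit_ellipsoid(ep.head, ep.tip,
                                      minor_full_axis=config.minor_full_axis_mm)
                        for ep in eps)
    return EllipsoidSet(members=members), eps


def run_pmaa(config: RunConfig | None = None, *,
             ellipsoids: EllipsoidSet | None = None,
             endpoints: Sequence[ScrewEndpoints | tuple] | None = None,
             scene: Scene | None = None,
             observations: ObservationSet | None = None,
             proposals: tuple[Sequence[KeypointProposal],
                              Sequence[KeypointProposal]] | None = None,
             poses: tuple[Pose, Pose] | None = None,
             per_object: bool = False,
             out_dir: str | Path | None = None) -> PmaaResult:
    """Run the full pipeline from any single input modality.

    Exactly one of ``ellipsoids`` / ``endpoints`` / ``scene`` /
    ``observations`` / ``proposals`` (with ``poses``) must be given.
    Returns a :class:`PmaaResult`; with ``out_dir`` the report, metric
    map and ellipsoid files are also written.
    """
    config = config or RunConfig()
    if per_object and config.scoring_method == "voxel":
        # a union mask sums overlapping paths, breaking the exact
        # collective-equals-max-of-singletons decomposition
        raise ValidationError("per-object curves require the analytic or rendered scorer")
    ell, eps = _resolve_ellipsoids(config, ellipsoids, endpoints, scene,
                                   observations, proposals, poses)
    with _stage("score"):
        mmap = metric_map(ell, config.geometry, method=config.scoring_method,
                          sampling=config.sampling_mm, voxel_size=config.voxel_size_mm)
        per_maps = (per_object_metric_maps(ell, config.geometry,
                                           method=config.scoring_method,
                                           sampling=config.sampling_mm,
                                           voxel_size=config.voxel_size_mm)
                    if per_object else None)
    with _stage("objective"):
        curve = objective_curve(mmap, per_object_maps=per_maps)
    with _stage("select"):
        selection = select_tilt(curve, fraction=config.fraction)
    logger.info("selected tilt %g deg (Q %g -> %g mm, threshold %g mm)",
                selection.delta_star, selection.q_max, selection.q_at_star,
                selection.threshold)
    result = PmaaResult(ell, mmap, curve, selection, endpoints=eps)
    if out_dir is not None:
        with _stage("write"):
            result.write(out_dir)
    return result
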