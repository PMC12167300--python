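"""View-quality scoring: maximum metal path length per C-arm pose.

The per-view metric ``q_atten`` is the maximum X-ray path length (mm)
through any modelled metal object for a given pose — a proxy for
photon starvation, the dominant driver of streak/blooming artifacts.
Three scorers are provided:

``analytic``
    The fast parametric method. For an ellipsoid the maximum projection
    is attained by the ray through its centroid, so the metric reduces
    to one central-chord evaluation per object: cost proportional to
    the number of objects only, no image is rendered. Overlap between
    objects is deliberately ignored (max over objects, not sum).

``rendered``
    Per-pixel oracle: exact ray-ellipsoid path-length images sampled on
    the detector; the metric is the max over pixels and objects.
    Detector-limited (an object outside the field contributes nothing),
    whereas the analytic scorer evaluates the centroid chord regardless
    of the field of view.

``voxel``
    Segmentation-style baseline: the ellipsoids are voxelized into a
    binary mask and each detector ray accumulates its exact radiological
    path (Siddon-style traversal) through occupied voxels.

Scorers increment the module-level :data:`counters` so the cost
mechanism (chords vs. rays) can be asserted rather than timed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .ellipsoids import Ellipsoid, EllipsoidSet, pixel_ray_directions, silhouette_bounds
from .errors import EmptySceneError, PmaaIOError, ValidationError
from .geometry import CArmGeometry, Pose, make_pose

__all__ = [
    "MetricMap",
    "VoxelMask",
    "ScoringCounters",
    "counters",
    "q_atten_analytic",
    "q_atten_rendered",
    "q_atten_summed",
    "q_atten_voxel",
    "voxelize",
    "metric_map",
    "per_object_metric_maps",
    "read_metric_map",
    "write_metric_map",
]

logger = logging.getLogger(__name__)

Method = Literal["analytic", "rendered", "voxel"]


@dataclass
class ScoringCounters:
    """Instrumentation: chord evaluations (analytic) and rays cast."""

    chord_evaluations: int = 0
    rays_cast: int = 0

    def reset(self) -> None:
        self.chord_evaluations = 0
        self.rays_cast = 0


counters = ScoringCounters()


@dataclass(frozen=True, eq=False)
class MetricMap:
    """q_atten values over the (delta x theta') grid, in mm."""

    theta_values: np.ndarray
    delta_values: np.ndarray
    values: np.ndarray  # shape (len(delta_values), len(theta_values))
    method: str
    geometry: CArmGeometry | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        tv = np.asarray(self.theta_values, float)
        dv = np.asarray(self.delta_values, float)
        vals = np.asarray(self.values, float)
        if vals.shape != (len(dv), len(tv)):
            raise ValidationError("metric map values must have shape (n_delta, n_theta)")
        if np.any(np.diff(tv) <= 0) or np.any(np.diff(dv) <= 0):
            raise ValidationError("metric map grids must be strictly increasing")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValidationError("metric map values must be finite and >= 0")
        object.__setattr__(self, "theta_values", tv)
        object.__setattr__(self, "delta_values", dv)
        object.__setattr__(self, "values", vals)

    def argmax(self) -> tuple[float, float]:
        """(theta', delta) of the largest entry."""
        j, i = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return float(self.theta_values[i]), float(self.delta_values[j])


@dataclass(frozen=True, eq=False)
class VoxelMask:
    """Axis-aligned binary occupancy grid (corner ``origin``, cubic voxels)."""

    origin: np.ndarray
    voxel_size: float
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, bool)
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be positive")
        if occ.ndim != 3 or occ.size == 0:
            raise ValidationError("occupancy must be a non-empty 3D array")
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "occupancy", occ)

    def occupied_voxel_count(self) -> int:
        return int(self.occupancy.sum())

    def tight(self) -> "VoxelMask":
        """Crop empty margins (the traversal cost scales with grid extent)."""
        idx = np.nonzero(self.occupancy)
        if len(idx[0]) == 0:
            return self
        lo = [int(i.min()) for i in idx]
        hi = [int(i.max()) + 1 for i in idx]
        occ = self.occupancy[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        return VoxelMask(origin=self.origin + np.array(lo) * self.voxel_size,
                         voxel_size=self.voxel_size, occupancy=occ)


def _require_members(ellipsoids: EllipsoidSet | Sequence[Ellipsoid]) -> tuple[Ellipsoid, ...]:
    members = tuple(ellipsoids)
    if not members:
        raise EmptySceneError("the view metric is undefined for an empty scene")
    return members


def q_atten_analytic(ellipsoids: EllipsoidSet, pose: Pose) -> float:
    """Fast parametric metric: max central chord toward the source.

    For each object the ray through the centroid carries the maximum
    path length of its direction class, so the metric is
    ``max_m chord(E_m, unit(mu_m - source))`` — no rendering.
    """
    members = _require_members(ellipsoids)
    best = 0.0
    for e in members:
        d = e.mu - pose.source
        d = d / np.linalg.norm(d)
        counters.chord_evaluations += 1
        best = max(best, 2.0 / float(np.sqrt(d @ e.sigma_inv @ d)))
    return best


def _sample_pixels(pose: Pose, bounds: tuple[float, float, float, float],
                   sampling: float, pad_px: float = 1.0) -> np.ndarray:
    """Detector sample positions (pixel units) on a lattice of pitch
    ``sampling`` mm covering ``bounds``, clipped to the physical detector."""
    geom = pose.geometry
    step = sampling / geom.pixel_pitch
    umin = max(bounds[0] - pad_px, 0.0)
    umax = min(bounds[1] + pad_px, geom.detector_cols)
    vmin = max(bounds[2] - pad_px, 0.0)
    vmax = min(bounds[3] + pad_px, geom.detector_rows)
    if umin >= umax or vmin >= vmax:
        return np.empty((0, 2))
    # global lattice (k + 1/2) * step so different objects sample consistently
    u = (np.arange(np.floor(umin / step), np.ceil(umax / step)) + 0.5) * step
    v = (np.arange(np.floor(vmin / step), np.ceil(vmax / step)) + 0.5) * step
    u = u[(u >= umin) & (u <= umax)]
    v = v[(v >= vmin) & (v <= vmax)]
    if len(u) == 0 or len(v) == 0:
        return np.empty((0, 2))
    uu, vv = np.meshgrid(u, v)
    return np.column_stack([uu.ravel(), vv.ravel()])


def _rendered_object_max(e: Ellipsoid, pose: Pose, sampling: float) -> float:
    from .ellipsoids import _quadratic_path_lengths

    try:
        bounds = silhouette_bounds(e, pose)
    except Exception:
        return 0.0
    pixels = _sample_pixels(pose, bounds, sampling)
    if len(pixels) == 0:
        return 0.0
    dirs = pixel_ray_directions(pose, pixels)
    counters.rays_cast += len(pixels)
    return float(_quadratic_path_lengths(e, pose.source, dirs).max(initial=0.0))


def q_atten_rendered(ellipsoids: EllipsoidSet, pose: Pose, sampling: float = 1.0) -> float:
    """Per-pixel oracle: max over sampled detector rays and objects.

    Each object is sampled only inside its exact silhouette bounding box
    (intersected with the detector), which preserves the maximum while
    keeping the ray count proportional to the silhouette area.
    """
    members = _require_members(ellipsoids)
    if sampling <= 0:
        raise ValidationError("sampling must be positive (mm)")
    if pose.geometry is None:
        raise ValidationError("rendered scoring needs a pose with attached geometry")
    return max(_rendered_object_max(e, pose, sampling) for e in members)


def q_atten_summed(ellipsoids: EllipsoidSet, pose: Pose, sampling: float = 1.0) -> float:
    """Diagnostic variant: pixel values are summed over objects before
    the max, quantifying the overlap the analytic method disregards."""
    from .ellipsoids import _quadratic_path_lengths

    members = _require_members(ellipsoids)
    if sampling <= 0:
        raise ValidationError("sampling must be positive (mm)")
    if pose.geometry is None:
        raise ValidationError("rendered scoring needs a pose with attached geometry")
    bounds_list = []
    for e in members:
        try:
            bounds_list.append(silhouette_bounds(e, pose))
        except Exception:
            continue
    if not bounds_list:
        return 0.0
    union = (min(b[0] for b in bounds_list), max(b[1] for b in bounds_list),
             min(b[2] for b in bounds_list), max(b[3] for b in bounds_list))
    pixels = _sample_pixels(pose, union, sampling)
    if len(pixels) == 0:
        return 0.0
    dirs = pixel_ray_directions(pose, pixels)
    total = np.zeros(len(pixels))
    for e in members:
        counters.rays_cast += len(pixels)
        total += _quadratic_path_lengths(e, pose.source, dirs)
    return float(total.max(initial=0.0))


# -- voxel baseline --------------------------------------------------------

def voxelize(ellipsoids: EllipsoidSet, voxel_size: float = 1.0,
             padding: float = 2.0) -> VoxelMask:
    """Binary occupancy of the union of ellipsoids on a cubic grid.

    A voxel is occupied when its center lies inside any ellipsoid; the
    grid covers all ellipsoid bounding boxes plus ``padding`` mm.
    """
    members = _require_members(ellipsoids)
    if voxel_size <= 0:
        raise ValidationError("voxel_size must be positive")
    los, his = zip(*(e.bounding_box() for e in members))
    lo = np.min(los, axis=0) - padding
    hi = np.max(his, axis=0) + padding
    dims = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int), 1)
    centers = [lo[k] + (np.arange(dims[k]) + 0.5) * voxel_size for k in range(3)]
    occ = np.zeros(tuple(dims), bool)
    for e in members:
        # evaluate the quadratic form separably to avoid a full point list
        elo, ehi = e.bounding_box()
        sl = [slice(int(np.clip(np.floor((elo[k] - lo[k]) / voxel_size), 0, dims[k])),
                    int(np.clip(np.ceil((ehi[k] - lo[k]) / voxel_size), 0, dims[k])))
              for k in range(3)]
        xs, ys, zs = (centers[k][sl[k]] for k in range(3))
        if any(len(c) == 0 for c in (xs, ys, zs)):
            continue
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        inside = e.contains(pts).reshape(X.shape)
        occ[sl[0], sl[1], sl[2]] |= inside
    return VoxelMask(origin=lo, voxel_size=voxel_size, occupancy=occ)


def _ray_bbox_interval(dirs: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                       origin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slab-test entry/exit parameters of rays against an AABB."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo - origin) / dirs
        t_hi = (hi - origin) / dirs
    t1 = np.minimum(t_lo, t_hi)
    t2 = np.maximum(t_lo, t_hi)
    # axes with zero direction: ray parallel to slab; inside iff origin within
    parallel = np.abs(dirs) < 1e-300
    inside = (origin >= lo) & (origin <= hi)
    t1 = np.where(parallel, np.where(inside, -np.inf, np.inf), t1)
    t2 = np.where(parallel, np.where(inside, np.inf, -np.inf), t2)
    entry = np.maximum(t1.max(axis=1), 0.0)
    exit_ = t2.min(axis=1)
    return entry, exit_


try:  # grid traversal is the hot loop; JIT it when numba is present
    import numba

    @numba.njit(fastmath=False)
    def _traverse_nb(occ, lo0, lo1, lo2, h, s0, s1, s2, dirs, entry, exit_, out):
        n0, n1, n2 = occ.shape
        inf = np.inf
        for r in range(dirs.shape[0]):
            t0 = entry[r]
            t1 = exit_[r]
            if t1 <= t0:
                continue
            d0, d1, d2 = dirs[r, 0], dirs[r, 1], dirs[r, 2]
            eps = 1e-9 * (t1 - t0) + 1e-12
            p0 = s0 + (t0 + eps) * d0
            p1 = s1 + (t0 + eps) * d1
            p2 = s2 + (t0 + eps) * d2
            i0 = min(max(int(np.floor((p0 - lo0) / h)), 0), n0 - 1)
            i1 = min(max(int(np.floor((p1 - lo1) / h)), 0), n1 - 1)
            i2 = min(max(int(np.floor((p2 - lo2) / h)), 0), n2 - 1)
            if d0 > 0:
                tm0 = t0 + (lo0 + (i0 + 1) * h - (s0 + t0 * d0)) / d0
                td0, st0 = h / d0, 1
            elif d0 < 0:
                tm0 = t0 + (lo0 + i0 * h - (s0 + t0 * d0)) / d0
                td0, st0 = -h / d0, -1
            else:
                tm0, td0, st0 = inf, inf, 0
            if d1 > 0:
                tm1 = t0 + (lo1 + (i1 + 1) * h - (s1 + t0 * d1)) / d1
                td1, st1 = h / d1, 1
            elif d1 < 0:
                tm1 = t0 + (lo1 + i1 * h - (s1 + t0 * d1)) / d1
                td1, st1 = -h / d1, -1
            else:
                tm1, td1, st1 = inf, inf, 0
            if d2 > 0:
                tm2 = t0 + (lo2 + (i2 + 1) * h - (s2 + t0 * d2)) / d2
                td2, st2 = h / d2, 1
            elif d2 < 0:
                tm2 = t0 + (lo2 + i2 * h - (s2 + t0 * d2)) / d2
                td2, st2 = -h / d2, -1
            else:
                tm2, td2, st2 = inf, inf, 0
            t = t0
            total = 0.0
            while t < t1 - 1e-12:
                tn = tm0
                axis = 0
                if tm1 < tn:
                    tn, axis = tm1, 1
                if tm2 < tn:
                    tn, axis = tm2, 2
                if tn > t1:
                    tn = t1
                if occ[i0, i1, i2]:
                    total += tn - t
                t = tn
                if t >= t1 - 1e-12:
                    break
                if axis == 0:
                    i0 += st0
                    tm0 += td0
                    if i0 < 0 or i0 >= n0:
                        break
                elif axis == 1:
                    i1 += st1
                    tm1 += td1
                    if i1 < 0 or i1 >= n1:
                        break
                else:
                    i2 += st2
                    tm2 += td2
                    if i2 < 0 or i2 >= n2:
                        break
            out[r] = total

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _radiological_paths(mask: VoxelMask, source: np.ndarray,
                        dirs: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Exact per-ray radiological path lengths through occupied voxels."""
    if _HAVE_NUMBA:
        lo = mask.origin
        hi = lo + np.array(mask.occupancy.shape) * mask.voxel_size
        entry, exit_ = _ray_bbox_interval(dirs, lo, hi, source)
        out = np.zeros(len(dirs))
        _traverse_nb(mask.occupancy, lo[0], lo[1], lo[2], mask.voxel_size,
                     source[0], source[1], source[2],
                     np.ascontiguousarray(dirs), entry, exit_, out)
        return out
    return _radiological_paths_numpy(mask, source, dirs, chunk)


def _radiological_paths_numpy(mask: VoxelMask, source: np.ndarray,
                              dirs: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Vectorized fallback: sorted grid-plane crossings, midpoint lookup."""
    occ = mask.occupancy
    h = mask.voxel_size
    dims = np.array(occ.shape)
    lo = mask.origin
    hi = lo + dims * h
    planes = [lo[k] + h * np.arange(dims[k] + 1) for k in range(3)]
    out = np.zeros(len(dirs))
    for s in range(0, len(dirs), chunk):
        d = dirs[s:s + chunk]
        entry, exit_ = _ray_bbox_interval(d, lo, hi, source)
        hit = exit_ > entry
        if not np.any(hit):
            continue
        dh = d[hit]
        a0 = entry[hit][:, None]
        a1 = exit_[hit][:, None]
        cols = []
        for k in range(3):
            with np.errstate(divide="ignore", invalid="ignore"):
                ak = (planes[k][None, :] - source[k]) / dh[:, k:k + 1]
            ak = np.where(np.isfinite(ak), ak, a0)
            cols.append(np.clip(ak, a0, a1))
        A = np.concatenate(cols + [a0, a1], axis=1)
        A.sort(axis=1)
        seg = np.diff(A, axis=1)
        amid = A[:, :-1] + 0.5 * seg
        vals = np.zeros(seg.shape)
        ok = seg > 1e-12
        idx = []
        for k in range(3):
            ik = np.floor((source[k] + amid * dh[:, k:k + 1] - lo[k]) / h).astype(np.int64)
            np.clip(ik, 0, dims[k] - 1, out=ik)
            idx.append(ik)
        vals[ok] = np.where(occ[idx[0], idx[1], idx[2]], seg, 0.0)[ok]
        out[np.flatnonzero(hit) + s] = vals.sum(axis=1)
    return out


def q_atten_voxel(mask: VoxelMask, pose: Pose, sampling: float = 1.0) -> float:
    """Raytracing baseline: max radiological path through the mask.

    Candidate detector samples are limited to the projections of the
    occupied region (coarse 8x8x8-voxel blocks), which cannot discard
    a ray that intersects metal.
    """
    if sampling <= 0:
        raise ValidationError("sampling must be positive (mm)")
    if pose.geometry is None:
        raise ValidationError("voxel scoring needs a pose with attached geometry")
    tight = mask.tight()
    if tight.occupied_voxel_count() == 0:
        return 0.0
    geom = pose.geometry
    occ = tight.occupancy
    h = tight.voxel_size
    # coarse occupied blocks -> conservative detector-space footprint
    b = 8
    dims = np.array(occ.shape)
    cdims = -(-dims // b)
    coarse = np.zeros(tuple(cdims), bool)
    pad = tuple((0, int(c * b - d)) for c, d in zip(cdims, dims))
    occ_p = np.pad(occ, pad)
    coarse = occ_p.reshape(cdims[0], b, cdims[1], b, cdims[2], b).any(axis=(1, 3, 5))
    step = sampling / geom.pixel_pitch
    nu = int(np.ceil(geom.detector_cols / step))
    nv = int(np.ceil(geom.detector_rows / step))
    selected = np.zeros((nv, nu), bool)
    P = pose.projection_matrix
    blocks = np.column_stack(np.nonzero(coarse)).astype(float)
    offsets = np.array([[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0)
                        for z in (0.0, 1.0)])
    corners = (blocks[:, None, :] + offsets[None, :, :]) * (b * h) + tight.origin
    flat = corners.reshape(-1, 3)
    hcl = P @ np.vstack([flat.T, np.ones(len(flat))])
    w = hcl[2]
    if np.any(w <= 1e-9):  # a block straddles the principal plane
        selected[:, :] = True
    else:
        uv = (hcl[:2] / w).T.reshape(len(blocks), 8, 2)
        u0 = np.clip(np.floor(uv[:, :, 0].min(axis=1) / step) - 1, 0, nu).astype(int)
        u1 = np.clip(np.ceil(uv[:, :, 0].max(axis=1) / step) + 1, 0, nu).astype(int)
        v0 = np.clip(np.floor(uv[:, :, 1].min(axis=1) / step) - 1, 0, nv).astype(int)
        v1 = np.clip(np.ceil(uv[:, :, 1].max(axis=1) / step) + 1, 0, nv).astype(int)
        for a, bb, c, d in zip(v0, v1, u0, u1):
            selected[a:bb, c:d] = True
    vv, uu = np.nonzero(selected)
    if len(uu) == 0:
        return 0.0
    pixels = np.column_stack([(uu + 0.5) * step, (vv + 0.5) * step])
    keep = (pixels[:, 0] <= geom.detector_cols) & (pixels[:, 1] <= geom.detector_rows)
    pixels = pixels[keep]
    if len(pixels) == 0:
        return 0.0
    dirs = pixel_ray_directions(pose, pixels)
    counters.rays_cast += len(pixels)
    return float(_radiological_paths(tight, pose.source, dirs).max(initial=0.0))


# -- metric maps -----------------------------------------------------------

def _analytic_map_values(members: Sequence[Ellipsoid], geom: CArmGeometry,
                         thetas: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    sources = np.array([[make_pose(geom, float(t), float(d)).source for t in thetas]
                        for d in deltas])  # (nd, nt, 3)
    flat = sources.reshape(-1, 3)
    best = np.zeros(len(flat))
    for e in members:
        d = e.mu - flat
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        counters.chord_evaluations += len(flat)
        chords = 2.0 / np.sqrt(np.einsum("ni,ij,nj->n", d, e.sigma_inv, d))
        np.maximum(best, chords, out=best)
    return best.reshape(len(deltas), len(thetas))


def metric_map(objects: EllipsoidSet | VoxelMask, geom: CArmGeometry,
               method: Method = "analytic", sampling: float = 1.0,
               voxel_size: float = 1.0) -> MetricMap:
    """Score every pose of the (theta', delta) grid with one scorer.

    ``objects`` is an :class:`EllipsoidSet` (any method; voxelized on
    the fly for ``method='voxel'``) or a prebuilt :class:`VoxelMask`
    (``method='voxel'`` only).
    """
    thetas = geom.theta_values()
    deltas = geom.delta_values()
    if method == "analytic":
        if not isinstance(objects, EllipsoidSet):
            raise ValidationError("analytic scoring needs an EllipsoidSet")
        values = _analytic_map_values(_require_members(objects), geom, thetas, deltas)
        return MetricMap(thetas, deltas, values, "analytic", geometry=geom)
    if method == "rendered":
        if not isinstance(objects, EllipsoidSet):
            raise ValidationError("rendered scoring needs an EllipsoidSet")
        scorer = lambda pose: q_atten_rendered(objects, pose, sampling)
    elif method == "voxel":
        mask = objects if isinstance(objects, VoxelMask) else \
            voxelize(objects, voxel_size=voxel_size).tight()
        scorer = lambda pose: q_atten_voxel(mask, pose, sampling)
    else:
        raise ValidationError(f"unknown scoring method {method!r}")
    values = np.zeros((len(deltas), len(thetas)))
    for j, dlt in enumerate(deltas):
        for i, th in enumerate(thetas):
            values[j, i] = scorer(make_pose(geom, float(th), float(dlt)))
        logger.info("metric map (%s): tilt %g deg done (%d/%d)",
                    method, dlt, j + 1, len(deltas))
    return MetricMap(thetas, deltas, values, method, geometry=geom)


def per_object_metric_maps(ellipsoids: EllipsoidSet, geom: CArmGeometry,
                           method: Method = "analytic", sampling: float = 1.0,
                           voxel_size: float = 1.0) -> list[MetricMap]:
    """One metric map per object (single-object scenes), same grid."""
    _require_members(ellipsoids)
    return [metric_map(EllipsoidSet(members=(e,)), geom, method=method,
                       sampling=sampling, voxel_size=voxel_size) for e in ellipsoids]


# -- file format -----------------------------------------------------------

def geometry_hash(geom: CArmGeometry) -> str:
    payload = json.dumps(geom.model_dump(), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_metric_map(mmap: MetricMap, path: str | Path) -> None:
    """Delimited text (row 0 = theta grid; rows: delta then values) plus
    a JSON sidecar with the method and geometry hash. Full precision."""
    path = Path(path)
    lines = [" ".join(repr(float(t)) for t in mmap.theta_values)]
    for dlt, row in zip(mmap.delta_values, mmap.values):
        lines.append(" ".join([repr(float(dlt))] + [repr(float(x)) for x in row]))
    meta = {"method": mmap.method,
            "geometry_hash": geometry_hash(mmap.geometry) if mmap.geometry else None}
    try:
        path.write_text("\n".join(lines) + "\n")
        _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise PmaaIOError(f"cannot write metric map: {exc}") from exc


def read_metric_map(path: str | Path) -> MetricMap:
    path = Path(path)
    try:
        rows = [ln.split() for ln in path.read_text().splitlines() if ln.strip()]
    except OSError as exc:
        raise PmaaIOError(f"cannot read metric map: {exc}") from exc
    if len(rows) < 2:
        raise ValidationError(f"metric map {path} needs a theta row and data rows")
    thetas = np.array([float(x) for x in rows[0]])
    deltas = np.array([float(r[0]) for r in rows[1:]])
    values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    method = "analytic"
    sidecar = _sidecar(path)
    if sidecar.exists():
        method = json.loads(sidecar.read_text()).get("method", "analytic")
    return MetricMap(thetas, deltas, values, method)
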