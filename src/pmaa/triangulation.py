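"""Two-view keypoint matching and 3D screw-endpoint triangulation.

Head and tip keypoints detected in two calibrated scout views are
back-projected to rays; a cross-view pair of object proposals is
accepted when the two head rays and the two tip rays each pass within a
tolerance (default 5 mm) of one another, and the closest midpoint of
each ray pair becomes the 3D head or tip coordinate. When several
pairings pass the gate, a minimum-cost one-to-one assignment on the sum
of head and tip gaps resolves the ambiguity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import DegenerateGeometryError, PmaaIOError, ValidationError
from .geometry import Pose, Ray3D, backproject

__all__ = [
    "KeypointProposal",
    "ScrewEndpoints",
    "RayClosestApproach",
    "closest_point_between_rays",
    "match_and_triangulate",
    "read_keypoints",
    "write_keypoints",
]

logger = logging.getLogger(__name__)

KIND_HEAD = "head"
KIND_TIP = "tip"


@dataclass(frozen=True, eq=False)
class KeypointProposal:
    """One detected keypoint in one view (pixel coordinates)."""

    view_id: str
    object_id: str
    kind: str
    pixel: np.ndarray
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in (KIND_HEAD, KIND_TIP):
            raise ValidationError(f"keypoint kind must be head or tip, got {self.kind!r}")
        pix = np.asarray(self.pixel, float)
        if pix.shape != (2,) or not np.all(np.isfinite(pix)):
            raise ValidationError("keypoint pixel must be a finite 2-vector")
        object.__setattr__(self, "pixel", pix)


@dataclass(frozen=True, eq=False)
class ScrewEndpoints:
    """Triangulated 3D head/tip with the ray closest-approach gaps (mm)."""

    head: np.ndarray
    tip: np.ndarray
    head_gap: float
    tip_gap: float

    def __post_init__(self) -> None:
        head = np.asarray(self.head, float)
        tip = np.asarray(self.tip, float)
        if np.linalg.norm(head - tip) <= 0:
            raise ValidationError("screw endpoints must be distinct")
        if self.head_gap < 0 or self.tip_gap < 0:
            raise ValidationError("ray gaps are distances and must be >= 0")
        object.__setattr__(self, "head", head)
        object.__setattr__(self, "tip", tip)

    @property
    def centroid(self) -> np.ndarray:
        return 0.5 * (self.head + self.tip)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.head - self.tip))


class RayClosestApproach(NamedTuple):
    """Unconstrained line-line closest approach with the ray parameters."""

    midpoint: np.ndarray
    gap: float
    t1: float
    t2: float


def closest_point_between_rays(r1: Ray3D, r2: Ray3D) -> RayClosestApproach:
    """Midpoint and length of the shortest segment joining two ray lines.

    Solves the two-parameter least-squares problem on the supporting
    lines; the returned parameters ``t1, t2`` locate the closest points
    (negative values mean the approach happens behind a ray's origin,
    which the matching stage treats as inadmissible). Parallel rays are
    degenerate.
    """
    d1, d2 = r1.direction, r2.direction
    cross = np.cross(d1, d2)
    if np.linalg.norm(cross) < 1e-12:
        raise DegenerateGeometryError("rays are parallel; closest approach is undefined")
    w = r2.origin - r1.origin
    a = float(d1 @ d2)
    # normal equations of min_{t1,t2} ||o1 + t1 d1 - o2 - t2 d2||^2
    denom = 1.0 - a * a
    t1 = float((w @ d1 - a * (w @ d2)) / denom)
    t2 = float((a * (w @ d1) - w @ d2) / denom)
    p1 = r1.point_at(t1)
    p2 = r2.point_at(t2)
    return RayClosestApproach(midpoint=0.5 * (p1 + p2),
                              gap=float(np.linalg.norm(p1 - p2)), t1=t1, t2=t2)


def _objects_by_id(proposals: Sequence[KeypointProposal]) -> dict[str, dict[str, KeypointProposal]]:
    objects: dict[str, dict[str, KeypointProposal]] = {}
    for p in proposals:
        slot = objects.setdefault(p.object_id, {})
        if p.kind in slot:
            raise ValidationError(
                f"object {p.object_id!r} in view {p.view_id!r} has duplicate {p.kind} keypoints")
        slot[p.kind] = p
    for oid, slot in objects.items():
        missing = {KIND_HEAD, KIND_TIP} - set(slot)
        if missing:
            raise ValidationError(
                f"object {oid!r} is missing its {missing.pop()} keypoint")
    return objects


def match_and_triangulate(proposals_a: Sequence[KeypointProposal],
                          proposals_b: Sequence[KeypointProposal],
                          pose_a: Pose, pose_b: Pose,
                          tolerance: float = 5.0) -> list[ScrewEndpoints]:
    """Match proposals across two views and triangulate screw endpoints.

    A cross-view pair is admissible when its head rays and its tip rays
    each approach within ``tolerance`` mm in front of both sources;
    among admissible pairs a one-to-one assignment minimizing the summed
    gaps is returned. Unmatched proposals are dropped (logged).
    """
    objs_a = _objects_by_id(proposals_a)
    objs_b = _objects_by_id(proposals_b)
    ids_a, ids_b = sorted(objs_a), sorted(objs_b)
    if not ids_a or not ids_b:
        logger.info("triangulation: %d + %d proposals, nothing to match",
                    len(ids_a), len(ids_b))
        return []

    rays_a = {oid: {k: backproject(pose_a, objs_a[oid][k].pixel) for k in (KIND_HEAD, KIND_TIP)}
              for oid in ids_a}
    rays_b = {oid: {k: backproject(pose_b, objs_b[oid][k].pixel) for k in (KIND_HEAD, KIND_TIP)}
              for oid in ids_b}

    big = 1e12
    cost = np.full((len(ids_a), len(ids_b)), big)
    approach: dict[tuple[int, int], tuple[RayClosestApproach, RayClosestApproach]] = {}
    for i, oa in enumerate(ids_a):
        for j, ob in enumerate(ids_b):
            try:
                ha = closest_point_between_rays(rays_a[oa][KIND_HEAD], rays_b[ob][KIND_HEAD])
                ta = closest_point_between_rays(rays_a[oa][KIND_TIP], rays_b[ob][KIND_TIP])
            except DegenerateGeometryError:
                continue
            forward = min(ha.t1, ha.t2, ta.t1, ta.t2) >= 0
            if forward and ha.gap <= tolerance and ta.gap <= tolerance:
                cost[i, j] = ha.gap + ta.gap
                approach[i, j] = (ha, ta)

    rows, cols = linear_sum_assignment(cost)
    matches: list[ScrewEndpoints] = []
    for i, j in zip(rows, cols):
        if cost[i, j] >= big:
            continue
        ha, ta = approach[i, j]
        matches.append(ScrewEndpoints(head=ha.midpoint, tip=ta.midpoint,
                                      head_gap=ha.gap, tip_gap=ta.gap))
    dropped = (len(ids_a) - len(matches)) + (len(ids_b) - len(matches))
    logger.info("triangulation: %d/%d + %d/%d proposals matched (%d dropped)",
                len(matches), len(ids_a), len(matches), len(ids_b), dropped)
    return matches


# -- file format -----------------------------------------------------------

_CSV_COLUMNS = ["view_id", "object_id", "kind", "u", "v", "score"]


def write_keypoints(proposals: Sequence[KeypointProposal], path: str | Path) -> None:
    """Write keypoint proposals as CSV (view_id,object_id,kind,u,v,score)."""
    df = pd.DataFrame(
        [{"view_id": p.view_id, "object_id": p.object_id, "kind": p.kind,
          "u": repr(float(p.pixel[0])), "v": repr(float(p.pixel[1])),
          "score": repr(float(p.score))} for p in proposals],
        columns=_CSV_COLUMNS)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise PmaaIOError(f"cannot write keypoints: {exc}") from exc


def read_keypoints(path: str | Path) -> list[KeypointProposal]:
    """Read keypoint proposals from the CSV format."""
    try:
        df = pd.read_csv(path, dtype={"view_id": str, "object_id": str, "kind": str},
                         float_precision="round_trip")
    except OSError as exc:
        raise PmaaIOError(f"cannot read keypoints: {exc}") from exc
    except pd.errors.EmptyDataError:
        return []
    missing = set(_CSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValidationError(f"keypoint CSV {path} is missing columns {sorted(missing)}")
    if "score" not in df.columns:
        df["score"] = 1.0
    return [KeypointProposal(view_id=r.view_id, object_id=r.object_id, kind=r.kind,
                             pixel=np.array([r.u, r.v], float), score=float(r.score))
            for r in df.itertuples()]
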