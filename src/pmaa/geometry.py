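"""C-arm geometry: tilted circular orbits, projection matrices, rays.

Coordinate conventions
----------------------
The world frame is fixed at the isocenter (origin). By default the
untilted orbit revolves about ``orbit_axis = +z`` (patient cranio-caudal)
and the orbit plane is tilted about ``tilt_axis = +x`` (patient
left-right). At ``theta_prime = 0, delta = 0`` the X-ray source sits on
the -y axis (the anterior-posterior reference direction
``-(orbit_axis x tilt_axis)``), and the whole rig (source, detector and
its axes) is rotated rigidly by ``R(tilt_axis, delta) @
R(orbit_axis, theta_prime)``; the orbital angle is therefore measured
within the tilted plane.

Detector pixels use continuous coordinates ``(u, v)`` with ``u`` along
columns and ``v`` along rows; the corner of the detector is ``(0, 0)``,
the center is ``(cols / 2, rows / 2)``, and the center of integer pixel
``(i, j)`` is ``(i + 0.5, j + 0.5)``. All interface angles are degrees,
all lengths millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.linalg import null_space
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, PmaaIOError, ValidationError

__all__ = [
    "CArmGeometry",
    "Pose",
    "Ray3D",
    "make_pose",
    "project",
    "backproject",
    "read_geometry",
    "write_geometry",
    "read_poses",
    "write_poses",
]


class CArmGeometry(BaseModel):
    """Fixed imaging-system parameters and the (theta', delta) grids.

    Defaults mimic a mobile interventional C-arm with a 200-degree
    short-scan arc sampled at 1-degree increments and candidate orbit
    tilts in [-30, 30] degrees.
    """

    model_config = {"frozen": True}

    source_isocenter_distance: float = Field(default=622.0, gt=0)
    source_detector_distance: float = Field(default=1164.0, gt=0)
    detector_rows: int = Field(default=400, ge=1)
    detector_cols: int = Field(default=400, ge=1)
    pixel_pitch: float = Field(default=1.0, gt=0)
    theta_range: tuple[float, float] = (-100.0, 100.0)
    theta_step: float = Field(default=1.0, gt=0)
    delta_range: tuple[float, float] = (-30.0, 30.0)
    delta_step: float = Field(default=1.0, gt=0)
    orbit_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    tilt_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    @model_validator(mode="after")
    def _check(self) -> "CArmGeometry":
        if not self.source_isocenter_distance < self.source_detector_distance:
            raise ValueError("source_isocenter_distance must be < source_detector_distance")
        for name in ("theta_range", "delta_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be non-empty (min <= max)")
        oa = np.asarray(self.orbit_axis, float)
        ta = np.asarray(self.tilt_axis, float)
        for name, ax in (("orbit_axis", oa), ("tilt_axis", ta)):
            if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be unit length")
        if abs(float(oa @ ta)) > 1e-9:
            raise ValueError("orbit_axis and tilt_axis must be perpendicular")
        return self

    # -- derived quantities ------------------------------------------------

    @property
    def magnification(self) -> float:
        """Geometric magnification at the isocenter (SDD / SID)."""
        return self.source_detector_distance / self.source_isocenter_distance

    @property
    def detector_center(self) -> np.ndarray:
        """Continuous pixel coordinates of the detector center."""
        return np.array([self.detector_cols / 2.0, self.detector_rows / 2.0])

    def theta_values(self) -> np.ndarray:
        lo, hi = self.theta_range
        n = int(round((hi - lo) / self.theta_step))
        return lo + self.theta_step * np.arange(n + 1)

    def delta_values(self) -> np.ndarray:
        lo, hi = self.delta_range
        n = int(round((hi - lo) / self.delta_step))
        return lo + self.delta_step * np.arange(n + 1)

    def pose(self, theta_prime: float, delta: float) -> "Pose":
        return make_pose(self, theta_prime, delta)

    def orbit_poses(self, delta: float) -> Iterator["Pose"]:
        """All poses of the orbit at a fixed tilt."""
        for theta in self.theta_values():
            yield make_pose(self, float(theta), delta)


@dataclass(frozen=True, eq=False)
class Ray3D:
    """Half-line from ``origin`` along unit vector ``direction`` (mm)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, float)
        d = np.asarray(self.direction, float)
        n = float(np.linalg.norm(d))
        if not np.isfinite(n) or n < 1e-300:
            raise ValidationError("ray direction must be a nonzero finite vector")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def point_at(self, t: float | np.ndarray) -> np.ndarray:
        return self.origin + np.multiply.outer(t, self.direction)


@dataclass(frozen=True, eq=False)
class Pose:
    """One C-arm position: orbital angle, tilt, source and 3x4 matrix.

    ``projection_matrix`` maps homogeneous world mm to homogeneous
    detector pixels. ``geometry`` is attached when the pose was built
    from a :class:`CArmGeometry` and is required by detector-sampling
    scorers; poses imported from external calibration carry only the
    matrix and the source.
    """

    theta_prime: float
    delta: float
    source: np.ndarray
    projection_matrix: np.ndarray
    geometry: CArmGeometry | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        P = np.asarray(self.projection_matrix, float)
        if P.shape != (3, 4):
            raise ValidationError("projection_matrix must be 3x4")
        if np.linalg.matrix_rank(P) != 3:
            raise ValidationError("projection_matrix must have rank 3")
        object.__setattr__(self, "projection_matrix", P)
        object.__setattr__(self, "source", np.asarray(self.source, float))

    def camera_center(self) -> np.ndarray:
        """Camera center recovered from the projection matrix null space."""
        ns = null_space(self.projection_matrix)
        c = ns[:, 0]
        if abs(c[3]) < 1e-12:
            raise DegenerateGeometryError("projection matrix has camera center at infinity")
        return c[:3] / c[3]


def _rig_rotation(geom: CArmGeometry, theta_prime: float, delta: float) -> Rotation:
    tilt = Rotation.from_rotvec(np.deg2rad(delta) * np.asarray(geom.tilt_axis, float))
    orbit = Rotation.from_rotvec(np.deg2rad(theta_prime) * np.asarray(geom.orbit_axis, float))
    return tilt * orbit


def make_pose(geom: CArmGeometry, theta_prime: float, delta: float) -> Pose:
    """Construct the pose at orbital angle ``theta_prime`` and tilt ``delta``.

    The source lies on the circle of radius ``source_isocenter_distance``
    in the tilted orbit plane; the detector is perpendicular to the
    central (source -> isocenter) ray, beyond the isocenter, and the
    isocenter projects exactly to the detector center.
    """
    if not (np.isfinite(theta_prime) and np.isfinite(delta)):
        raise ValidationError("pose angles must be finite")
    oa = np.asarray(geom.orbit_axis, float)
    ta = np.asarray(geom.tilt_axis, float)
    ap = -np.cross(oa, ta)  # anterior-posterior source reference direction
    R = _rig_rotation(geom, theta_prime, delta)
    source = geom.source_isocenter_distance * R.apply(ap)
    u_axis = R.apply(ta)  # detector column direction
    v_axis = R.apply(oa)  # detector row direction
    n_axis = -R.apply(ap)  # central ray direction (source -> isocenter)
    f_pix = geom.source_detector_distance / geom.pixel_pitch
    cu, cv = geom.detector_center
    K = np.array([[f_pix, 0.0, cu], [0.0, f_pix, cv], [0.0, 0.0, 1.0]])
    Rc = np.vstack([u_axis, v_axis, n_axis])
    P = K @ np.hstack([Rc, -(Rc @ source)[:, None]])
    return Pose(theta_prime=float(theta_prime), delta=float(delta), source=source,
                projection_matrix=P, geometry=geom)


def project(pose: Pose, point: np.ndarray) -> np.ndarray:
    """Pinhole-project world point(s) (mm) to detector pixels (u, v).

    Accepts a single 3-vector or an (N, 3) array. Points on the
    principal plane (zero homogeneous depth) raise
    :class:`DegenerateGeometryError`.
    """
    pts = np.atleast_2d(np.asarray(point, float))
    h = pose.projection_matrix @ np.vstack([pts.T, np.ones(len(pts))])
    w = h[2]
    if np.any(np.abs(w) < 1e-8):
        raise DegenerateGeometryError("point lies on the principal plane of the pose")
    uv = (h[:2] / w).T
    return uv[0] if np.asarray(point).ndim == 1 else uv


def backproject(pose: Pose, pixel: Sequence[float]) -> Ray3D:
    """Back-project a detector pixel into the world-space ray it observes.

    The ray originates at the source and is oriented away from the
    source toward the detector. Works from the projection matrix alone,
    so externally calibrated poses are supported.
    """
    pix = np.asarray(pixel, float)
    if not np.all(np.isfinite(pix)):
        raise ValidationError("pixel coordinates must be finite")
    P = pose.projection_matrix
    X = np.linalg.pinv(P) @ np.array([pix[0], pix[1], 1.0])
    if abs(X[3]) > 1e-12:
        direction = X[:3] / X[3] - pose.source
    else:  # pixel's preimage is at infinity in this particular solution
        direction = X[:3]
    # orient toward positive depth (the detector side)
    w = P[2] @ np.append(pose.source + direction / np.linalg.norm(direction), 1.0)
    if w < 0:
        direction = -direction
    return Ray3D(origin=pose.source, direction=direction)


# -- file formats ----------------------------------------------------------

_GEOM_FIELDS = list(CArmGeometry.model_fields)


def write_geometry(geom: CArmGeometry, path: str | Path) -> None:
    """Write a geometry config as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = {k: getattr(geom, k) for k in _GEOM_FIELDS}
    data = {k: list(v) if isinstance(v, tuple) else v for k, v in data.items()}
    try:
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))
    except OSError as exc:
        raise PmaaIOError(f"cannot write geometry config: {exc}") from exc


def read_geometry(path: str | Path) -> CArmGeometry:
    """Read a geometry config from YAML or JSON (keys = field names)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())  # JSON is a YAML subset
    except OSError as exc:
        raise PmaaIOError(f"cannot read geometry config: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"geometry config {path} must be a mapping")
    unknown = set(raw) - set(_GEOM_FIELDS)
    if unknown:
        raise ValidationError(f"unknown geometry fields: {sorted(unknown)}")
    try:
        return CArmGeometry(**raw)
    except ValueError as exc:
        raise ValidationError(f"invalid geometry config {path}: {exc}") from exc


def write_poses(poses: Sequence[Pose], path: str | Path) -> None:
    """Write poses as text blocks: 'theta_prime delta' then the 3x4 matrix."""
    lines = []
    for p in poses:
        lines.append(f"{p.theta_prime!r} {p.delta!r}")
        for row in p.projection_matrix:
            lines.append(" ".join(repr(float(x)) for x in row))
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise PmaaIOError(f"cannot write poses: {exc}") from exc


def read_poses(path: str | Path, geometry: CArmGeometry | None = None) -> list[Pose]:
    """Read poses from the block text format written by :func:`write_poses`."""
    try:
        tokens = Path(path).read_text().split("\n")
    except OSError as exc:
        raise PmaaIOError(f"cannot read poses: {exc}") from exc
    rows = [ln.split() for ln in tokens if ln.strip()]
    if len(rows) % 4 != 0:
        raise ValidationError(f"pose file {path} is malformed (blocks of 4 lines expected)")
    poses = []
    for i in range(0, len(rows), 4):
        if len(rows[i]) != 2 or any(len(r) != 4 for r in rows[i + 1 : i + 4]):
            raise ValidationError(f"pose file {path}: bad block starting at line {i + 1}")
        theta, delta = (float(x) for x in rows[i])
        P = np.array([[float(x) for x in r] for r in rows[i + 1 : i + 4]])
        ns = null_space(P)
        if ns.shape[1] != 1 or abs(ns[3, 0]) < 1e-12:
            raise ValidationError(f"pose file {path}: matrix in block {i // 4} is degenerate")
        source = ns[:3, 0] / ns[3, 0]
        poses.append(Pose(theta_prime=theta, delta=delta, source=source,
                          projection_matrix=P, geometry=geometry))
    return poses
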