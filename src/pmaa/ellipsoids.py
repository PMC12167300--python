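"""Ellipsoidal implant surrogates and exact ray path-length geometry.

An implant is modelled by its centroid ``mu`` and a symmetric positive
definite shape matrix ``sigma`` whose eigenvalues are squared semi-axis
lengths: the surface is ``{x : (x - mu)^T sigma^-1 (x - mu) = 1}``. For
a pedicle screw the major full axis equals the head-tip distance and
the two minor full axes default to 5 mm, a representative screw
diameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import DegenerateGeometryError, PmaaIOError, ValidationError
from .geometry import Pose, Ray3D

__all__ = [
    "Ellipsoid",
    "EllipsoidSet",
    "fit_ellipsoid",
    "chord_length",
    "ray_path_length",
    "render_path_length_image",
    "read_ellipsoids",
    "write_ellipsoids",
]

_MAX_SEMI_AXIS_MM = 200.0  # sanity bound for surgical scenes


@dataclass(frozen=True, eq=False)
class Ellipsoid:
    """Solid ellipsoid (mu, sigma) in mm / mm^2."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, float)
        sigma = np.asarray(self.sigma, float)
        if mu.shape != (3,) or sigma.shape != (3, 3):
            raise ValidationError("ellipsoid needs a 3-vector mu and 3x3 sigma")
        if np.abs(sigma - sigma.T).max() > 1e-9:
            raise ValidationError("sigma must be symmetric within 1e-9")
        sigma = 0.5 * (sigma + sigma.T)
        evals = np.linalg.eigvalsh(sigma)
        if evals[0] <= 0:
            raise ValidationError("sigma must be positive definite")
        if np.sqrt(evals[-1]) > _MAX_SEMI_AXIS_MM:
            raise ValidationError(
                f"semi-axis {np.sqrt(evals[-1]):.1f} mm exceeds the "
                f"{_MAX_SEMI_AXIS_MM:.0f} mm sanity bound")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "_sigma_inv", np.linalg.inv(sigma))

    @property
    def sigma_inv(self) -> np.ndarray:
        return self._sigma_inv  # type: ignore[attr-defined]

    @property
    def semi_axes(self) -> np.ndarray:
        """Semi-axis lengths, ascending (sqrt of sigma's eigenvalues)."""
        return np.sqrt(np.linalg.eigvalsh(self.sigma))

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semi_axes))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Tight axis-aligned bounds: mu +/- sqrt(diag(sigma))."""
        half = np.sqrt(np.diag(self.sigma))
        return self.mu - half, self.mu + half

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized solid-membership test for (N, 3) points."""
        d = np.atleast_2d(points) - self.mu
        return np.einsum("ni,ij,nj->n", d, self.sigma_inv, d) <= 1.0


@dataclass(frozen=True, eq=False)
class EllipsoidSet:
    """Ordered collection of ellipsoids; the index is the object identity."""

    members: tuple[Ellipsoid, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Ellipsoid]:
        return iter(self.members)

    def __getitem__(self, m: int) -> Ellipsoid:
        return self.members[m]


def fit_ellipsoid(head: Sequence[float], tip: Sequence[float],
                  minor_full_axis: float = 5.0) -> Ellipsoid:
    """Fit a screw surrogate to its 3D head and tip points.

    The principal axis is aligned with head -> tip and its full length
    equals the head-tip distance; both minor full axes equal
    ``minor_full_axis`` (a diameter, default 5 mm).
    """
    head = np.asarray(head, float)
    tip = np.asarray(tip, float)
    axis = tip - head
    length = float(np.linalg.norm(axis))
    if length <= 1.0:
        raise DegenerateGeometryError(
            f"head-tip distance {length:.3f} mm is degenerate (<= 1 mm)")
    if minor_full_axis <= 0:
        raise ValidationError("minor_full_axis must be positive")
    e1 = axis / length
    # any orthonormal completion of e1 (minor directions are arbitrary)
    helper = np.array([1.0, 0.0, 0.0]) if abs(e1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    a = length / 2.0
    b = minor_full_axis / 2.0
    sigma = R @ np.diag([a * a, b * b, b * b]) @ R.T
    sigma = 0.5 * (sigma + sigma.T)
    return Ellipsoid(mu=0.5 * (head + tip), sigma=sigma)


def chord_length(e: Ellipsoid, direction: Sequence[float]) -> float:
    """Length of the chord through the centroid along a unit direction.

    This is ``2 / sqrt(d^T sigma^-1 d)``, the longest path through the
    ellipsoid among all rays of that direction.
    """
    d = np.asarray(direction, float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValidationError("chord direction must be unit length")
    return 2.0 / float(np.sqrt(d @ e.sigma_inv @ d))


def _quadratic_path_lengths(e: Ellipsoid, origin: np.ndarray,
                            directions: np.ndarray) -> np.ndarray:
    """Forward intersection lengths of rays (one origin, (N,3) unit dirs)."""
    Si = e.sigma_inv
    o = origin - e.mu
    a = np.einsum("ni,ij,nj->n", directions, Si, directions)
    b = 2.0 * directions @ (Si @ o)
    c = float(o @ Si @ o) - 1.0
    disc = b * b - 4.0 * a * c
    out = np.zeros(len(directions))
    hit = disc > 0
    if np.any(hit):
        sq = np.sqrt(disc[hit])
        t1 = (-b[hit] - sq) / (2.0 * a[hit])
        t2 = (-b[hit] + sq) / (2.0 * a[hit])
        out[hit] = np.maximum(t2, 0.0) - np.maximum(t1, 0.0)
    return out


def ray_path_length(e: Ellipsoid, ray: Ray3D) -> float:
    """Exact intersection length (mm) of a half-line with the solid.

    Substituting ``x = o + t d`` into the solid's quadratic inequality
    gives a quadratic in ``t``; the roots are clipped to ``t >= 0`` and
    their separation is the traversed length. A miss returns 0.
    """
    return float(_quadratic_path_lengths(e, ray.origin, ray.direction[None, :])[0])


def render_path_length_image(e: Ellipsoid, pose: Pose, row_stride: int = 1,
                             col_stride: int = 1) -> np.ndarray:
    """Per-pixel path-length image (mm) of one ellipsoid in one pose.

    Samples the centers of every ``row_stride``-th row and
    ``col_stride``-th column of the detector and casts the exact
    source -> pixel ray through the ellipsoid.
    """
    if pose.geometry is None:
        raise ValidationError("rendering needs a pose with attached geometry")
    if row_stride < 1 or col_stride < 1:
        raise ValidationError("strides must be >= 1 pixel")
    geom = pose.geometry
    v = np.arange(0, geom.detector_rows, row_stride) + 0.5
    u = np.arange(0, geom.detector_cols, col_stride) + 0.5
    uu, vv = np.meshgrid(u, v)
    dirs = pixel_ray_directions(pose, np.column_stack([uu.ravel(), vv.ravel()]))
    vals = _quadratic_path_lengths(e, pose.source, dirs)
    return vals.reshape(len(v), len(u))


def pixel_ray_directions(pose: Pose, pixels: np.ndarray) -> np.ndarray:
    """Unit world directions of the rays through (N, 2) detector pixels."""
    P = pose.projection_matrix
    Ppinv = np.linalg.pinv(P)
    h = np.column_stack([pixels, np.ones(len(pixels))])
    X = h @ Ppinv.T
    finite = np.abs(X[:, 3]) > 1e-12
    dirs = np.empty((len(pixels), 3))
    dirs[finite] = X[finite, :3] / X[finite, 3, None] - pose.source
    dirs[~finite] = X[~finite, :3]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # orient all rays toward positive depth
    w = (pose.source + dirs) @ P[2, :3] + P[2, 3]
    dirs[w < 0] *= -1.0
    return dirs


# -- silhouette geometry ---------------------------------------------------

def silhouette_bounds(e: Ellipsoid, pose: Pose) -> tuple[float, float, float, float]:
    """Exact pixel bounding box (umin, umax, vmin, vmax) of the silhouette.

    The pinhole image of an ellipsoid outline is a conic; its dual is
    ``C* = P Q* P^T`` where ``Q*`` is the ellipsoid's dual quadric, and
    the axis-aligned tangent lines of ``C*`` give closed-form bounds.
    """
    T = np.eye(4)
    T[:3, 3] = e.mu
    Qd = T @ np.block([[e.sigma, np.zeros((3, 1))], [np.zeros((1, 3)), -np.ones((1, 1))]]) @ T.T
    C = pose.projection_matrix @ Qd @ pose.projection_matrix.T
    C = C / C[2, 2]
    du = C[0, 2] ** 2 - C[0, 0] * C[2, 2]
    dv = C[1, 2] ** 2 - C[1, 1] * C[2, 2]
    if du < 0 or dv < 0:
        raise DegenerateGeometryError("ellipsoid silhouette is not a bounded ellipse")
    su, sv = np.sqrt(du), np.sqrt(dv)
    return (C[0, 2] - su, C[0, 2] + su, C[1, 2] - sv, C[1, 2] + sv)


def silhouette_in_field(e: Ellipsoid, pose: Pose, margin_px: float = 0.0) -> bool:
    """True when the whole silhouette falls on the physical detector."""
    if pose.geometry is None:
        raise ValidationError("field-of-view test needs a pose with geometry")
    umin, umax, vmin, vmax = silhouette_bounds(e, pose)
    return (umin >= margin_px and vmin >= margin_px
            and umax <= pose.geometry.detector_cols - margin_px
            and vmax <= pose.geometry.detector_rows - margin_px)


# -- file format -----------------------------------------------------------

def write_ellipsoids(ellipsoids: EllipsoidSet, path: str | Path) -> None:
    """Write an ellipsoid set as a JSON array of {mu, sigma} records."""
    records = [{"mu": [float(x) for x in e.mu],
                "sigma": [[float(x) for x in row] for row in e.sigma]}
               for e in ellipsoids]
    try:
        Path(path).write_text(json.dumps(records, indent=2) + "\n")
    except OSError as exc:
        raise PmaaIOError(f"cannot write ellipsoids: {exc}") from exc


def read_ellipsoids(path: str | Path, minor_full_axis: float = 5.0) -> EllipsoidSet:
    """Read an ellipsoid set from JSON.

    Records may be {"mu": ..., "sigma": ...} or raw endpoint records
    {"head": ..., "tip": ...}, which are fitted on load.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except OSError as exc:
        raise PmaaIOError(f"cannot read ellipsoids: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ValidationError(f"ellipsoid file {path} is not valid JSON: {exc}") from exc
    members = []
    for i, rec in enumerate(raw):
        if "mu" in rec and "sigma" in rec:
            members.append(Ellipsoid(mu=np.array(rec["mu"]), sigma=np.array(rec["sigma"])))
        elif "head" in rec and "tip" in rec:
            members.append(fit_ellipsoid(rec["head"], rec["tip"],
                                         minor_full_axis=rec.get("minor_full_axis",
                                                                 minor_full_axis)))
        else:
            raise ValidationError(
                f"ellipsoid record {i} needs mu/sigma or head/tip fields")
    return EllipsoidSet(members=tuple(members))
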