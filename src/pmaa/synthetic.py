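"""Seeded synthetic surgical scenes and scout-view observations.

Scenes emulate randomly placed pedicle screws with realistic sizes
(lengths 35-65 mm, diameters 4-7.5 mm) inside a surgical field around
the isocenter, and keypoint observations emulate the output of a
2D screw detector on two scout views: projected head/tip pixels with
Gaussian localization noise, per-view object dropout, spurious
proposals, and shuffled per-view object identities (so cross-view
correspondence is genuinely unknown).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .ellipsoids import EllipsoidSet, fit_ellipsoid
from .errors import InfeasibleSceneError, PmaaIOError, ValidationError
from .geometry import Pose, project
from .triangulation import KIND_HEAD, KIND_TIP, KeypointProposal

__all__ = [
    "Screw",
    "Scene",
    "ObservationSet",
    "generate_scene",
    "generate_paired_scene",
    "observe_scene",
    "scene_to_ellipsoids",
    "read_scene",
    "write_scene",
]

DEFAULT_BOUNDS = ((-70.0, -70.0, -70.0), (70.0, 70.0, 70.0))
DEFAULT_LENGTH_RANGE = (35.0, 65.0)
DEFAULT_DIAMETER_RANGE = (4.0, 7.5)


@dataclass(frozen=True, eq=False)
class Screw:
    """Ground-truth screw: 3D head/tip endpoints (mm) and diameter (mm)."""

    head: np.ndarray
    tip: np.ndarray
    diameter: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "head", np.asarray(self.head, float))
        object.__setattr__(self, "tip", np.asarray(self.tip, float))

    @property
    def centroid(self) -> np.ndarray:
        return 0.5 * (self.head + self.tip)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.head - self.tip))


@dataclass(frozen=True, eq=False)
class Scene:
    """Synthetic ground truth: screws, the bounding volume, the seed."""

    screws: tuple[Screw, ...]
    volume_bounds: tuple[tuple[float, float, float], tuple[float, float, float]]
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "screws", tuple(self.screws))

    def __len__(self) -> int:
        return len(self.screws)


@dataclass(frozen=True, eq=False)
class ObservationSet:
    """Per-view keypoint proposals for the two scout poses."""

    views: dict[str, list[KeypointProposal]]
    poses: dict[str, Pose]
    noise_sigma: float
    dropout_rate: float
    spurious_rate: float


def _uniform_sphere(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def _clinical_direction(rng: np.random.Generator, half_angle_deg: float = 30.0) -> np.ndarray:
    """Axis within a cone about the anterior-posterior (y) direction."""
    cos_max = np.cos(np.deg2rad(half_angle_deg))
    c = rng.uniform(cos_max, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(1.0 - c * c)
    d = np.array([s * np.cos(phi), c, s * np.sin(phi)])
    return d if rng.random() < 0.5 else -d


def generate_scene(n_screws: int,
                   length_range: tuple[float, float] = DEFAULT_LENGTH_RANGE,
                   diameter_range: tuple[float, float] = DEFAULT_DIAMETER_RANGE,
                   bounds: Sequence[Sequence[float]] = DEFAULT_BOUNDS,
                   min_separation: float = 20.0,
                   seed: int = 0,
                   orientation: str = "uniform") -> Scene:
    """Rejection-sample a scene of randomly placed screws.

    Lengths and diameters are uniform in their ranges and axes uniform
    on the sphere (or biased toward the anterior-posterior direction
    with ``orientation='clinical'``); each screw's centroid is then
    uniform over the sub-box where both endpoints stay inside the
    volume, with rejection on the centroid alone enforcing pairwise
    ``min_separation``. Drawing size and orientation before placement
    keeps their marginal distributions exactly uniform (placing whole
    screws by rejection would bias accepted lengths short near the
    volume boundary).
    """
    if n_screws < 0:
        raise ValidationError("n_screws must be >= 0")
    if orientation not in ("uniform", "clinical"):
        raise ValidationError("orientation must be 'uniform' or 'clinical'")
    lo = np.asarray(bounds[0], float)
    hi = np.asarray(bounds[1], float)
    if np.any(hi <= lo):
        raise ValidationError("volume bounds must have positive extent")
    rng = np.random.default_rng(seed)
    screws: list[Screw] = []
    for m in range(n_screws):
        d = _uniform_sphere(rng) if orientation == "uniform" else _clinical_direction(rng)
        length = rng.uniform(*length_range)
        diameter = rng.uniform(*diameter_range)
        half = 0.5 * length * np.abs(d)
        clo, chi = lo + half, hi - half
        if np.any(chi < clo):
            raise InfeasibleSceneError(
                f"screw {m} (length {length:.1f} mm) does not fit in the volume")
        for _ in range(10_000):
            c = rng.uniform(clo, chi)
            if any(np.linalg.norm(c - s.centroid) < min_separation for s in screws):
                continue
            screws.append(Screw(head=c - 0.5 * length * d, tip=c + 0.5 * length * d,
                                diameter=diameter))
            break
        else:
            raise InfeasibleSceneError(
                f"could not place screw {m} after 10000 attempts; "
                "loosen min_separation or enlarge the volume")
    return Scene(screws=tuple(screws), volume_bounds=(tuple(lo), tuple(hi)), seed=seed)


def generate_paired_scene(n_vertebrae: int = 4,
                          level_spacing: float = 35.0,
                          pedicle_offset: float = 12.0,
                          length_range: tuple[float, float] = DEFAULT_LENGTH_RANGE,
                          diameter_range: tuple[float, float] = DEFAULT_DIAMETER_RANGE,
                          seed: int = 0,
                          jitter: float = 2.0) -> Scene:
    """Bilateral screw pairs per vertebral level along the orbit axis.

    Emulates lumbar pedicle instrumentation: per level two screws enter
    left/right of midline, converging anteriorly (toward -y), with
    small positional jitter. Levels are spaced along +z.
    """
    rng = np.random.default_rng(seed)
    screws: list[Screw] = []
    z0 = -0.5 * (n_vertebrae - 1) * level_spacing
    for level in range(n_vertebrae):
        z = z0 + level * level_spacing
        for side in (-1.0, 1.0):
            length = rng.uniform(*length_range)
            diameter = rng.uniform(*diameter_range)
            entry = np.array([side * pedicle_offset, 25.0, z]) + rng.normal(0, jitter, 3)
            # converge ~15 deg toward midline while advancing anteriorly
            d = np.array([-side * np.sin(np.deg2rad(15.0)), -np.cos(np.deg2rad(15.0)), 0.0])
            d += rng.normal(0, 0.03, 3)
            d /= np.linalg.norm(d)
            screws.append(Screw(head=entry, tip=entry + length * d, diameter=diameter))
    all_pts = np.array([p for s in screws for p in (s.head, s.tip)])
    lo = tuple(np.floor(all_pts.min(axis=0) - 5.0))
    hi = tuple(np.ceil(all_pts.max(axis=0) + 5.0))
    return Scene(screws=tuple(screws), volume_bounds=(lo, hi), seed=seed)


def observe_scene(scene: Scene, pose_a: Pose, pose_b: Pose,
                  noise_sigma: float = 0.0, dropout_rate: float = 0.0,
                  spurious_rate: float = 0.0, seed: int = 0) -> ObservationSet:
    """Emulate a keypoint detector on two scout views.

    Projects each screw's endpoints through both poses, adds isotropic
    Gaussian pixel noise, drops whole per-view objects with probability
    ``dropout_rate``, injects spurious head/tip pairs uniformly on the
    detector with expected count ``spurious_rate`` per true object, and
    shuffles per-view object identifiers.
    """
    for name, rate in (("dropout_rate", dropout_rate), ("spurious_rate", spurious_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    views: dict[str, list[KeypointProposal]] = {}
    poses = {"A": pose_a, "B": pose_b}
    for view_id, pose in poses.items():
        pairs: list[tuple[np.ndarray, np.ndarray]] = []
        for s in scene.screws:
            if rng.random() < dropout_rate:
                continue
            head_px = project(pose, s.head) + rng.normal(0.0, noise_sigma, 2)
            tip_px = project(pose, s.tip) + rng.normal(0.0, noise_sigma, 2)
            pairs.append((head_px, tip_px))
        n_spurious = rng.binomial(max(len(scene.screws), 1), spurious_rate)
        geom = pose.geometry
        for _ in range(int(n_spurious)):
            head_px = rng.uniform([0, 0], [geom.detector_cols, geom.detector_rows])
            tip_px = rng.uniform([0, 0], [geom.detector_cols, geom.detector_rows])
            pairs.append((head_px, tip_px))
        order = rng.permutation(len(pairs))
        proposals: list[KeypointProposal] = []
        for new_id, idx in enumerate(order):
            head_px, tip_px = pairs[idx]
            proposals.append(KeypointProposal(view_id=view_id, object_id=str(new_id),
                                              kind=KIND_HEAD, pixel=head_px))
            proposals.append(KeypointProposal(view_id=view_id, object_id=str(new_id),
                                              kind=KIND_TIP, pixel=tip_px))
        views[view_id] = proposals
    return ObservationSet(views=views, poses=poses, noise_sigma=noise_sigma,
                          dropout_rate=dropout_rate, spurious_rate=spurious_rate)


def scene_to_ellipsoids(scene: Scene, minor_from_diameter: bool = False,
                        minor_full_axis: float = 5.0) -> EllipsoidSet:
    """Ground-truth ellipsoids, one per screw, in scene order."""
    members = [fit_ellipsoid(s.head, s.tip,
                             minor_full_axis=s.diameter if minor_from_diameter
                             else minor_full_axis)
               for s in scene.screws]
    return EllipsoidSet(members=tuple(members))


# -- file format -----------------------------------------------------------

def write_scene(scene: Scene, path: str | Path) -> None:
    data = {"seed": scene.seed,
            "volume_bounds": [list(scene.volume_bounds[0]), list(scene.volume_bounds[1])],
            "screws": [{"head": [float(x) for x in s.head],
                        "tip": [float(x) for x in s.tip],
                        "diameter": float(s.diameter)} for s in scene.screws]}
    try:
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise PmaaIOError(f"cannot write scene: {exc}") from exc


def read_scene(path: str | Path) -> Scene:
    try:
        data = json.loads(Path(path).read_text())
    except OSError as exc:
        raise PmaaIOError(f"cannot read scene: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ValidationError(f"scene file {path} is not valid JSON: {exc}") from exc
    screws = tuple(Screw(head=np.array(s["head"]), tip=np.array(s["tip"]),
                         diameter=float(s["diameter"])) for s in data["screws"])
    vb = data["volume_bounds"]
    return Scene(screws=screws, volume_bounds=(tuple(vb[0]), tuple(vb[1])),
                 seed=int(data["seed"]))
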