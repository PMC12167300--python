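"""Trajectory objective and optimal-tilt selection.

The trajectory objective ``Q_atten(delta)`` is the worst view metric
over the orbit at tilt ``delta``. Minimizing it outright can push the
C-arm to large tilts that are clinically awkward (table collisions,
degraded calibration), so the selected tilt ``delta*`` is instead the
smallest-magnitude grid tilt achieving a configurable fraction
(default 95%) of the maximum possible reduction from the worst to the
best trajectory score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .scoring import MetricMap

__all__ = ["ObjectiveCurve", "TiltSelection", "objective_curve", "select_tilt"]


@dataclass(frozen=True, eq=False)
class ObjectiveCurve:
    """Q_atten(delta) over the tilt grid, optionally per object."""

    delta_values: np.ndarray
    q_values: np.ndarray
    per_object_curves: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        dv = np.asarray(self.delta_values, float)
        qv = np.asarray(self.q_values, float)
        if dv.ndim != 1 or qv.shape != dv.shape:
            raise ValidationError("objective curve needs matching delta and Q vectors")
        if np.any(qv < 0):
            raise ValidationError("Q_atten values must be >= 0")
        object.__setattr__(self, "delta_values", dv)
        object.__setattr__(self, "q_values", qv)
        if self.per_object_curves is not None:
            poc = np.atleast_2d(np.asarray(self.per_object_curves, float))
            if poc.shape[1] != len(dv):
                raise ValidationError("per-object curves must share the tilt grid")
            if np.abs(poc.max(axis=0) - qv).max() > 1e-12 * max(1.0, qv.max()):
                raise ValidationError(
                    "collective Q must equal the elementwise max of per-object curves")
            object.__setattr__(self, "per_object_curves", poc)


@dataclass(frozen=True)
class TiltSelection:
    """The selected tilt and the quantities behind the selection rule."""

    delta_star: float
    q_at_star: float
    q_min: float
    q_max: float
    threshold: float
    fraction: float


def objective_curve(mmap: MetricMap,
                    per_object_maps: list[MetricMap] | None = None) -> ObjectiveCurve:
    """Collapse a metric map over the orbital angle: Q(delta) = max_theta q."""
    q = mmap.values.max(axis=1)
    poc = None
    if per_object_maps is not None:
        for pm in per_object_maps:
            if (len(pm.delta_values) != len(mmap.delta_values)
                    or np.abs(pm.delta_values - mmap.delta_values).max() > 1e-9):
                raise ValidationError("per-object maps must share the collective tilt grid")
        poc = np.vstack([pm.values.max(axis=1) for pm in per_object_maps])
    return ObjectiveCurve(delta_values=mmap.delta_values, q_values=q,
                          per_object_curves=poc)


def select_tilt(curve: ObjectiveCurve, fraction: float = 0.95) -> TiltSelection:
    """Pick the smallest-magnitude tilt achieving the target reduction.

    ``threshold = q_max - fraction * (q_max - q_min)``; among grid tilts
    with ``Q(delta) <= threshold`` the one with smallest ``|delta|`` is
    returned (tie -> positive tilt). A flat curve offers no improvement
    and selects the tilt nearest 0 (the standard untilted orbit).
    """
    if len(curve.delta_values) == 0:
        raise ValidationError("cannot select a tilt from an empty curve")
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    deltas = curve.delta_values
    q = curve.q_values
    q_min = float(q.min())
    q_max = float(q.max())
    threshold = q_max - fraction * (q_max - q_min)
    eligible = np.flatnonzero(q <= threshold)
    if eligible.size == 0:  # guard against threshold rounding just below q_min
        eligible = np.flatnonzero(q == q_min)
    if q_max == q_min:
        eligible = np.arange(len(deltas))
    # smallest |delta| first; ties broken toward positive delta
    order = sorted(eligible, key=lambda i: (abs(deltas[i]), -np.sign(deltas[i])))
    pick = order[0]
    return TiltSelection(delta_star=float(deltas[pick]), q_at_star=float(q[pick]),
                         q_min=q_min, q_max=q_max, threshold=float(threshold),
                         fraction=float(fraction))
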