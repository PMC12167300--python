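"""Quick-look figures for metric maps and objective curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .optimization import ObjectiveCurve, TiltSelection
from .scoring import MetricMap

__all__ = ["plot_metric_map", "plot_objective_curve"]


def plot_metric_map(mmap: MetricMap, ax: plt.Axes | None = None) -> plt.Axes:
    """Heatmap of q_atten over (theta', delta)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    tv, dv = mmap.theta_values, mmap.delta_values
    im = ax.imshow(mmap.values, origin="lower", aspect="auto",
                   extent=(tv[0], tv[-1], dv[0], dv[-1]), cmap="viridis")
    ax.set_xlabel("orbital angle theta' (deg)")
    ax.set_ylabel("tilt delta (deg)")
    ax.set_title(f"q_atten ({mmap.method})")
    plt.colorbar(im, ax=ax, label="max metal path length (mm)")
    return ax


def plot_objective_curve(curve: ObjectiveCurve,
                         selection: TiltSelection | None = None,
                         ax: plt.Axes | None = None) -> plt.Axes:
    """Q_atten(delta) with the selected tilt and threshold marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(curve.delta_values, curve.q_values, "k-", lw=1.5, label="collective")
    if curve.per_object_curves is not None:
        for i, row in enumerate(curve.per_object_curves):
            ax.plot(curve.delta_values, row, lw=0.8, alpha=0.6, label=f"screw {i}")
    if selection is not None:
        ax.axhline(selection.threshold, color="tab:orange", ls=":", label="threshold")
        ax.axvline(selection.delta_star, color="tab:red", ls="--",
                   label=f"delta* = {selection.delta_star:g} deg")
    ax.set_xlabel("tilt delta (deg)")
    ax.set_ylabel("Q_atten (mm)")
    ax.legend(fontsize=7)
    return ax
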