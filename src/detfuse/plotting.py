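"""Plotting helpers for evaluation output (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluate import ewma_smooth

__all__ = ["plot_npv_curves", "plot_timepoint_counts"]


def plot_npv_curves(curves: dict, alpha: float = 0.1, ax=None,
                    targets=(0.95, 0.90)):
    """Fraction flagged low-risk vs NPV, one line per model.

    *curves* maps model name → NPV-sweep DataFrame. The displayed NPV is
    exponentially smoothed (``alpha``) for readability; dashed horizontal
    lines mark the target NPVs. Counts are never taken from the smoothed
    curve.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        sm = ewma_smooth(curve, alpha)
        ax.plot(sm["fraction_flagged"], sm["npv"], label=name)
    for t in targets:
        ax.axhline(t, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("fraction of patients flagged low-risk")
    ax.set_ylabel("negative predictive value (smoothed)")
    ax.set_ylim(0.5, 1.02)
    ax.legend(frameon=False)
    return ax


def plot_timepoint_counts(timepoint_counts: dict, target: float, ax=None,
                          label=None):
    """Low-risk patients identified vs evaluation timepoint at one NPV."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    hours = sorted(timepoint_counts)
    counts = [timepoint_counts[h][target] for h in hours]
    ax.plot(hours, counts, marker="o", label=label)
    ax.set_xlabel("hours of observation")
    ax.set_ylabel(f"patients identified low-risk at NPV {target}")
    if label:
        ax.legend(frameon=False)
    return ax
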