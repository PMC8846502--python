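"""Temporal alignment of irregular score streams onto the 4-hour prediction grid.

Deterioration indices emit scores every 15 minutes (or 4 hours); image-model
scores exist only at radiograph times. Fused predictions are made on a fixed
grid of 4-hour windows anchored at admission. Windows are half-open
``[start, start + 4)``; the prediction "at" a window is made at the window's
end, so the two features available to it are

* the reduced index score of the last *completed* window ``[start-4, start)``
  (the maximum of the raw scores in that window, carried forward through
  windows with no observation), and
* the most recent image score with radiograph time ≤ ``start``, together with
  the elapsed time since that radiograph.

This makes every feature a pure function of data observed at or before the
window start — nothing downstream of the prediction point can leak in.

Two task-specific instance sets are built per hospitalization:

* ``low_risk`` — windows from the first radiograph through 48 h; the label is
  whether the patient ever deteriorates.
* ``high_risk`` — windows from the first radiograph through the 5-day
  horizon; the window containing the event and the window immediately before
  it are dropped (censoring against label leakage); the label is
  deterioration within 120 h.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import Hospitalization, ScoreStream

__all__ = [
    "GridSpec",
    "PredictionInstance",
    "INSTANCE_COLUMNS",
    "reduce_index_to_windows",
    "carry_forward_image",
    "make_instances",
    "make_horizon_labels",
    "instances_frame",
    "build_instances",
    "HORIZONS",
]

HORIZONS = (12, 24, 48, 72, 96, 120)

INSTANCE_COLUMNS = [
    "hosp_id", "window_start", "image_score", "index_score",
    "hours_since_xray", "hours_since_admit", "label",
]


@dataclass(frozen=True)
class GridSpec:
    """Prediction-grid geometry for one task.

    ``window_hours`` must divide ``horizon_hours``; the defaults are the
    48-hour low-risk instance window and the 120-hour (5-day) high-risk one.
    """

    window_hours: float = 4.0
    task: str = "low_risk"
    horizon_hours: float = 48.0

    def __post_init__(self):
        if self.task not in ("low_risk", "high_risk"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.window_hours <= 0:
            raise ValueError("window_hours must be positive")
        if self.horizon_hours % self.window_hours != 0:
            raise ValueError("window_hours must divide horizon_hours")

    @classmethod
    def for_task(cls, task: str) -> "GridSpec":
        return cls(4.0, task, 48.0 if task == "low_risk" else 120.0)


@dataclass(frozen=True)
class PredictionInstance:
    hosp_id: str
    window_start: float
    image_score: float
    index_score: float
    hours_since_xray: float
    hours_since_admit: float
    label: int | None = None


def reduce_index_to_windows(stream: ScoreStream, grid: GridSpec) -> ScoreStream:
    """Reduce a raw index stream to one value per grid window.

    Each window ``[start, start + w)`` takes the maximum raw score observed in
    it; windows with no observation inherit the most recent reduced value
    (last observation carried forward). A stream already at window cadence
    passes through unchanged. Output times are window starts; leading windows
    before the first observation are dropped.
    """
    if stream.source != "index":
        raise ValueError("reduce_index_to_windows expects an index stream")
    if len(stream.times) == 0:
        raise ValueError("cannot reduce an empty index stream")
    w = grid.window_hours
    starts = np.arange(0.0, grid.horizon_hours, w)
    out_t, out_s = [], []
    last = None
    for s0 in starts:
        in_win = (stream.times >= s0) & (stream.times < s0 + w)
        if np.any(in_win):
            last = float(stream.scores[in_win].max())
        if last is not None:
            out_t.append(s0)
            out_s.append(last)
    return ScoreStream(stream.hosp_id, "index", np.array(out_t), np.array(out_s))


def carry_forward_image(
    xray_times: Sequence[float],
    xray_scores: Sequence[float],
    window_starts: Sequence[float],
):
    """Carry the most recent image score forward to each prediction window.

    For each window start ``t`` the latest radiograph with time ≤ ``t`` is
    used; ``hours_since_xray = t - xray_time`` (0 when the radiograph falls
    exactly on the window start). Windows before the first radiograph are
    omitted from the output rather than raising.

    Returns a list of ``(window_start, image_score, hours_since_xray)``.
    """
    xt = np.asarray(xray_times, dtype=float)
    xs = np.asarray(xray_scores, dtype=float)
    if len(xt) == 0:
        raise ValueError("at least one radiograph is required")
    order = np.argsort(xt, kind="stable")
    xt, xs = xt[order], xs[order]
    out = []
    for t in window_starts:
        k = np.searchsorted(xt, t, side="right") - 1
        if k < 0:
            continue  # window precedes the first radiograph
        out.append((float(t), float(xs[k]), float(t - xt[k])))
    return out


def _grid_starts(first_xray: float, last_start: float, w: float) -> np.ndarray:
    """Grid starts from the smallest grid point ≥ first x-ray (floored at w)."""
    start0 = max(w, w * math.ceil(first_xray / w))
    if start0 > last_start:
        return np.array([])
    n = int(round((last_start - start0) / w)) + 1
    return start0 + w * np.arange(n)


def make_instances(
    hosp: Hospitalization,
    index_stream: ScoreStream,
    image_stream: ScoreStream,
    grid: GridSpec,
) -> list[PredictionInstance]:
    """Build the fused feature vectors for one hospitalization.

    Assumes *hosp* passed the inclusion filters (in particular, it has a
    radiograph). Returns an empty list, with a warning, when no valid window
    exists (e.g. discharge immediately after the first radiograph).
    """
    w = grid.window_hours
    first_xray = hosp.first_xray
    if first_xray is None:
        raise ValueError(f"{hosp.hosp_id}: no radiograph; run inclusion filters first")

    if grid.task == "low_risk":
        last_start = grid.horizon_hours
        label = int(hosp.deteriorated)
    else:
        last_start = grid.horizon_hours
        label = int(hosp.deteriorated and hosp.deterioration_time <= grid.horizon_hours)
        if hosp.deteriorated and hosp.deterioration_time <= grid.horizon_hours:
            # censor: drop the event-containing window and the one before it
            event_win = w * math.floor(hosp.deterioration_time / w)
            last_start = min(last_start, event_win - 2 * w)

    starts = _grid_starts(first_xray, last_start, w)
    starts = starts[starts < hosp.exit_time]  # no predictions after exit
    if len(starts) == 0:
        warnings.warn(f"{hosp.hosp_id}: no valid prediction windows", stacklevel=2)
        return []

    reduced = reduce_index_to_windows(index_stream, grid)
    img = dict()
    for t, sc, dt in carry_forward_image(image_stream.times, image_stream.scores, starts):
        img[t] = (sc, dt)

    instances = []
    for s0 in starts:
        if s0 not in img:
            continue
        # index feature: reduced value of the last completed window [s0-w, s0)
        k = np.searchsorted(reduced.times, s0 - w, side="right") - 1
        if k < 0:
            continue  # no index observation before the window
        sc, dt = img[s0]
        instances.append(PredictionInstance(
            hosp_id=hosp.hosp_id,
            window_start=float(s0),
            image_score=sc,
            index_score=float(reduced.scores[k]),
            hours_since_xray=dt,
            hours_since_admit=float(s0 + w),
            label=label,
        ))
    if not instances:
        warnings.warn(f"{hosp.hosp_id}: no valid prediction windows", stacklevel=2)
    return instances


def index_baseline_predictions(
    hosp: Hospitalization,
    index_stream: ScoreStream,
    grid: GridSpec,
    anchor: str = "admission",
) -> pd.DataFrame:
    """Per-window DI-only risk scores for a like-for-like baseline.

    The raw index stream is reduced to the same 4-hour windows and each
    window's prediction is the reduced value of the last completed window —
    exactly the index feature the fused model sees — so baseline and
    augmented model differ only in what they do with the information. With
    ``anchor="admission"`` the baseline predicts from the first grid point
    (the index needs no radiograph); ``anchor="first_xray"`` restricts it to
    the augmented model's windows. High-risk censoring matches
    :func:`make_instances`.

    Returns a DataFrame with columns (hosp_id, window_start, pred).
    """
    w = grid.window_hours
    last_start = grid.horizon_hours
    if (grid.task == "high_risk" and hosp.deteriorated
            and hosp.deterioration_time <= grid.horizon_hours):
        event_win = w * math.floor(hosp.deterioration_time / w)
        last_start = min(last_start, event_win - 2 * w)
    if anchor == "admission":
        first = 0.0
    elif anchor == "first_xray":
        if hosp.first_xray is None:
            raise ValueError(f"{hosp.hosp_id}: no radiograph")
        first = hosp.first_xray
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    starts = _grid_starts(first, last_start, w)
    starts = starts[starts < hosp.exit_time]
    reduced = reduce_index_to_windows(index_stream, grid)
    rows = []
    for s0 in starts:
        k = np.searchsorted(reduced.times, s0 - w, side="right") - 1
        if k < 0:
            continue
        rows.append((hosp.hosp_id, float(s0), float(reduced.scores[k])))
    return pd.DataFrame(rows, columns=["hosp_id", "window_start", "pred"])


def make_horizon_labels(hosp: Hospitalization, reference_time: float) -> dict:
    """Multi-horizon outcome labels relative to *reference_time*.

    ``label_h = 1`` iff the deterioration falls in ``(reference, reference+h]``
    for h in 12/24/48/72/96/120 hours; ``label["any"] = 1`` iff the patient
    ever deteriorates.
    """
    if reference_time < 0:
        raise ValueError("reference_time must be >= 0")
    t = hosp.deterioration_time
    labels = {}
    for h in HORIZONS:
        labels[h] = int(t is not None and reference_time < t <= reference_time + h)
    labels["any"] = int(t is not None)
    return labels


def instances_frame(instances: Sequence[PredictionInstance]) -> pd.DataFrame:
    """Instances as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [(i.hosp_id, i.window_start, i.image_score, i.index_score,
          i.hours_since_xray, i.hours_since_admit, i.label) for i in instances],
        columns=INSTANCE_COLUMNS,
    )


def build_instances(hosps, streams, task: str) -> pd.DataFrame:
    """Vector of all prediction instances for a filtered cohort and task."""
    grid = GridSpec.for_task(task)
    idx = {s.hosp_id: s for s in streams if s.source == "index"}
    img = {s.hosp_id: s for s in streams if s.source == "image"}
    rows: list[PredictionInstance] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for h in hosps:
            rows.extend(make_instances(h, idx[h.hosp_id], img[h.hosp_id], grid))
    return instances_frame(rows)
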