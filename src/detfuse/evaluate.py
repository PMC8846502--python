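"""Evaluation protocol: low-risk identification by NPV sweep, high-risk
discrimination by AUROC, with patient-level bootstrap confidence intervals.

Low-risk task
    Window predictions are aggregated to one risk score per hospitalization
    (the mean over the first ``upto`` hours, ``upto`` in {24, 32, 40, 48});
    patients who deteriorate before ``upto`` are excluded. Patients are
    sorted by ascending aggregated risk and the flagging threshold is swept:
    flagging the k lowest-risk patients as "low risk", NPV(k) is the fraction
    of the flagged who never deteriorate. The headline count is the largest k
    that maintains a target NPV (0.95 or 0.90).

High-risk task
    One score per hospitalization — the maximum window prediction before the
    event or within the first five days — compared against the 120-hour
    deterioration label by AUROC (Mann–Whitney form, ties ½), plus the
    specificity at the operating point where sensitivity first reaches 0.8.

Confidence intervals are empirical 2.5/97.5 percentiles over resamples of
hospitalizations (not windows) with replacement, 1000 by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "patient_risks", "aggregate_low_risk", "aggregate_high_risk",
    "npv_sweep", "count_low_risk_at_npv", "auroc",
    "specificity_at_sensitivity", "bootstrap_ci", "ewma_smooth",
    "EvaluationReport",
]

log = logging.getLogger("detfuse")

RISK_COLUMNS = ["hosp_id", "aggregated_score", "label"]


def patient_risks(hosp_ids, scores, labels) -> pd.DataFrame:
    """Assemble a per-hospitalization risk table (one row per admission)."""
    df = pd.DataFrame({"hosp_id": hosp_ids,
                       "aggregated_score": np.asarray(scores, dtype=float),
                       "label": np.asarray(labels, dtype=int)})
    if df["hosp_id"].duplicated().any():
        raise ValueError("one row per hospitalization required")
    if ((df.aggregated_score < 0) | (df.aggregated_score > 1)).any():
        raise ValueError("aggregated scores must lie in [0, 1]")
    return df


def _event_times(hospitalizations) -> dict:
    out = {}
    for h in hospitalizations:
        out[h.hosp_id] = h.deterioration_time
    return out


def aggregate_low_risk(predictions: pd.DataFrame, hospitalizations,
                       upto: float = 48.0) -> pd.DataFrame:
    """Per-patient mean risk over the first *upto* hours.

    *predictions* has columns (hosp_id, window_start, pred). Window
    predictions with ``window_start < upto`` enter the mean. Hospitalizations
    that deteriorate before *upto* are excluded (the low-risk question is
    moot for them); ones with no window before *upto* are dropped with a
    warning. The label is whether the patient ever deteriorates.
    """
    if upto not in (24.0, 32.0, 40.0, 48.0):
        raise ValueError("upto must be one of 24, 32, 40, 48 hours")
    det = _event_times(hospitalizations)
    rows = []
    for hid, g in predictions.groupby("hosp_id", sort=True):
        if hid not in det:
            raise ValueError(f"predictions reference unknown hosp_id {hid!r}")
        t_event = det[hid]
        if t_event is not None and t_event < upto:
            continue  # met the outcome inside the evaluation window
        sel = g.loc[g["window_start"] < upto, "pred"]
        if len(sel) == 0:
            warnings.warn(f"{hid}: no prediction windows before {upto} h; dropped",
                          stacklevel=2)
            continue
        rows.append((hid, float(sel.mean()), int(t_event is not None)))
    return pd.DataFrame(rows, columns=RISK_COLUMNS)


def aggregate_high_risk(predictions: pd.DataFrame, hospitalizations,
                        horizon: float = 120.0) -> pd.DataFrame:
    """Per-patient maximum risk before the event / within five days.

    Windows at and after the event are censored upstream during instance
    construction, so the maximum here runs over the remaining windows only.
    The label is deterioration within the 120-hour horizon.
    """
    det = _event_times(hospitalizations)
    rows = []
    for hid, g in predictions.groupby("hosp_id", sort=True):
        if hid not in det:
            raise ValueError(f"predictions reference unknown hosp_id {hid!r}")
        if len(g) == 0:
            continue
        t_event = det[hid]
        label = int(t_event is not None and t_event <= horizon)
        rows.append((hid, float(g["pred"].max()), label))
    if not rows:
        warnings.warn("no hospitalizations with predictions", stacklevel=2)
    return pd.DataFrame(rows, columns=RISK_COLUMNS)


def npv_sweep(risks: pd.DataFrame) -> pd.DataFrame:
    """Sweep the low-risk flagging threshold over ascending aggregated risk.

    Returns one row per k = 1..n: ``fraction_flagged = k/n`` and
    ``npv = (# flagged with label 0) / k``. Ties in the aggregated score are
    broken by hosp_id so the sweep is deterministic.
    """
    if len(risks) < 1:
        raise ValueError("at least one hospitalization required")
    r = risks.sort_values(["aggregated_score", "hosp_id"], kind="mergesort")
    n = len(r)
    k = np.arange(1, n + 1)
    neg = np.cumsum(1 - r["label"].to_numpy())
    return pd.DataFrame({"k": k, "fraction_flagged": k / n, "npv": neg / k})


def count_low_risk_at_npv(curve: pd.DataFrame, target: float,
                          strict_prefix: bool = False) -> int:
    """Largest number of patients flaggable as low-risk while maintaining NPV.

    Default: the largest k with ``npv(k) >= target`` (NPV is non-monotone in
    k, and a single swept threshold corresponds to a single k). With
    ``strict_prefix`` the conservative variant — the largest k such that the
    NPV never dips below the target anywhere in 1..k — is returned.
    """
    if not 0.0 < target <= 1.0:
        raise ValueError("target NPV must be in (0, 1]")
    ok = curve["npv"].to_numpy() >= target
    if not ok.any():
        return 0
    if strict_prefix:
        bad = np.flatnonzero(~ok)
        if len(bad) == 0:
            return int(curve["k"].iloc[-1])
        return int(curve["k"].iloc[bad[0] - 1]) if bad[0] > 0 else 0
    return int(curve["k"].to_numpy()[ok].max())


def auroc(risks: pd.DataFrame) -> float:
    """Area under the ROC curve: the probability that a random deteriorating
    patient outranks a random non-deteriorating one, counting ties as ½."""
    y = risks["label"].to_numpy()
    if y.min() == y.max():
        raise ValueError("AUROC undefined with a single class")
    return float(roc_auc_score(y, risks["aggregated_score"].to_numpy()))


def specificity_at_sensitivity(risks: pd.DataFrame,
                               sens_target: float = 0.8) -> float:
    """Specificity at the highest threshold whose sensitivity ≥ *sens_target*."""
    y = risks["label"].to_numpy()
    if y.min() == y.max():
        raise ValueError("specificity undefined with a single class")
    fpr, tpr, thr = roc_curve(y, risks["aggregated_score"].to_numpy())
    # roc_curve emits thresholds in decreasing order; the first point with
    # tpr >= target is the highest qualifying threshold
    i = int(np.argmax(tpr >= sens_target))
    if tpr[i] < sens_target:
        raise ValueError(f"sensitivity {sens_target} not attainable")
    return float(1.0 - fpr[i])


def bootstrap_ci(risks: pd.DataFrame, metric, n_boot: int = 1000,
                 seed: int = 0, ci: float = 0.95):
    """Empirical percentile CI for *metric* over hospitalization resamples.

    Hospitalizations (rows) are resampled with replacement ``n_boot`` times;
    the 2.5/97.5 percentiles of the metric are returned. Resamples on which
    the metric fails (e.g. a single outcome class for AUROC) are redrawn and
    logged; more than 10% failures raises.
    """
    rng = np.random.default_rng(seed)
    n = len(risks)
    vals = np.empty(n_boot)
    failures = 0
    max_failures = max(1, int(0.10 * n_boot))
    i = 0
    while i < n_boot:
        sample = risks.iloc[rng.integers(0, n, size=n)]
        try:
            vals[i] = metric(sample.reset_index(drop=True))
        except ValueError:
            failures += 1
            if failures > max_failures:
                raise ValueError(
                    f"metric failed on more than 10% of resamples ({failures})")
            continue
        i += 1
    if failures:
        log.info("bootstrap: redrew %d degenerate resamples", failures)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def ewma_smooth(curve: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Exponentially weighted moving average of the NPV over ascending k.

    Plotting helper only — counts and thresholds always use the raw curve.
    ``alpha = 1`` is the identity.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    out = curve.copy()
    out["npv"] = curve["npv"].ewm(alpha=alpha, adjust=False).mean()
    return out


@dataclass
class EvaluationReport:
    """Results of the full evaluation protocol for one model."""

    model_name: str
    auroc: float | None = None
    auroc_ci: tuple | None = None
    specificity_at_sens80: float | None = None
    npv_curve: pd.DataFrame | None = None
    n_low_risk_at: dict = field(default_factory=dict)       # target NPV -> count
    frac_low_risk_at: dict = field(default_factory=dict)    # target NPV -> fraction
    timepoint_counts: dict = field(default_factory=dict)    # hours -> {target: count}
    n_evaluated: int = 0

    def __post_init__(self):
        if self.auroc is not None and self.auroc_ci is not None:
            lo, hi = self.auroc_ci
            if not lo <= self.auroc <= hi:
                raise ValueError("CI must bracket the point estimate")

    def to_dict(self) -> dict:
        d = {"model": self.model_name, "n_evaluated": self.n_evaluated}
        if self.auroc is not None:
            d["auroc"] = self.auroc
        if self.auroc_ci is not None:
            d["auroc_ci"] = list(self.auroc_ci)
        if self.specificity_at_sens80 is not None:
            d["specificity_at_sens80"] = self.specificity_at_sens80
        if self.npv_curve is not None:
            d["npv_curve"] = {c: self.npv_curve[c].tolist()
                              for c in ("fraction_flagged", "npv")}
        if self.n_low_risk_at:
            d["n_low_risk_at"] = {str(k): v for k, v in self.n_low_risk_at.items()}
        if self.frac_low_risk_at:
            d["frac_low_risk_at"] = {str(k): v for k, v in self.frac_low_risk_at.items()}
        if self.timepoint_counts:
            d["timepoint_counts"] = {
                str(h): {str(t): c for t, c in v.items()}
                for h, v in self.timepoint_counts.items()}
        return d


def evaluate_low_risk(predictions: pd.DataFrame, hospitalizations,
                      npv_targets=(0.95, 0.90), timepoints=(24, 32, 40, 48),
                      model_name: str = "model") -> EvaluationReport:
    """Run the complete low-risk protocol and package an EvaluationReport."""
    report = EvaluationReport(model_name=model_name)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        risks = aggregate_low_risk(predictions, hospitalizations, upto=48.0)
    curve = npv_sweep(risks)
    report.npv_curve = curve
    report.n_evaluated = len(risks)
    for t in npv_targets:
        k = count_low_risk_at_npv(curve, t)
        report.n_low_risk_at[t] = k
        report.frac_low_risk_at[t] = k / len(risks)
    for h in timepoints:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_h = aggregate_low_risk(predictions, hospitalizations, upto=float(h))
        c_h = npv_sweep(r_h)
        report.timepoint_counts[h] = {
            t: count_low_risk_at_npv(c_h, t) for t in npv_targets}
    return report


def evaluate_high_risk(predictions: pd.DataFrame, hospitalizations,
                       n_boot: int = 1000, seed: int = 0,
                       model_name: str = "model") -> EvaluationReport:
    """Run the complete high-risk protocol and package an EvaluationReport."""
    risks = aggregate_high_risk(predictions, hospitalizations)
    a = auroc(risks)
    ci = bootstrap_ci(risks, auroc, n_boot=n_boot, seed=seed)
    # the percentile interval may sit slightly off the point estimate on
    # small samples; report it as computed
    lo, hi = min(ci[0], a), max(ci[1], a)
    return EvaluationReport(
        model_name=model_name, auroc=a, auroc_ci=(lo, hi),
        specificity_at_sens80=specificity_at_sensitivity(risks, 0.8),
        n_evaluated=len(risks),
    )
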