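"""Synthetic inpatient cohort simulator.

Generates hospitalizations with a shared latent severity observable through
two modalities — a recurring EHR deterioration-index score stream and
image-derived risk scores at radiograph times — plus an image-specific
latent component that carries outcome signal the index cannot see. This is
the regime in which augmenting an EHR index with imaging can help: the image
score is a second, partially independent view of the patient's risk.

Generative model (per patient, all times in hours from admission):

* shared severity  ``s ~ N(0, 1)`` and image-specific latent ``u ~ N(0, 1)``
* deterioration indicator ``D ~ Bernoulli(sigmoid(logit(p0) + w_s*s + w_u*u))``
* length of stay ``los ~ Gamma(k=2, theta=los_mean/2)``; deterioration time
  uniform on ``(4, min(los, horizon_max))``; event type multinomial
* first radiograph uniform on ``(0, min(xray_window, los))``; the number of
  radiographs is geometric (mean configurable, default 1.8)
* index score at each cadence tick: ``sigmoid(a0 + a1*s + eps)``,
  ``eps ~ N(0, index_noise_sd)``
* image score at each radiograph: ``sigmoid(b0 + b1*s + b2*u + eta)``,
  ``eta ~ N(0, image_noise_sd)``

Each patient draws from an independent RNG stream derived from
``(seed, patient index)``, so cohorts are reproducible and membership is
order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Hospitalization",
    "ScoreStream",
    "DETERIORATION_TYPES",
    "EXCLUSION_REASONS",
    "simulate_cohort",
    "apply_inclusion_filters",
    "write_cohort",
    "read_cohort",
    "cohort_frame",
    "streams_frames",
]

#: Deterioration event types: death or ICU-level respiratory/hemodynamic support
#: (mechanical ventilation, heated high-flow nasal cannula, IV vasopressors).
DETERIORATION_TYPES = ("death", "MV", "HHFNC", "IV_pressors")

# Default event-type mix among deteriorators: COVID-positive test-cohort
# first-event proportions (death 0.013, MV 0.029, HHFNC 0.250, pressors 0.013)
# renormalized. Event type is metadata only; nothing downstream reads it.
_DEFAULT_EVENT_TYPE_P = (0.013 / 0.305, 0.029 / 0.305, 0.250 / 0.305, 0.013 / 0.305)

EXCLUSION_REASONS = (
    "no_oxygen",
    "no_xray_first_48h",
    "event_or_discharge_within_4h",
    "deterioration_before_first_xray",
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulation parameters.

    Probabilities must lie in [0, 1], standard deviations must be
    non-negative, and the index cadence is 15 or 240 minutes (the two
    cadences of deployed deterioration indices).
    """

    n_patients: int = 500
    cadence_index: int = 15            # minutes between index scores
    horizon_max: float = 120.0         # hours; events beyond this are "late"
    p_deteriorate_base: float = 0.3    # marginal event probability at s=u=0
    w_shared: float = 1.0              # weight of shared severity in outcome
    w_image_only: float = 1.0          # weight of image-specific latent in outcome
    index_noise_sd: float = 0.5
    image_noise_sd: float = 0.5
    los_mean: float = 96.0             # mean length of stay, hours
    xray_window: float = 48.0          # first radiograph falls in (0, xray_window)
    seed: int = 0
    # observation-model coefficients
    a0: float = -1.0
    a1: float = 1.0
    b0: float = -1.0
    b1: float = 1.0
    b2: float = 1.0
    mean_xrays: float = 1.8            # geometric mean radiograph count
    p_on_oxygen: float = 0.97
    event_type_p: tuple = _DEFAULT_EVENT_TYPE_P

    def validate(self) -> None:
        vals = {
            "horizon_max": self.horizon_max, "p_deteriorate_base": self.p_deteriorate_base,
            "w_shared": self.w_shared, "w_image_only": self.w_image_only,
            "index_noise_sd": self.index_noise_sd, "image_noise_sd": self.image_noise_sd,
            "los_mean": self.los_mean, "xray_window": self.xray_window,
            "a0": self.a0, "a1": self.a1, "b0": self.b0, "b1": self.b1, "b2": self.b2,
            "mean_xrays": self.mean_xrays, "p_on_oxygen": self.p_on_oxygen,
        }
        for name, v in vals.items():
            if not math.isfinite(float(v)):
                raise ValueError(f"non-finite config value: {name}={v!r}")
        if not 0.0 < self.p_deteriorate_base < 1.0:
            raise ValueError("p_deteriorate_base must be in (0, 1)")
        if not 0.0 <= self.p_on_oxygen <= 1.0:
            raise ValueError("p_on_oxygen must be in [0, 1]")
        if self.index_noise_sd < 0 or self.image_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.cadence_index not in (15, 240):
            raise ValueError("cadence_index must be 15 or 240 minutes")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mean_xrays < 1.0:
            raise ValueError("mean_xrays must be >= 1")
        if abs(sum(self.event_type_p) - 1.0) > 1e-9 or min(self.event_type_p) < 0:
            raise ValueError("event_type_p must be a probability vector")


@dataclass
class Hospitalization:
    """One admission. Times are decimal hours from admission (admit_time = 0).

    ``deterioration_time`` is the time of the *first* qualifying event when a
    patient has several; ``exit_time`` is discharge (length of stay), which
    bounds every event time.
    """

    patient_id: str
    hosp_id: str
    admit_time: float = 0.0
    exit_time: float = 0.0
    deterioration_time: float | None = None
    deterioration_type: str | None = None
    xray_times: list = field(default_factory=list)
    on_oxygen: bool = True

    @property
    def deteriorated(self) -> bool:
        return self.deterioration_time is not None

    @property
    def first_xray(self) -> float | None:
        return self.xray_times[0] if self.xray_times else None


@dataclass
class ScoreStream:
    """Timestamped probability scores from one source for one hospitalization."""

    hosp_id: str
    source: str                      # "index" or "image"
    times: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.source not in ("index", "image"):
            raise ValueError(f"unknown stream source {self.source!r}")
        if len(self.times) != len(self.scores):
            raise ValueError("times and scores must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("stream times must be strictly increasing")
        if len(self.scores) and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")


def _simulate_patient(i: int, cfg: SimConfig):
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, i])
    s = rng.standard_normal()
    u = rng.standard_normal()

    p_det = float(_sigmoid(_logit(cfg.p_deteriorate_base)
                           + cfg.w_shared * s + cfg.w_image_only * u))
    deteriorates = rng.random() < p_det
    los = rng.gamma(2.0, cfg.los_mean / 2.0)
    det_time = det_type = None
    if deteriorates:
        los = max(los, 6.0)  # an event needs a stay that clears the 4-h floor
        det_time = rng.uniform(4.0, min(los, cfg.horizon_max))
        det_type = DETERIORATION_TYPES[rng.choice(4, p=np.asarray(cfg.event_type_p))]
    on_oxygen = rng.random() < cfg.p_on_oxygen

    first_xray = rng.uniform(0.0, min(cfg.xray_window, los))
    n_xrays = int(rng.geometric(1.0 / cfg.mean_xrays))
    xray_times = np.sort(np.concatenate(
        [[first_xray], rng.uniform(first_xray, los, size=n_xrays - 1)]))
    # enforce strict ordering for the stream invariant
    xray_times = np.unique(xray_times)

    hosp = Hospitalization(
        patient_id=f"P{i:06d}", hosp_id=f"H{i:06d}",
        exit_time=float(los),
        deterioration_time=float(det_time) if det_time is not None else None,
        deterioration_type=det_type,
        xray_times=[float(t) for t in xray_times],
        on_oxygen=bool(on_oxygen),
    )

    dt = cfg.cadence_index / 60.0
    idx_times = np.arange(0.0, los, dt)
    eps = rng.normal(0.0, cfg.index_noise_sd, size=idx_times.shape)
    idx_scores = _sigmoid(cfg.a0 + cfg.a1 * s + eps)
    index_stream = ScoreStream(hosp.hosp_id, "index", idx_times, idx_scores)

    eta = rng.normal(0.0, cfg.image_noise_sd, size=xray_times.shape)
    img_scores = _sigmoid(cfg.b0 + cfg.b1 * s + cfg.b2 * u + eta)
    image_stream = ScoreStream(hosp.hosp_id, "image", xray_times, img_scores)

    return hosp, index_stream, image_stream, s, u


def simulate_cohort(cfg: SimConfig, return_latents: bool = False):
    """Generate a cohort of hospitalizations and their two score streams.

    Returns ``(hospitalizations, streams)`` where ``streams`` contains one
    index stream and one image stream per hospitalization. With
    ``return_latents`` a DataFrame of the per-patient latents (s, u, outcome)
    is appended — useful for checking that the image-specific latent actually
    carries outcome signal.
    """
    cfg.validate()
    hosps: list[Hospitalization] = []
    streams: list[ScoreStream] = []
    lat = []
    for i in range(cfg.n_patients):
        hosp, idx, img, s, u = _simulate_patient(i, cfg)
        hosps.append(hosp)
        streams.append(idx)
        streams.append(img)
        lat.append((hosp.hosp_id, s, u, hosp.deteriorated))
    if return_latents:
        latents = pd.DataFrame(lat, columns=["hosp_id", "s", "u", "deteriorated"])
        return hosps, streams, latents
    return hosps, streams


def apply_inclusion_filters(
    hospitalizations: Sequence[Hospitalization],
    streams: Sequence[ScoreStream] | None = None,
):
    """Apply the cohort inclusion/exclusion rules.

    Exclusions, first-matching reason in order:

    a. ``no_oxygen`` — never required supplemental oxygen;
    b. ``no_xray_first_48h`` — no chest radiograph within the first 48 hours;
    c. ``event_or_discharge_within_4h`` — deterioration, or discharge without
       an event, within 4 hours of presentation;
    d. ``deterioration_before_first_xray`` — the event precedes the first
       radiograph, so no post-imaging prediction window exists.

    Returns ``(kept, excluded)`` with ``excluded`` a list of
    ``(hospitalization, reason)`` pairs.
    """
    if streams is not None:
        known = {h.hosp_id for h in hospitalizations}
        for st in streams:
            if st.hosp_id not in known:
                raise ValueError(f"stream references unknown hosp_id {st.hosp_id!r}")

    kept: list[Hospitalization] = []
    excluded: list[tuple[Hospitalization, str]] = []
    for h in hospitalizations:
        reason = None
        first_xray = h.first_xray
        if not h.on_oxygen:
            reason = "no_oxygen"
        elif first_xray is None or first_xray > 48.0:
            reason = "no_xray_first_48h"
        elif ((h.deterioration_time is not None and h.deterioration_time <= 4.0)
              or (h.deterioration_time is None and h.exit_time <= 4.0)):
            reason = "event_or_discharge_within_4h"
        elif h.deterioration_time is not None and h.deterioration_time < first_xray:
            reason = "deterioration_before_first_xray"
        if reason is None:
            kept.append(h)
        else:
            excluded.append((h, reason))
    return kept, excluded


# ---------------------------------------------------------------------------
# table I/O — three comma-separated tables with header rows, times in hours

def cohort_frame(hosps: Sequence[Hospitalization]) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [h.patient_id for h in hosps],
        "hosp_id": [h.hosp_id for h in hosps],
        "admit_time": [h.admit_time for h in hosps],
        "exit_time": [h.exit_time for h in hosps],
        "deterioration_time": [h.deterioration_time for h in hosps],
        "deterioration_type": [h.deterioration_type for h in hosps],
        "on_oxygen": [int(h.on_oxygen) for h in hosps],
    })


def streams_frames(hosps, streams):
    xray_lookup = {st.hosp_id: st for st in streams if st.source == "image"}
    xr_rows, idx_rows = [], []
    for st in streams:
        if st.source == "image":
            for t, sc in zip(st.times, st.scores):
                xr_rows.append((st.hosp_id, t, sc))
        else:
            for t, sc in zip(st.times, st.scores):
                idx_rows.append((st.hosp_id, t, sc))
    xrays = pd.DataFrame(xr_rows, columns=["hosp_id", "time", "image_score"])
    index_scores = pd.DataFrame(idx_rows, columns=["hosp_id", "time", "score"])
    del xray_lookup
    return xrays, index_scores


def write_cohort(hosps, streams, out_dir) -> None:
    """Write hospitalizations.csv, xrays.csv, index_scores.csv into *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_frame(hosps).to_csv(out / "hospitalizations.csv", index=False)
    xrays, idx = streams_frames(hosps, streams)
    xrays.to_csv(out / "xrays.csv", index=False)
    idx.to_csv(out / "index_scores.csv", index=False)


def read_cohort(in_dir):
    """Read the three tables back into Hospitalization / ScoreStream objects."""
    inp = Path(in_dir)
    hdf = pd.read_csv(inp / "hospitalizations.csv")
    xdf = pd.read_csv(inp / "xrays.csv")
    idf = pd.read_csv(inp / "index_scores.csv")

    xray_times = {k: g.sort_values("time") for k, g in xdf.groupby("hosp_id")}
    hosps = []
    for row in hdf.itertuples(index=False):
        det_t = None if pd.isna(row.deterioration_time) else float(row.deterioration_time)
        det_ty = None if (isinstance(row.deterioration_type, float) and
                          pd.isna(row.deterioration_type)) else row.deterioration_type
        xt = xray_times.get(row.hosp_id)
        hosps.append(Hospitalization(
            patient_id=str(row.patient_id), hosp_id=str(row.hosp_id),
            admit_time=float(row.admit_time), exit_time=float(row.exit_time),
            deterioration_time=det_t, deterioration_type=det_ty,
            xray_times=[] if xt is None else [float(t) for t in xt["time"]],
            on_oxygen=bool(row.on_oxygen),
        ))

    streams: list[ScoreStream] = []
    for hid, g in idf.groupby("hosp_id"):
        g = g.sort_values("time")
        streams.append(ScoreStream(str(hid), "index", g["time"].to_numpy(),
                                   g["score"].to_numpy()))
    for hid, g in xdf.groupby("hosp_id"):
        g = g.sort_values("time")
        streams.append(ScoreStream(str(hid), "image", g["time"].to_numpy(),
                                   g["image_score"].to_numpy()))
    return hosps, streams


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Convenience: copy of *cfg* with a different seed."""
    return replace(cfg, seed=seed)
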