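import numpy as np
import pandas as pd
import pytest

from detfuse.simulate import Hospitalization, ScoreStream, SimConfig, simulate_cohort


def make_hosp(hosp_id="H1", exit_time=100.0, det=None, xrays=(6.0,),
              on_oxygen=True, det_type=None):
    return Hospitalization(
        patient_id="P" + hosp_id, hosp_id=hosp_id, exit_time=exit_time,
        deterioration_time=det, deterioration_type=det_type,
        xray_times=sorted(xrays), on_oxygen=on_oxygen)


def constant_index_stream(hosp_id="H1", value=0.3, until=120.0, dt=0.25):
    times = np.arange(0.0, until, dt)
    return ScoreStream(hosp_id, "index", times, np.full_like(times, value))


def make_instances_df(n, seed=0, signal=False):
    """Random instance table; with signal=True the label is separable by
    index_score alone."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    if signal:
        idx = np.where(y == 1, rng.uniform(0.6, 0.9, n), rng.uniform(0.1, 0.4, n))
    else:
        idx = rng.uniform(0, 1, n)
    return pd.DataFrame({
        "hosp_id": [f"H{i:05d}" for i in range(n)],
        "window_start": rng.choice(np.arange(4, 49, 4.0), n),
        "image_score": rng.uniform(0, 1, n),
        "index_score": idx,
        "hours_since_xray": rng.uniform(0, 48, n),
        "hours_since_admit": rng.uniform(4, 52, n),
        "label": y,
    })


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_patients=300, seed=42)
    return simulate_cohort(cfg)
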