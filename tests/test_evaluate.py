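import numpy as np
import pandas as pd
import pytest

from detfuse.evaluate import (aggregate_high_risk, aggregate_low_risk, auroc,
                              bootstrap_ci, count_low_risk_at_npv, ewma_smooth,
                              npv_sweep, patient_risks,
                              specificity_at_sensitivity, EvaluationReport)
from conftest import make_hosp


def risks_df(scores, labels, ids=None):
    ids = ids or [f"H{i:03d}" for i in range(len(scores))]
    return patient_risks(ids, scores, labels)


# ------------------------- independent oracles -----------------------------

def brute_force_npv(scores, labels, ids):
    """Flag the k lowest (score, id) patients and count label-0 among them."""
    order = sorted(range(len(scores)), key=lambda i: (scores[i], ids[i]))
    rows = []
    for k in range(1, len(scores) + 1):
        flagged = order[:k]
        npv = sum(1 for i in flagged if labels[i] == 0) / k
        rows.append((k, k / len(scores), npv))
    return rows


def brute_force_auroc(scores, labels):
    """All-pairs Mann-Whitney count, ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------

class TestAggregation:
    def test_low_risk_mean_of_window_predictions(self):
        preds = pd.DataFrame({"hosp_id": ["H1", "H1"], "window_start": [8.0, 12.0],
                              "pred": [0.2, 0.4]})
        out = aggregate_low_risk(preds, [make_hosp("H1")], upto=48.0)
        assert out.aggregated_score.iloc[0] == pytest.approx(0.3)
        assert out.label.iloc[0] == 0

    def test_singleton_mean(self):
        preds = pd.DataFrame({"hosp_id": ["H1"], "window_start": [8.0],
                              "pred": [0.8]})
        out = aggregate_low_risk(preds, [make_hosp("H1")], upto=48.0)
        assert out.aggregated_score.iloc[0] == pytest.approx(0.8)

    def test_early_deteriorator_excluded(self):
        # outcome met inside the evaluation window: patient leaves the pool
        preds = pd.DataFrame({"hosp_id": ["H1"], "window_start": [8.0],
                              "pred": [0.2]})
        out = aggregate_low_risk(preds, [make_hosp("H1", det=40.0)], upto=48.0)
        assert len(out) == 0

    def test_windows_at_24_are_prefix_of_48(self):
        rng = np.random.default_rng(0)
        preds = pd.DataFrame({
            "hosp_id": ["H1"] * 11,
            "window_start": np.arange(8.0, 49.0, 4.0),
            "pred": rng.uniform(0, 1, 11)})
        hosp = [make_hosp("H1")]
        m24 = aggregate_low_risk(preds, hosp, upto=24.0).aggregated_score.iloc[0]
        used24 = preds[preds.window_start < 24.0]["pred"]
        assert m24 == pytest.approx(used24.mean())
        used48 = preds[preds.window_start < 48.0]["pred"]
        assert set(used24.index) <= set(used48.index)

    def test_invalid_timepoint_rejected(self):
        preds = pd.DataFrame({"hosp_id": ["H1"], "window_start": [8.0],
                              "pred": [0.2]})
        with pytest.raises(ValueError):
            aggregate_low_risk(preds, [make_hosp("H1")], upto=30.0)

    def test_high_risk_takes_maximum(self):
        preds = pd.DataFrame({"hosp_id": ["H1"] * 3,
                              "window_start": [8.0, 12.0, 16.0],
                              "pred": [0.1, 0.9, 0.3]})
        out = aggregate_high_risk(preds, [make_hosp("H1", det=60.0)])
        assert out.aggregated_score.iloc[0] == pytest.approx(0.9)
        assert out.label.iloc[0] == 1

    def test_high_risk_label_requires_event_within_five_days(self):
        preds = pd.DataFrame({"hosp_id": ["H1"], "window_start": [8.0],
                              "pred": [0.5]})
        out = aggregate_high_risk(preds, [make_hosp("H1", det=130.0,
                                                    exit_time=150.0)])
        assert out.label.iloc[0] == 0

    def test_unknown_hosp_id_rejected(self):
        preds = pd.DataFrame({"hosp_id": ["HX"], "window_start": [8.0],
                              "pred": [0.5]})
        with pytest.raises(ValueError, match="unknown"):
            aggregate_low_risk(preds, [make_hosp("H1")], upto=48.0)


class TestNPVSweep:
    def test_hand_example(self):
        curve = npv_sweep(risks_df([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1]))
        assert curve.npv.iloc[1] == pytest.approx(1.0)      # k=2
        assert curve.npv.iloc[2] == pytest.approx(2 / 3)    # k=3

    def test_all_negative_labels(self):
        curve = npv_sweep(risks_df([0.5, 0.2, 0.9], [0, 0, 0]))
        assert (curve.npv == 1.0).all()

    def test_all_positive_labels(self):
        curve = npv_sweep(risks_df([0.5, 0.2, 0.9], [1, 1, 1]))
        assert (curve.npv == 0.0).all()

    def test_matches_brute_force_on_random_cohorts(self):
        # oracle equivalence over 200 random cohorts of n <= 20
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(1, 21))
            scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.8], size=n)  # heavy ties
            labels = rng.integers(0, 2, n)
            ids = [f"H{i:02d}" for i in range(n)]
            got = npv_sweep(risks_df(list(scores), list(labels), ids))
            want = brute_force_npv(list(scores), list(labels), ids)
            for (k, ff, npv), row in zip(want, got.itertuples(index=False)):
                assert row.k == k
                assert row.fraction_flagged == pytest.approx(ff)
                assert row.npv == pytest.approx(npv)

    def test_fraction_flagged_strictly_increasing(self):
        curve = npv_sweep(risks_df([0.3, 0.3, 0.3], [0, 1, 0]))
        assert (np.diff(curve.fraction_flagged) > 0).all()


class TestCountAtNPV:
    def test_hand_example_target_095(self):
        curve = npv_sweep(risks_df([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1]))
        assert count_low_risk_at_npv(curve, 0.95) == 2

    def test_hand_example_target_06(self):
        curve = npv_sweep(risks_df([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1]))
        assert count_low_risk_at_npv(curve, 0.6) == 3

    def test_all_positive_gives_zero(self):
        curve = npv_sweep(risks_df([0.1, 0.2], [1, 1]))
        assert count_low_risk_at_npv(curve, 0.5) == 0

    def test_non_increasing_in_target(self):
        rng = np.random.default_rng(7)
        curve = npv_sweep(risks_df(list(rng.uniform(0, 1, 50)),
                                   list(rng.integers(0, 2, 50))))
        counts = [count_low_risk_at_npv(curve, t)
                  for t in np.linspace(0.05, 1.0, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_matches_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(1, 21))
            curve = npv_sweep(risks_df(list(rng.uniform(0, 1, n)),
                                       list(rng.integers(0, 2, n))))
            for target in (0.9, 0.95, 0.6):
                want = max((int(k) for k, npv in zip(curve.k, curve.npv)
                            if npv >= target), default=0)
                assert count_low_risk_at_npv(curve, target) == want

    def test_strict_prefix_variant_is_conservative(self):
        # npv dips below target at k=2 then recovers: default looks past the
        # dip, the strict variant stops before it
        curve = npv_sweep(risks_df([0.1, 0.2, 0.3, 0.4, 0.5],
                                   [0, 1, 0, 0, 0]))
        assert count_low_risk_at_npv(curve, 0.7) == 5
        assert count_low_risk_at_npv(curve, 0.7, strict_prefix=True) == 1


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc(risks_df([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0

    def test_all_ties_is_half(self):
        assert auroc(risks_df([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])) == 0.5

    def test_hand_example_three_quarters(self):
        assert auroc(risks_df([0.9, 0.4, 0.6, 0.1],
                              [1, 1, 0, 0])) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(risks_df([0.1, 0.2], [1, 1]))

    def test_matches_all_pairs_counting(self):
        # oracle equivalence over 200 random score/label sets with heavy ties
        rng = np.random.default_rng(321)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            scores = list(rng.choice([0.0, 0.25, 0.5, 0.5, 0.75, 1.0], size=n))
            labels = list(rng.integers(0, 2, n))
            if len(set(labels)) < 2:
                labels[0] = 1 - labels[0]
            got = auroc(risks_df(scores, labels))
            assert got == pytest.approx(brute_force_auroc(scores, labels))


class TestSpecificityAtSensitivity:
    def test_perfect_classifier(self):
        r = risks_df([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert specificity_at_sensitivity(r, 0.8) == 1.0

    def test_positives_above_all_negatives(self):
        scores = [0.9, 0.85, 0.8, 0.75, 0.7] + list(np.linspace(0.0, 0.6, 20))
        labels = [1] * 5 + [0] * 20
        assert specificity_at_sensitivity(risks_df(scores, labels), 0.8) == 1.0

    def test_random_scores_give_one_minus_target(self):
        rng = np.random.default_rng(17)
        n = 10_000
        r = risks_df(list(rng.uniform(0, 1, n)), list(rng.integers(0, 2, n)))
        spec = specificity_at_sensitivity(r, 0.8)
        assert abs(spec - 0.2) < 3.0 / np.sqrt(n)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            specificity_at_sensitivity(risks_df([0.1], [1]), 0.8)


class TestBootstrapCI:
    def test_same_seed_identical_interval(self):
        rng = np.random.default_rng(1)
        r = risks_df(list(rng.uniform(0, 1, 80)), list(rng.integers(0, 2, 80)))
        ci1 = bootstrap_ci(r, auroc, n_boot=200, seed=5)
        ci2 = bootstrap_ci(r, auroc, n_boot=200, seed=5)
        assert ci1 == ci2

    def test_constant_metric_zero_width(self):
        r = risks_df([0.5] * 30, [0, 1] * 15)
        ci = bootstrap_ci(r, auroc, n_boot=100, seed=0)
        assert ci == (0.5, 0.5)

    def test_failing_metric_raises_after_tolerance(self):
        r = risks_df([0.1, 0.2, 0.9], [0, 0, 1])  # resamples often one-class

        def fragile(sample):
            raise ValueError("always fails")

        with pytest.raises(ValueError, match="10%"):
            bootstrap_ci(r, fragile, n_boot=50, seed=0)


class TestEWMA:
    def test_alpha_one_is_identity(self):
        curve = npv_sweep(risks_df([0.1, 0.5, 0.9], [0, 1, 0]))
        sm = ewma_smooth(curve, 1.0)
        assert np.allclose(sm.npv, curve.npv)

    def test_constant_curve_unchanged(self):
        curve = npv_sweep(risks_df([0.1, 0.5, 0.9], [0, 0, 0]))
        sm = ewma_smooth(curve, 0.3)
        assert np.allclose(sm.npv, 1.0)

    def test_alternating_converges_to_thirds(self):
        # recursion y_k = 0.5 x_k + 0.5 y_{k-1} on alternating 0/1 converges
        # to the 2/3, 1/3 cycle
        n = 400
        curve = pd.DataFrame({"k": np.arange(1, n + 1),
                              "fraction_flagged": np.arange(1, n + 1) / n,
                              "npv": np.tile([1.0, 0.0], n // 2)})
        sm = ewma_smooth(curve, 0.5)
        tail = sm.npv.to_numpy()[-2:]
        assert tail[0] == pytest.approx(2 / 3, abs=1e-6)
        assert tail[1] == pytest.approx(1 / 3, abs=1e-6)

    def test_invalid_alpha_rejected(self):
        curve = npv_sweep(risks_df([0.1], [0]))
        with pytest.raises(ValueError):
            ewma_smooth(curve, 0.0)


class TestEvaluationReport:
    def test_ci_must_bracket_point(self):
        with pytest.raises(ValueError):
            EvaluationReport("m", auroc=0.9, auroc_ci=(0.5, 0.8))

    def test_to_dict_round_trips_curve(self):
        curve = npv_sweep(risks_df([0.1, 0.5], [0, 1]))
        rep = EvaluationReport("m", npv_curve=curve, n_evaluated=2)
        d = rep.to_dict()
        assert d["npv_curve"]["npv"] == list(curve.npv)
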