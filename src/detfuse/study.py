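"""Canned study conditions: the signal-recovery experiment.

One replicate simulates disjoint train/validation/test cohorts (2000/600/3000
admissions before filtering), trains the fusion model, and compares it with
the DI-only baseline on the common evaluable patient set — the low-risk
counts at the target NPVs and the high-risk AUROCs. Run with the image-
specific latent switched on (``w_image_only=1``) the augmentation has real
signal to find; switched off (``w_image_only=0``) the image adds only a
second noisy view of the shared severity, and the high-risk AUROC gap should
be near zero.
"""

from __future__ import annotations

import dataclasses

from . import align, evaluate, fuse
from .fuse import TrainConfig
from .pipeline import (_baseline_predictions, _derive_seeds, _filtered_cohort,
                       _window_predictions, compare_low_risk)
from .simulate import SimConfig

__all__ = ["signal_recovery_replicate"]

N_TRAIN, N_VALID, N_TEST = 2000, 600, 3000


def signal_recovery_replicate(seed: int, w_image_only: float,
                              tasks=("low_risk", "high_risk"),
                              train_config: TrainConfig | None = None,
                              return_risks: bool = False) -> dict:
    """One seed of the augmentation-vs-baseline comparison.

    Returns a dict with, per requested task, the augmented and baseline
    summary metrics on the test cohort (low-risk counts on the common
    patient set; high-risk AUROC for both models). With ``return_risks`` the
    per-patient aggregated high-risk tables are included, for bootstrapping.
    """
    sim = SimConfig(w_image_only=w_image_only)
    cfg_train = train_config or TrainConfig(seed=seed)
    s_tr, s_va, s_te = _derive_seeds(seed, 3)
    h_tr, st_tr, _ = _filtered_cohort(
        dataclasses.replace(sim, n_patients=N_TRAIN, seed=s_tr), "train")
    h_va, st_va, _ = _filtered_cohort(
        dataclasses.replace(sim, n_patients=N_VALID, seed=s_va), "valid")
    h_te, st_te, _ = _filtered_cohort(
        dataclasses.replace(sim, n_patients=N_TEST, seed=s_te), "test")

    out: dict = {"seed": seed, "w_image_only": w_image_only,
                 "n_test_kept": len(h_te)}
    for task in tasks:
        ins_tr = align.build_instances(h_tr, st_tr, task)
        ins_va = align.build_instances(h_va, st_va, task)
        ins_te = align.build_instances(h_te, st_te, task)
        results = fuse.FusionModel(ins_tr, ins_va, task=task).fit(cfg_train)
        aug = _window_predictions(results, ins_te)
        base = _baseline_predictions(h_te, st_te, task)
        if task == "low_risk":
            out[task] = compare_low_risk(aug, base, h_te, (0.95, 0.90))
        else:
            ra = evaluate.aggregate_high_risk(aug, h_te)
            rb = evaluate.aggregate_high_risk(base, h_te)
            out[task] = {
                "auroc_augmented": evaluate.auroc(ra),
                "auroc_baseline": evaluate.auroc(rb),
                "specificity_at_sens80_augmented":
                    evaluate.specificity_at_sensitivity(ra, 0.8),
                "specificity_at_sens80_baseline":
                    evaluate.specificity_at_sensitivity(rb, 0.8),
            }
            if return_risks:
                out["high_risk_risks_augmented"] = ra
                out["high_risk_risks_baseline"] = rb
    return out
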