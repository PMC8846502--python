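"""End-to-end pipeline: simulate (or load) → filter → align → train → evaluate.

Train, validation and test sets are three disjoint cohorts (70/30
train/validation for model selection, a held-out test cohort for
evaluation); when an existing cohort is loaded from tables instead, it is
split at the hospitalization level so no admission contributes instances to
more than one split. Every stage logs row counts and exclusion tallies to
stderr; given a config and seed the whole run, including the report, is
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align, evaluate, fuse, simulate
from .simulate import SimConfig
from .fuse import TrainConfig

__all__ = ["PipelineConfig", "run_pipeline", "split_by_hospitalization",
           "compare_low_risk", "configure_logging"]

log = logging.getLogger("detfuse")


class _JsonLineFormatter(logging.Formatter):
    def format(self, record):
        payload = {"stage": record.name, "msg": record.getMessage()}
        return json.dumps(payload)


def configure_logging(json_lines: bool = False, level: int = logging.INFO) -> None:
    """Route pipeline logging to stderr, optionally as JSON lines."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(_JsonLineFormatter() if json_lines
                         else logging.Formatter("[%(name)s] %(message)s"))
    log.handlers = [handler]
    log.setLevel(level)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a single YAML file."""

    sim: SimConfig = field(default_factory=SimConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_train: int = 2000
    n_valid: int = 600
    n_test: int = 1000
    data_dir: str | None = None        # load tables instead of simulating
    valid_frac: float = 0.3            # hospitalization-level validation split
    test_frac: float = 0.3             # only used when loading tables
    npv_targets: tuple = (0.95, 0.90)
    timepoints: tuple = (24, 32, 40, 48)
    n_boot: int = 1000
    pre_xray_policy: str = "abstain"   # or "di_passthrough"
    seed: int = 0

    def __post_init__(self):
        if self.pre_xray_policy not in ("abstain", "di_passthrough"):
            raise ValueError("pre_xray_policy must be 'abstain' or 'di_passthrough'")
        if self.data_dir is not None and not Path(self.data_dir).is_dir():
            raise FileNotFoundError(f"data_dir does not exist: {self.data_dir}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**{**raw.get("simulate", {}),
                           "seed": raw.get("seed", 0)})
        train = TrainConfig(**{**raw.get("train", {}),
                               "seed": raw.get("seed", 0)})
        keys = {f.name for f in dataclasses.fields(cls)} - {"sim", "train"}
        top = {k: v for k, v in raw.items() if k in keys}
        if "npv_targets" in top:
            top["npv_targets"] = tuple(top["npv_targets"])
        if "timepoints" in top:
            top["timepoints"] = tuple(top["timepoints"])
        return cls(sim=sim, train=train, **top)


def split_by_hospitalization(instances: pd.DataFrame, valid_frac: float = 0.3,
                             seed: int = 0):
    """Split an instance table so each hospitalization lands in one split."""
    ids = np.sort(instances["hosp_id"].unique())
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_valid = max(1, int(round(valid_frac * len(ids))))
    valid_ids = set(ids[:n_valid])
    mask = instances["hosp_id"].isin(valid_ids)
    return instances[~mask].reset_index(drop=True), instances[mask].reset_index(drop=True)


def _derive_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _filtered_cohort(cfg_sim: SimConfig, stage: str):
    hosps, streams = simulate.simulate_cohort(cfg_sim)
    kept, excluded = simulate.apply_inclusion_filters(hosps, streams)
    tally = {r: 0 for r in simulate.EXCLUSION_REASONS}
    for _, reason in excluded:
        tally[reason] += 1
    assert len(kept) + sum(tally.values()) == len(hosps)
    log.info("%s cohort: %d admissions, %d kept, exclusions %s",
             stage, len(hosps), len(kept), tally)
    kept_ids = {h.hosp_id for h in kept}
    streams = [s for s in streams if s.hosp_id in kept_ids]
    return kept, streams, tally


def _split_loaded_cohort(cfg: PipelineConfig):
    hosps, streams = simulate.read_cohort(cfg.data_dir)
    kept, excluded = simulate.apply_inclusion_filters(hosps, streams)
    tally = {r: 0 for r in simulate.EXCLUSION_REASONS}
    for _, reason in excluded:
        tally[reason] += 1
    ids = np.sort(np.array([h.hosp_id for h in kept]))
    rng = np.random.default_rng(cfg.seed)
    rng.shuffle(ids)
    n_test = max(1, int(round(cfg.test_frac * len(ids))))
    n_valid = max(1, int(round(cfg.valid_frac * (len(ids) - n_test))))
    test_ids = set(ids[:n_test])
    valid_ids = set(ids[n_test:n_test + n_valid])
    by_id = {h.hosp_id: h for h in kept}
    groups = {"train": [], "valid": [], "test": []}
    for hid in sorted(by_id):
        split = ("test" if hid in test_ids else
                 "valid" if hid in valid_ids else "train")
        groups[split].append(by_id[hid])
    out = []
    for name in ("train", "valid", "test"):
        gids = {h.hosp_id for h in groups[name]}
        out.append((groups[name], [s for s in streams if s.hosp_id in gids]))
        log.info("loaded %s split: %d admissions", name, len(groups[name]))
    return out, tally


def _window_predictions(results: fuse.FusionResults,
                        instances: pd.DataFrame) -> pd.DataFrame:
    preds = instances[["hosp_id", "window_start"]].copy()
    preds["pred"] = results.predict(instances)
    return preds


def _baseline_predictions(hosps, streams, task: str) -> pd.DataFrame:
    grid = align.GridSpec.for_task(task)
    idx = {s.hosp_id: s for s in streams if s.source == "index"}
    frames = [align.index_baseline_predictions(h, idx[h.hosp_id], grid)
              for h in hosps]
    frames = [f for f in frames if len(f)]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["hosp_id", "window_start", "pred"])


def _with_pre_xray_passthrough(aug_preds: pd.DataFrame,
                               baseline_preds: pd.DataFrame) -> pd.DataFrame:
    """Fill windows before each patient's first fused prediction with the
    DI-only score, so the combined index covers the whole stay."""
    first_fused = aug_preds.groupby("hosp_id")["window_start"].min()
    keep = []
    for hid, g in baseline_preds.groupby("hosp_id"):
        cut = first_fused.get(hid, np.inf)
        keep.append(g[g["window_start"] < cut])
    filler = pd.concat(keep, ignore_index=True) if keep else baseline_preds.iloc[:0]
    return pd.concat([aug_preds, filler], ignore_index=True)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full study: returns a JSON-serializable report comparing the
    image-augmented model with the DI-only baseline on both tasks."""
    if cfg.data_dir is None:
        s_train, s_valid, s_test = _derive_seeds(cfg.seed, 3)
        tr = dataclasses.replace(cfg.sim, n_patients=cfg.n_train, seed=s_train)
        va = dataclasses.replace(cfg.sim, n_patients=cfg.n_valid, seed=s_valid)
        te = dataclasses.replace(cfg.sim, n_patients=cfg.n_test, seed=s_test)
        (h_tr, st_tr, tally_tr) = _filtered_cohort(tr, "train")
        (h_va, st_va, tally_va) = _filtered_cohort(va, "valid")
        (h_te, st_te, tally_te) = _filtered_cohort(te, "test")
        tallies = {"train": tally_tr, "valid": tally_va, "test": tally_te}
    else:
        splits, tally = _split_loaded_cohort(cfg)
        (h_tr, st_tr), (h_va, st_va), (h_te, st_te) = splits
        tallies = {"all": tally}

    report: dict = {
        "seed": cfg.seed,
        "exclusions": tallies,
        "n_hospitalizations": {"train": len(h_tr), "valid": len(h_va),
                               "test": len(h_te)},
    }

    for task in ("low_risk", "high_risk"):
        ins_tr = align.build_instances(h_tr, st_tr, task)
        ins_va = align.build_instances(h_va, st_va, task)
        ins_te = align.build_instances(h_te, st_te, task)
        log.info("%s instances: train=%d valid=%d test=%d",
                 task, len(ins_tr), len(ins_va), len(ins_te))

        model = fuse.FusionModel(ins_tr, ins_va, task=task)
        results = model.fit(cfg.train)
        log.info("%s model: best epoch %d, valid BCE %.4f",
                 task, results.best_epoch, results.valid_bce)

        aug_preds = _window_predictions(results, ins_te)
        base_preds = _baseline_predictions(h_te, st_te, task)

        if task == "low_risk":
            if cfg.pre_xray_policy == "di_passthrough":
                aug_preds = _with_pre_xray_passthrough(aug_preds, base_preds)
            rep_aug = evaluate.evaluate_low_risk(
                aug_preds, h_te, cfg.npv_targets, cfg.timepoints,
                model_name="image_augmented")
            rep_base = evaluate.evaluate_low_risk(
                base_preds, h_te, cfg.npv_targets, cfg.timepoints,
                model_name="di_baseline")
            comparison = compare_low_risk(aug_preds, base_preds, h_te,
                                          cfg.npv_targets)
        else:
            rep_aug = evaluate.evaluate_high_risk(
                aug_preds, h_te, n_boot=cfg.n_boot, seed=cfg.seed,
                model_name="image_augmented")
            rep_base = evaluate.evaluate_high_risk(
                base_preds, h_te, n_boot=cfg.n_boot, seed=cfg.seed,
                model_name="di_baseline")
        report[task] = {"image_augmented": rep_aug.to_dict(),
                        "di_baseline": rep_base.to_dict()}
        if task == "low_risk":
            report[task]["comparison_common_patients"] = comparison
        log.info("%s evaluated: augmented n=%d baseline n=%d",
                 task, rep_aug.n_evaluated, rep_base.n_evaluated)

    comp = report["low_risk"]["comparison_common_patients"]
    report["headline"] = {
        "extra_low_risk_at_0.95":
            comp["image_augmented"]["0.95"] - comp["di_baseline"]["0.95"],
        "extra_low_risk_at_0.9":
            comp["image_augmented"]["0.9"] - comp["di_baseline"]["0.9"],
        "auroc_gain":
            report["high_risk"]["image_augmented"]["auroc"]
            - report["high_risk"]["di_baseline"]["auroc"],
    }
    return report


def compare_low_risk(aug_preds: pd.DataFrame, base_preds: pd.DataFrame,
                     hospitalizations, npv_targets=(0.95, 0.90)) -> dict:
    """Like-for-like low-risk comparison on the common patient set.

    The DI baseline can score patients the fused model abstains on (no fused
    window in the first 48 h), so raw per-model counts have different
    denominators. Here both models are swept over exactly the
    hospitalizations that both can score.
    """
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        ra = evaluate.aggregate_low_risk(aug_preds, hospitalizations, upto=48.0)
        rb = evaluate.aggregate_low_risk(base_preds, hospitalizations, upto=48.0)
    common = sorted(set(ra["hosp_id"]) & set(rb["hosp_id"]))
    ra = ra[ra["hosp_id"].isin(common)]
    rb = rb[rb["hosp_id"].isin(common)]
    out = {"n_common": len(common), "image_augmented": {}, "di_baseline": {}}
    if not common:
        return out
    ca, cb = evaluate.npv_sweep(ra), evaluate.npv_sweep(rb)
    for t in npv_targets:
        out["image_augmented"][str(t)] = evaluate.count_low_risk_at_npv(ca, t)
        out["di_baseline"][str(t)] = evaluate.count_low_risk_at_npv(cb, t)
    return out
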