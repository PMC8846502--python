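"""The image-augmented deterioration model.

A feed-forward network with a single hidden layer of five rectified-linear
nodes and a sigmoid output, over the four-element feature vector

    [image_score, index_score, hours_since_xray, hours_since_admit],

trained with binary cross-entropy at learning rate 0.001. Features are
z-scored with training-set statistics inside the model so the two elapsed-time
covariates (raw hours) do not swamp the two probability-scale scores. Training
checkpoints every epoch and returns the weights with the lowest validation
binary cross-entropy; early stopping uses a patience counter on the same
quantity. Separate models are trained for the low-risk (ever deteriorates)
and high-risk (deteriorates within 5 days) tasks.

The network is small enough that forward and backward passes are written
directly in numpy; given a seed, training is bit-reproducible.

Usage follows the Model/Results convention::

    model = FusionModel(train_df, valid_df, task="low_risk")
    res = model.fit(TrainConfig(seed=0))
    p = res.predict(test_df)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrainConfig", "FusionModel", "FusionResults", "train", "predict",
           "FEATURES", "binary_cross_entropy"]

FEATURES = ["image_score", "index_score", "hours_since_xray", "hours_since_admit"]

_HIDDEN = 5
_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings. Only the learning rate and the loss are fixed
    by the method; the rest are conventional defaults."""

    learning_rate: float = 0.001
    max_epochs: int = 200
    batch_size: int = 64
    seed: int = 0
    patience: int = 20
    optimizer: str = "adam"   # "adam" or "sgd"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.max_epochs < 1 or self.batch_size < 1 or self.patience < 1:
            raise ValueError("max_epochs, batch_size and patience must be >= 1")


def _features_matrix(instances) -> np.ndarray:
    if isinstance(instances, pd.DataFrame):
        for f in FEATURES:
            if f not in instances.columns:
                raise KeyError(f"missing feature: {f}")
            if instances[f].isna().any():
                raise ValueError(f"missing values in feature: {f}")
        return instances[FEATURES].to_numpy(dtype=float)
    X = np.asarray(instances, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURES):
        raise ValueError(f"expected an (n, {len(FEATURES)}) feature array")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def binary_cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, clipped away from 0/1 for stability."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _forward(params, Xs):
    h = np.maximum(Xs @ params["W1"] + params["b1"], 0.0)
    z = h @ params["W2"] + params["b2"]
    p = 1.0 / (1.0 + np.exp(-z))
    return h, p.ravel()


class FusionModel:
    """Image-augmented deterioration classifier (model specification + data).

    Parameters
    ----------
    train_instances, valid_instances : DataFrame
        Prediction instances with the four feature columns and a binary
        ``label`` column. Instances from one hospitalization must live in a
        single split; the splitting is the caller's responsibility (see
        ``pipeline.split_by_hospitalization``).
    task : str
        "low_risk" or "high_risk"; recorded on the results for bookkeeping.
    """

    def __init__(self, train_instances: pd.DataFrame,
                 valid_instances: pd.DataFrame, task: str = "low_risk"):
        if task not in ("low_risk", "high_risk"):
            raise ValueError(f"unknown task {task!r}")
        if len(train_instances) == 0 or len(valid_instances) == 0:
            raise ValueError("both splits must be non-empty")
        for name, df in (("training", train_instances), ("validation", valid_instances)):
            y = np.asarray(df["label"], dtype=float)
            if y.min() == y.max():
                raise ValueError(f"single-class {name} split: cannot fit")
        self.task = task
        self.X_train = _features_matrix(train_instances)
        self.y_train = np.asarray(train_instances["label"], dtype=float)
        self.X_valid = _features_matrix(valid_instances)
        self.y_valid = np.asarray(valid_instances["label"], dtype=float)
        # feature standardizer frozen from the training split
        self.mean_ = self.X_train.mean(axis=0)
        self.sd_ = np.maximum(self.X_train.std(axis=0), 1e-8)

    @classmethod
    def from_dataframe(cls, instances: pd.DataFrame, valid_frac: float = 0.3,
                       seed: int = 0, task: str = "low_risk") -> "FusionModel":
        """Build from one instance table, splitting by hospitalization."""
        from .pipeline import split_by_hospitalization
        tr, va = split_by_hospitalization(instances, valid_frac, seed)
        return cls(tr, va, task=task)

    def _standardize(self, X):
        return (X - self.mean_) / self.sd_

    def _init_params(self, rng):
        # small uniform init scaled by fan-in
        lim1 = 1.0 / np.sqrt(len(FEATURES))
        lim2 = 1.0 / np.sqrt(_HIDDEN)
        return {
            "W1": rng.uniform(-lim1, lim1, size=(len(FEATURES), _HIDDEN)),
            "b1": np.zeros(_HIDDEN),
            "W2": rng.uniform(-lim2, lim2, size=(_HIDDEN, 1)),
            "b2": np.zeros(1),
        }

    def fit(self, cfg: TrainConfig = TrainConfig()) -> "FusionResults":
        """Minimise instance-level binary cross-entropy by mini-batch
        gradient descent; return the epoch checkpoint with the lowest
        validation BCE. Deterministic given ``cfg.seed``."""
        rng = np.random.default_rng(cfg.seed)
        params = self._init_params(rng)
        Xs = self._standardize(self.X_train)
        Xv = self._standardize(self.X_valid)
        y = self.y_train
        n = len(y)

        if cfg.optimizer == "adam":
            m = {k: np.zeros_like(v) for k, v in params.items()}
            v2 = {k: np.zeros_like(v) for k, v in params.items()}
            b1d, b2d, eps, t = 0.9, 0.999, 1e-8, 0

        best = {k: v.copy() for k, v in params.items()}
        best_bce = np.inf
        best_epoch = -1
        history = []
        stale = 0

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo:lo + cfg.batch_size]
                Xb, yb = Xs[idx], y[idx]
                h, p = _forward(params, Xb)
                # gradient of mean BCE wrt pre-sigmoid output is (p - y)/m
                dz = ((p - yb) / len(yb))[:, None]
                gW2 = h.T @ dz
                gb2 = dz.sum(axis=0)
                dh = dz @ params["W2"].T
                dh[h <= 0.0] = 0.0
                gW1 = Xb.T @ dh
                gb1 = dh.sum(axis=0)
                grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}
                if cfg.optimizer == "sgd":
                    for k in params:
                        params[k] -= cfg.learning_rate * grads[k]
                else:
                    t += 1
                    for k in params:
                        m[k] = b1d * m[k] + (1 - b1d) * grads[k]
                        v2[k] = b2d * v2[k] + (1 - b2d) * grads[k] ** 2
                        mh = m[k] / (1 - b1d ** t)
                        vh = v2[k] / (1 - b2d ** t)
                        params[k] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)

            _, pt = _forward(params, Xs)
            _, pv = _forward(params, Xv)
            tr_bce = binary_cross_entropy(pt, y)
            va_bce = binary_cross_entropy(pv, self.y_valid)
            if not (np.isfinite(tr_bce) and np.isfinite(va_bce)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: train={tr_bce}, valid={va_bce}; "
                    "check feature scaling and learning rate")
            history.append((epoch, tr_bce, va_bce))
            if va_bce < best_bce:
                best_bce = va_bce
                best = {k: np.array(v, copy=True) for k, v in params.items()}
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break

        hist = pd.DataFrame(history, columns=["epoch", "train_bce", "valid_bce"])
        return FusionResults(self.task, best, self.mean_, self.sd_, hist,
                             best_epoch, cfg)


class FusionResults:
    """Fitted image-augmented deterioration model.

    Holds the checkpointed weights, the frozen feature standardizer, the
    per-epoch loss history and the training configuration.
    """

    def __init__(self, task, params, mean, sd, history, best_epoch, config):
        self.task = task
        self.params = params
        self.mean_ = np.asarray(mean, dtype=float)
        self.sd_ = np.asarray(sd, dtype=float)
        self.history = history
        self.best_epoch = int(best_epoch)
        self.config = config

    @property
    def valid_bce(self) -> float:
        """Validation BCE of the selected checkpoint."""
        return float(self.history.loc[self.history.epoch == self.best_epoch,
                                      "valid_bce"].iloc[0])

    def predict(self, instances) -> np.ndarray:
        """Deterioration-risk probability per instance, order-preserving.

        Accepts an instance DataFrame (the four feature columns) or an
        ``(n, 4)`` array. Output is strictly inside (0, 1).
        """
        X = _features_matrix(instances)
        Xs = (X - self.mean_) / self.sd_
        _, p = _forward(self.params, Xs)
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    def summary(self) -> str:
        lines = [
            f"Image-augmented deterioration model ({self.task})",
            "=" * 52,
            f"architecture:      {len(FEATURES)} -> {_HIDDEN} (ReLU) -> 1 (sigmoid)",
            f"loss:              binary cross-entropy",
            f"optimizer:         {self.config.optimizer} "
            f"(lr={self.config.learning_rate}, batch={self.config.batch_size})",
            f"epochs run:        {len(self.history)}",
            f"selected epoch:    {self.best_epoch}",
            f"train BCE (best):  "
            f"{float(self.history.loc[self.history.epoch == self.best_epoch, 'train_bce'].iloc[0]):.4f}",
            f"valid BCE (best):  {self.valid_bce:.4f}",
            "feature standardization (training statistics):",
        ]
        for f, mu, sd in zip(FEATURES, self.mean_, self.sd_):
            lines.append(f"  {f:<18s} mean={mu:9.4f}  sd={sd:9.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize the checkpoint as versioned JSON (weights as lists)."""
        payload = {
            "format": "detfuse-fusion-checkpoint",
            "version": _CHECKPOINT_VERSION,
            "task": self.task,
            "params": {k: np.asarray(v).tolist() for k, v in self.params.items()},
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "best_epoch": self.best_epoch,
            "config": asdict(self.config),
            "history": self.history.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "FusionResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "detfuse-fusion-checkpoint":
            raise ValueError(f"{path}: not a fusion checkpoint")
        if payload["version"] > _CHECKPOINT_VERSION:
            raise ValueError(f"{path}: unsupported checkpoint version")
        params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        return cls(payload["task"], params, payload["mean"], payload["sd"],
                   pd.DataFrame(payload["history"]), payload["best_epoch"],
                   TrainConfig(**payload["config"]))


def train(instances_train: pd.DataFrame, instances_valid: pd.DataFrame,
          cfg: TrainConfig = TrainConfig(), task: str = "low_risk") -> FusionResults:
    """Functional wrapper: fit a fusion model on pre-split instance tables."""
    return FusionModel(instances_train, instances_valid, task=task).fit(cfg)


def predict(results: FusionResults, instances) -> np.ndarray:
    """Functional wrapper for :meth:`FusionResults.predict`."""
    return results.predict(instances)
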