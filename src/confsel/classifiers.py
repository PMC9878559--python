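"""Stage-1 gradient-boosted trees and stage-2 CNN / LSTM classifiers.

Stage 1 is an XGBoost tree ensemble (additive trees minimizing a regularized
objective) trained on the raw, imbalanced training split; its correctly
classified rows (TN/TP) feed the resampling stage.  Stage 2 trains a 1-D CNN
and a two-layer LSTM on the rebalanced set: both read the ordered descriptor
vector as a length-d sequence (the column order is arbitrary but fixed),
use ReLU activations, a single sigmoid output and binary cross-entropy loss.
All training is single-threaded and seeded, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from . import _nets
from .core_data import ConfusionCounts, ConformationDataset, confusion_counts

__all__ = [
    "NetConfig",
    "PredictionSet",
    "StageOneResult",
    "train_stage1",
    "train_cnn",
    "train_rnn",
    "predict",
]


@dataclass(frozen=True)
class NetConfig:
    """Stage-2 network hyperparameters (none are dictated by the problem)."""

    # CNN
    conv_filters: int = 32
    kernel_length: int = 3
    pool_length: int = 2
    cnn_dense: int = 64
    # RNN
    lstm_units: tuple[int, int] = (64, 64)
    rnn_dense: int = 32
    # shared
    dropout: float = 0.2
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.conv_filters, self.kernel_length, self.pool_length,
               self.cnn_dense, self.rnn_dense, self.epochs, self.batch_size,
               *self.lstm_units) < 1:
            raise ValueError("network sizes must be positive")


_CATEGORIES = {(1, 1): "TP", (0, 0): "TN", (0, 1): "FP", (1, 0): "FN"}


@dataclass
class PredictionSet:
    """Per-conformation truth, probability, hard label and confusion category.

    The hard label is 1 iff probability >= threshold.
    """

    truth: np.ndarray
    probability: np.ndarray
    threshold: float
    hard: np.ndarray = field(init=False)
    category: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth).astype(int)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.truth.shape != self.probability.shape:
            raise ValueError("truth and probability lengths differ")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        self.hard = (self.probability >= self.threshold).astype(int)
        self.category = np.array(
            [_CATEGORIES[(t, p)] for t, p in zip(self.truth, self.hard)]
        )

    def __len__(self) -> int:
        return len(self.truth)

    def confusion(self) -> ConfusionCounts:
        return confusion_counts(self.truth, self.hard)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "truth": self.truth,
                "probability": self.probability,
                "hard": self.hard,
                "category": self.category,
            }
        )


@dataclass
class StageOneResult:
    """Stage-1 predictions on its own training split plus the row indices it
    classified correctly (TN rows gate the undersampling pool)."""

    predictions: PredictionSet
    tn_rows: np.ndarray
    tp_rows: np.ndarray


class _Handle:
    """Fitted model + the feature contract it was trained under."""

    def __init__(self, kind, feature_names, predict_fn):
        self.kind = kind
        self.feature_names = list(feature_names)
        self._predict_fn = predict_fn

    def predict_proba(self, ds: ConformationDataset) -> np.ndarray:
        if ds.feature_names != self.feature_names:
            missing = set(self.feature_names) - set(ds.feature_names)
            extra = set(ds.feature_names) - set(self.feature_names)
            raise ValueError(
                f"feature mismatch for {self.kind}: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
                if missing or extra
                else f"feature order differs from training order for {self.kind}"
            )
        return self._predict_fn(ds.features)


def train_stage1(train: ConformationDataset, params: dict | None = None,
                 seed: int = 0) -> _Handle:
    """Fit the boosted-tree stage on the (imbalanced) training split."""
    train.require_both_classes()
    defaults = dict(
        n_estimators=100,
        max_depth=3,
        learning_rate=0.1,
        reg_lambda=1.0,
        gamma=0.0,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )
    if params:
        defaults.update(params)
    model = XGBClassifier(**defaults)
    model.fit(train.features, train.labels)
    return _Handle(
        "xgboost", train.feature_names,
        lambda X: model.predict_proba(X)[:, 1].astype(float),
    )


def predict(handle: _Handle, ds: ConformationDataset,
            threshold: float = 0.5) -> PredictionSet:
    """Score a dataset with a trained handle (feature contract enforced)."""
    proba = handle.predict_proba(ds)
    return PredictionSet(truth=ds.labels, probability=proba, threshold=threshold)


def stage_one(train: ConformationDataset, params: dict | None = None,
              seed: int = 0, threshold: float = 0.5
              ) -> tuple[_Handle, StageOneResult]:
    """Train stage 1 and record which of its own training rows it got right."""
    handle = train_stage1(train, params, seed)
    preds = predict(handle, train, threshold)
    return handle, StageOneResult(
        predictions=preds,
        tn_rows=np.flatnonzero(preds.category == "TN"),
        tp_rows=np.flatnonzero(preds.category == "TP"),
    )


class _Standardizer:
    def __init__(self, X):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd = sd

    def __call__(self, X):
        return (X - self.mean) / self.sd


def train_cnn(train: ConformationDataset, cfg: NetConfig = NetConfig()) -> _Handle:
    """1-D CNN over the descriptor vector: conv -> dropout -> pool -> dense."""
    train.require_both_classes()
    if train.d < cfg.kernel_length:
        raise ValueError(
            f"{train.d} descriptors is shorter than kernel {cfg.kernel_length}"
        )
    scale = _Standardizer(train.features)
    rng = np.random.default_rng(cfg.seed)
    model = _nets.Conv1DNet(
        train.d, rng, filters=cfg.conv_filters, kernel=cfg.kernel_length,
        pool=cfg.pool_length, dense=cfg.cnn_dense, dropout=cfg.dropout,
    )
    _nets.train_binary(
        model, scale(train.features), train.labels,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        lr=cfg.learning_rate, seed=cfg.seed,
    )
    return _Handle(
        "cnn", train.feature_names,
        lambda X: _nets.predict_proba(model, scale(X)),
    )


def train_rnn(train: ConformationDataset, cfg: NetConfig = NetConfig()) -> _Handle:
    """Two stacked LSTM layers consuming the descriptors as a sequence."""
    train.require_both_classes()
    scale = _Standardizer(train.features)
    rng = np.random.default_rng(cfg.seed)
    model = _nets.LSTMNet(
        rng, units=cfg.lstm_units, dense=cfg.rnn_dense, dropout=cfg.dropout,
    )
    _nets.train_binary(
        model, scale(train.features), train.labels,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        lr=cfg.learning_rate, seed=cfg.seed, clip=1.0,
    )
    return _Handle(
        "rnn", train.feature_names,
        lambda X: _nets.predict_proba(model, scale(X)),
    )
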