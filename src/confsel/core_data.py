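"""Dataset container, CSV I/O, stratified splitting and confusion-matrix metrics.

A :class:`ConformationDataset` holds one row per MD-frame protein conformation
and one column per global physico-chemical descriptor (MOE-style quantities
such as ``pro_asa_vdw`` or ``pro_hyd_moment``), plus a binary label:
1 = binding conformation (the minority class ligands select), 0 = non-binding.
Row order is MD frame order and is treated as meaningful — recurrence analysis
reads each descriptor as a frame-ordered series — so I/O preserves it and only
:func:`stratified_split` reorders rows, recording which rows went where.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConformationDataset",
    "SplitSpec",
    "ConfusionCounts",
    "read_dataset",
    "write_dataset",
    "stratified_split",
    "confusion_counts",
    "accuracy",
    "sensitivity",
]

DEFAULT_LABEL_COLUMN = "label"
#: optional index column ignored on read
FRAME_COLUMN = "frame"


class DatasetError(ValueError):
    """Raised for malformed or degenerate conformation datasets."""


@dataclass
class ConformationDataset:
    """Descriptor matrix with binary binding labels, in MD frame order.

    Parameters
    ----------
    name
        Free-text identifier (e.g. protein or preset name).
    features
        ``(n, d)`` float matrix, one row per conformation.
    feature_names
        ``d`` unique column names, order matching ``features``.
    labels
        ``(n,)`` vector of 0/1; 1 marks binding (minority) conformations.
    source_rows
        Optional indices into a parent dataset (set by ``stratified_split``
        so a split can be traced back to original frame numbers).
    """

    name: str
    features: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    source_rows: np.ndarray | None = None
    provenance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_names = list(self.feature_names)
        if self.features.ndim != 2:
            raise DatasetError("features must be a 2-D matrix")
        n, d = self.features.shape
        if n < 2:
            raise DatasetError(f"need at least 2 conformations, got {n}")
        if d < 1:
            raise DatasetError("need at least 1 descriptor column")
        if len(self.feature_names) != d:
            raise DatasetError(
                f"{len(self.feature_names)} names for {d} feature columns"
            )
        if len(set(self.feature_names)) != d:
            dupes = sorted(
                {f for f in self.feature_names if self.feature_names.count(f) > 1}
            )
            raise DatasetError(f"duplicate feature names: {dupes}")
        if self.labels.shape != (n,):
            raise DatasetError("labels must be a vector with one entry per row")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1}:
            raise DatasetError(f"labels must be 0/1, found values {sorted(uniq)}")
        self.labels = self.labels.astype(np.int8)
        if not np.all(np.isfinite(self.features)):
            i, j = np.argwhere(~np.isfinite(self.features))[0]
            raise DatasetError(
                f"non-finite value at row {i}, column {self.feature_names[j]!r}"
            )

    # -- convenience ---------------------------------------------------------

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def minority_count(self) -> int:
        return int(self.labels.sum())

    def require_both_classes(self) -> None:
        if self.minority_count in (0, self.n):
            raise DatasetError(
                f"dataset {self.name!r} contains a single class "
                f"({self.minority_count} of {self.n} rows labeled 1)"
            )

    def column(self, feature: str) -> np.ndarray:
        try:
            j = self.feature_names.index(feature)
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None
        return self.features[:, j]

    def to_frame(self, label_column: str = DEFAULT_LABEL_COLUMN) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[label_column] = self.labels.astype(int)
        return df

    def take(self, rows: np.ndarray, name: str | None = None) -> "ConformationDataset":
        rows = np.asarray(rows)
        return ConformationDataset(
            name=name or self.name,
            features=self.features[rows],
            feature_names=self.feature_names,
            labels=self.labels[rows],
            source_rows=rows.copy(),
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition request: 30% train by default, stratified."""

    train_fraction: float = 0.30
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies; class 1 = binding conformation."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


# -- I/O ---------------------------------------------------------------------


def read_dataset(
    path, label_column: str = DEFAULT_LABEL_COLUMN, name: str | None = None
) -> ConformationDataset:
    """Load a descriptor CSV (header row, one conformation per line).

    All non-label columns must be numeric with no missing cells; an optional
    ``frame`` column is dropped.  Both the 50- and 51-descriptor dialects
    (``pro_pl_seq`` present or absent) load identically — the column count is
    simply whatever the file provides.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise DatasetError(
            f"label column {label_column!r} not found in {path} "
            f"(columns: {list(df.columns)[:8]}...)"
        )
    if FRAME_COLUMN in df.columns:
        df = df.drop(columns=[FRAME_COLUMN])
    feature_cols = [c for c in df.columns if c != label_column]
    if not feature_cols:
        raise DatasetError(f"{path} has no descriptor columns")
    for col in feature_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise DatasetError(
                f"non-numeric value {df[col][row]!r} at row {row}, column {col!r}"
            )
        df[col] = numeric
    if df.isna().any().any():
        col = df.columns[df.isna().any().to_numpy()][0]
        row = int(df[col].isna().idxmax())
        raise DatasetError(f"missing value at row {row}, column {col!r}")
    labels = df[label_column].to_numpy()
    if not set(np.unique(labels).tolist()) <= {0, 1}:
        raise DatasetError(f"label column {label_column!r} must contain only 0/1")
    if len(np.unique(labels)) < 2:
        raise DatasetError(
            f"label column {label_column!r} is single-class; both binding and "
            "non-binding conformations are required"
        )
    return ConformationDataset(
        name=name or str(path),
        features=df[feature_cols].to_numpy(dtype=float),
        feature_names=feature_cols,
        labels=labels,
    )


def write_dataset(
    ds: ConformationDataset, path, label_column: str = DEFAULT_LABEL_COLUMN
) -> None:
    """Write the dataset as CSV; ``read_dataset`` round-trips it exactly."""
    df = ds.to_frame(label_column=label_column)
    if ds.provenance is not None:
        df["provenance"] = ds.provenance
    # repr-precision floats so write->read is the identity
    df.to_csv(path, index=False, float_format="%.17g")


# -- splitting ---------------------------------------------------------------


def _largest_remainder(ideal: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to `total`, per-entry error < 1."""
    base = np.floor(ideal).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(ideal - base), kind="stable")
        base[order[:short]] += 1
    elif short < 0:  # pragma: no cover - cannot happen with floor
        order = np.argsort(ideal - base, kind="stable")
        base[order[: -short]] -= 1
    return base


def stratified_split(
    ds: ConformationDataset, spec: SplitSpec
) -> tuple[ConformationDataset, ConformationDataset]:
    """Disjoint, exhaustive train/test partition, deterministic per seed.

    Train size is ``round(train_fraction * n)``; with stratification the
    per-class train counts follow a largest-remainder allocation, so each
    class's count deviates from ``fraction * class_count`` by less than 1.
    Each split carries ``source_rows`` mapping back to parent row indices.
    """
    ds.require_both_classes()
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(spec.train_fraction * ds.n))
    if n_train < 1 or n_train >= ds.n:
        raise DatasetError(
            f"train_fraction {spec.train_fraction} leaves an empty split for n={ds.n}"
        )
    if spec.stratified:
        classes = [0, 1]
        counts = np.array([(ds.labels == c).sum() for c in classes])
        if counts.min() < 2:
            raise DatasetError("each class needs at least 2 members to split")
        alloc = _largest_remainder(spec.train_fraction * counts, n_train)
        train_idx = []
        for c, k in zip(classes, alloc):
            rows = np.flatnonzero(ds.labels == c)
            train_idx.append(rng.permutation(rows)[:k])
        train_rows = np.sort(np.concatenate(train_idx))
    else:
        train_rows = np.sort(rng.permutation(ds.n)[:n_train])
    mask = np.zeros(ds.n, dtype=bool)
    mask[train_rows] = True
    test_rows = np.flatnonzero(~mask)
    return (
        ds.take(train_rows, name=f"{ds.name}[train]"),
        ds.take(test_rows, name=f"{ds.name}[test]"),
    )


# -- metrics -----------------------------------------------------------------


def _check_binary(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v)
    if not set(np.unique(v).tolist()) <= {0, 1}:
        raise ValueError(f"{what} must contain only 0/1 values")
    return v.astype(int)


def confusion_counts(truth, predicted) -> ConfusionCounts:
    """Tally TP/TN/FP/FN for binary binding predictions."""
    t = _check_binary(truth, "truth")
    p = _check_binary(predicted, "predicted")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: truth {t.shape} vs predicted {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of conformations whose binding status is predicted correctly."""
    if c.total == 0:
        raise ValueError("accuracy undefined on an empty prediction set")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    """Fraction of true binding conformations that the classifier recovers."""
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: no binding conformations present")
    return c.tp / (c.tp + c.fn)
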