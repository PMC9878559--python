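"""Enrichment-ratio evaluation of binding-conformation predictions.

The base enrichment ratio is the binding fraction of the evaluation set — the
hit rate of picking conformations at random.  The ML enrichment ratio is
TP/(TP+FN) inside a filtered subset of the true-binding (TP ∪ FN)
conformations, and the final enrichment ratio is their quotient: the
fold-improvement of the classifier over random selection within that subset.

Subsets are defined by filters.  Prior-art filter definitions are not
recoverable, so this package defines a filter as (ranking key, direction,
percent kept) and ships four named defaults:

* ``A`` — rank by stage-2 probability, best first;
* ``B`` — rank by stage-1 probability, best first;
* ``C`` — rank by the mean of the two probabilities, best first;
* ``D`` — rank by stage-2 probability, worst first (a pessimistic control).

Each filter is evaluated at 0.5, 1, 5 and 10 percent of the ranked set (and
any other percentages requested).  "Percent of data" is percent of the
TP ∪ FN set — the set the ML ratio is computed over — with a ceiling-rounded
subset size floored at one row.  An external per-conformation score (e.g. a
docking interaction energy) can stand in as the ranking key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import PredictionSet

__all__ = [
    "FilterSpec",
    "EnrichmentReport",
    "DEFAULT_PERCENTS",
    "default_filters",
    "base_enrichment_ratio",
    "ml_enrichment_ratio",
    "final_enrichment_ratio",
    "apply_filter",
    "enrichment_report",
]

DEFAULT_PERCENTS = (0.5, 1.0, 5.0, 10.0)

_RANKING_KEYS = ("stage2", "stage1", "mean", "external")


@dataclass(frozen=True)
class FilterSpec:
    """Subset rule over the true-binding conformations."""

    id: str
    ranking_key: str = "stage2"
    best_first: bool = True
    percent: float = 1.0

    def __post_init__(self) -> None:
        if self.ranking_key not in _RANKING_KEYS:
            raise ValueError(
                f"ranking_key must be one of {_RANKING_KEYS}, got "
                f"{self.ranking_key!r}"
            )
        if not 0 < self.percent <= 100:
            raise ValueError("percent must be in (0, 100]")


def default_filters(percent: float = 1.0) -> list[FilterSpec]:
    """The package's A–D filter conventions at one subset percentage."""
    return [
        FilterSpec("A", "stage2", True, percent),
        FilterSpec("B", "stage1", True, percent),
        FilterSpec("C", "mean", True, percent),
        FilterSpec("D", "stage2", False, percent),
    ]


def base_enrichment_ratio(labels) -> float:
    """Binding fraction of the set: the random-selection hit rate."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    positives = int((labels == 1).sum())
    if positives == 0:
        raise ValueError("no binding conformations: base ratio undefined")
    return positives / labels.size


def ml_enrichment_ratio(tp: int, fn: int) -> float:
    """Recovered fraction of binding conformations within a subset."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("ML ratio undefined with no binding conformations")
    return tp / (tp + fn)


def final_enrichment_ratio(ml: float, base: float) -> float:
    """Fold-improvement of the classifier's hit rate over random selection."""
    if base <= 0:
        raise ValueError("base enrichment ratio must be positive")
    return ml / base


def _ranking_scores(preds: PredictionSet, key: str,
                    stage1_probability=None, external_scores=None) -> np.ndarray:
    if key == "stage2":
        return preds.probability
    if key == "stage1":
        if stage1_probability is None:
            raise ValueError("filter needs stage-1 probabilities")
        return np.asarray(stage1_probability, dtype=float)
    if key == "mean":
        if stage1_probability is None:
            raise ValueError("filter needs stage-1 probabilities")
        return (preds.probability + np.asarray(stage1_probability)) / 2.0
    if external_scores is None:
        raise ValueError("filter needs external scores")
    return np.asarray(external_scores, dtype=float)


def apply_filter(preds: PredictionSet, f: FilterSpec,
                 stage1_probability=None, external_scores=None
                 ) -> tuple[int, int]:
    """TP and FN counts inside the filter's top slice of true-binding rows.

    The true-binding (TP ∪ FN) rows are ordered by the filter's ranking key
    (ties kept in stable row order), the top ``ceil(percent% · count)`` rows
    (at least one) are kept, and their TP/FN tallies returned.
    """
    pos = np.flatnonzero(preds.truth == 1)
    if pos.size == 0:
        raise ValueError("prediction set contains no binding conformations")
    scores = _ranking_scores(preds, f.ranking_key, stage1_probability,
                             external_scores)
    key = -scores[pos] if f.best_first else scores[pos]
    order = pos[np.argsort(key, kind="stable")]
    keep = max(1, math.ceil(f.percent / 100.0 * pos.size))
    kept = order[:keep]
    tp = int((preds.hard[kept] == 1).sum())
    return tp, len(kept) - tp


@dataclass
class EnrichmentReport:
    """All (filter, percent) cells plus the table-style maxima/minima summary."""

    cells: pd.DataFrame  # columns: filter, percent, tp, fn, ml_ratio, base_ratio, final_ratio
    base_ratio: float

    def maxima(self) -> dict:
        row = self.cells.loc[self.cells["final_ratio"].idxmax()]
        return {"final_ratio": float(row["final_ratio"]),
                "filter": row["filter"], "percent": float(row["percent"])}

    def minima(self) -> dict:
        row = self.cells.loc[self.cells["final_ratio"].idxmin()]
        return {"final_ratio": float(row["final_ratio"]),
                "filter": row["filter"], "percent": float(row["percent"])}

    def cell(self, filter_id: str, percent: float) -> dict:
        m = self.cells[(self.cells["filter"] == filter_id)
                       & (self.cells["percent"] == percent)]
        if m.empty:
            raise KeyError(f"no cell for filter {filter_id!r} at {percent}%")
        return m.iloc[0].to_dict()

    def summary_row(self, classifier: str) -> pd.DataFrame:
        """One printed-table row: classifier, maxima, filter, %, minima, filter, %."""
        mx, mn = self.maxima(), self.minima()
        return pd.DataFrame([{
            "classifier": classifier,
            "maxima": round(mx["final_ratio"], 1),
            "maxima_filter": f"Filter {mx['filter']}",
            "maxima_percent": mx["percent"],
            "minima": round(mn["final_ratio"], 1),
            "minima_filter": f"Filter {mn['filter']}",
            "minima_percent": mn["percent"],
        }])


def enrichment_report(preds: PredictionSet, base_labels,
                      filters=None, percents=DEFAULT_PERCENTS,
                      stage1_probability=None, external_scores=None
                      ) -> EnrichmentReport:
    """Evaluate every (filter, percent) combination on one prediction set.

    ``filters`` defaults to the A–D conventions; each is evaluated at every
    percentage in ``percents`` (a filter's own percent field is overridden).
    ``base_labels`` sets the random-selection baseline — normally the labels
    of the evaluation set itself.
    """
    base = base_enrichment_ratio(base_labels)
    if filters is None:
        filters = default_filters()
    rows = []
    for f in filters:
        for pct in percents:
            spec = FilterSpec(f.id, f.ranking_key, f.best_first, pct)
            tp, fn = apply_filter(preds, spec, stage1_probability,
                                  external_scores)
            ml = ml_enrichment_ratio(tp, fn)
            rows.append({
                "filter": f.id, "percent": pct, "tp": tp, "fn": fn,
                "ml_ratio": ml, "base_ratio": base,
                "final_ratio": final_enrichment_ratio(ml, base),
            })
    return EnrichmentReport(cells=pd.DataFrame(rows), base_ratio=base)
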