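"""Four univariate feature scorers and their consensus vote.

Each descriptor column is scored against the binding label four ways:

* one-way ANOVA F statistic between binding and non-binding groups,
* mutual information (nats) between the quantile-binned descriptor and label,
* recurrence-quantification ENTR: Shannon entropy of the diagonal-line-length
  distribution of the descriptor's frame-ordered recurrence plot — the one
  scorer that uses frame order rather than the label,
* |Spearman rank correlation| with the label.

Each scorer retains its ``top_x`` features; a feature's consensus score is the
number of scorers (0–4) that retained it, and the consensus set keeps features
at or above a vote threshold (4 by default, 3 as the documented fallback when
the strict intersection is too small).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import ConformationDataset

__all__ = [
    "FeatureRanking",
    "ConsensusScore",
    "RqaConfig",
    "anova_f_scores",
    "mutual_information_scores",
    "recurrence_matrix",
    "recurrence_diagonals",
    "rqa_entropy_scores",
    "spearman_scores",
    "consensus_select",
    "project_features",
    "DEFAULT_TOP_X",
]

#: scorers retain this many features unless told otherwise — comfortably above
#: the largest consensus set seen in practice (~12 descriptors)
DEFAULT_TOP_X = 15


@dataclass(frozen=True)
class FeatureRanking:
    """Scores from one method plus the retained top-``x`` feature list.

    ``selected`` is ordered by score descending, ties broken by original
    column order (stable and reproducible).
    """

    method: str
    scores: dict[str, float]
    top_x: int
    selected: tuple[str, ...]


@dataclass(frozen=True)
class ConsensusScore:
    votes: dict[str, int]
    threshold: int
    selected: tuple[str, ...]


@dataclass(frozen=True)
class RqaConfig:
    """Recurrence-plot parameters.

    ``radius`` is the recurrence threshold as a fraction of the (optionally
    z-scored) series' standard deviation; ``jmin`` the minimum diagonal line
    length counted; embedding uses ``embedding_dim`` delayed copies spaced
    ``delay`` frames apart with a Chebyshev (max-coordinate) distance.
    """

    radius: float = 0.2
    jmin: int = 2
    embedding_dim: int = 1
    delay: int = 1
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.jmin < 2:
            raise ValueError("jmin must be at least 2")
        if self.embedding_dim < 1 or self.delay < 1:
            raise ValueError("embedding_dim and delay must be >= 1")


def _rank(ds: ConformationDataset, method: str, scores: np.ndarray, top_x: int
          ) -> FeatureRanking:
    names = ds.feature_names
    order = np.argsort(-scores, kind="stable")  # stable => ties by column order
    k = min(top_x, len(names))
    return FeatureRanking(
        method=method,
        scores={n: float(s) for n, s in zip(names, scores)},
        top_x=top_x,
        selected=tuple(names[j] for j in order[:k]),
    )


# -- ANOVA -------------------------------------------------------------------


def anova_f_scores(ds: ConformationDataset, top_x: int = DEFAULT_TOP_X
                   ) -> FeatureRanking:
    """One-way F statistic (between-group MS over within-group MS) per feature.

    Degenerate columns: zero within-group variance with a nonzero group-mean
    difference scores ``+inf`` (perfect separation ranks first); zero within
    and zero between scores 0.
    """
    ds.require_both_classes()
    y = ds.labels
    g0 = ds.features[y == 0]
    g1 = ds.features[y == 1]
    n0, n1 = len(g0), len(g1)
    n = n0 + n1
    m0, m1 = g0.mean(axis=0), g1.mean(axis=0)
    grand = ds.features.mean(axis=0)
    ssb = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ssw = ((g0 - m0) ** 2).sum(axis=0) + ((g1 - m1) ** 2).sum(axis=0)
    msb = ssb / 1.0  # k - 1 = 1 group dof
    msw = ssw / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f = np.where(msw == 0, np.where(msb == 0, 0.0, np.inf), f)
    return _rank(ds, "anova", f, top_x)


# -- mutual information ------------------------------------------------------


def _quantile_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to an equal-frequency bin (duplicate edges merged)."""
    # exact fractions (i/bins) keep edge values reproducible to the ulp
    edges = np.quantile(x, np.arange(bins + 1) / bins)
    inner = np.unique(edges[1:-1])
    return np.searchsorted(inner, x, side="right")


def binned_mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """I(binned x; y) in nats from the empirical joint distribution."""
    u = _quantile_bins(np.asarray(x, dtype=float), bins)
    v = np.asarray(y).astype(int)
    nu, nv = u.max() + 1, v.max() + 1
    joint = np.bincount(u * nv + v, minlength=nu * nv).reshape(nu, nv) / len(u)
    pu = joint.sum(axis=1, keepdims=True)
    pv = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pu * pv))
    return float(terms[nz].sum())


def mutual_information_scores(ds: ConformationDataset, bins: int = 10,
                              top_x: int = DEFAULT_TOP_X) -> FeatureRanking:
    """MI between each quantile-binned feature and the binding label, in nats.

    A constant feature occupies a single bin and scores exactly 0.
    """
    ds.require_both_classes()
    if ds.n < bins:
        raise ValueError(f"need at least {bins} rows for {bins} quantile bins")
    mi = np.array(
        [binned_mutual_information(ds.features[:, j], ds.labels, bins)
         for j in range(ds.d)]
    )
    # clip tiny negative rounding residue; MI is non-negative
    return _rank(ds, "mi", np.maximum(mi, 0.0), top_x)


# -- recurrence quantification ----------------------------------------------


def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    m = len(x) - (dim - 1) * delay
    if m < 1:
        raise ValueError("series too short for this embedding")
    return np.stack([x[i * delay: i * delay + m] for i in range(dim)], axis=1)


def recurrence_matrix(series: np.ndarray, cfg: RqaConfig = RqaConfig()) -> np.ndarray:
    """Boolean recurrence plot R[i,k] = (distance(x_i, x_k) <= radius * sd)."""
    x = np.asarray(series, dtype=float)
    if cfg.normalize:
        sd = x.std()
        x = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
    eps = cfg.radius * x.std()
    pts = _embed(x, cfg.embedding_dim, cfg.delay)
    if cfg.embedding_dim == 1:
        v = pts[:, 0].astype(np.float32)
        return np.abs(v[:, None] - v[None, :]) <= eps
    dist = np.max(np.abs(pts[:, None, :] - pts[None, :, :]), axis=2)
    return dist <= eps


def recurrence_diagonals(series: np.ndarray, cfg: RqaConfig = RqaConfig()
                         ) -> dict[int, int]:
    """Census of maximal diagonal line lengths (>= jmin) in the recurrence plot.

    The main diagonal (the trivial self-recurrence line) is excluded; both
    triangles of the symmetric plot are counted.  A constant series with
    normalization requested is treated as all-recurrent, giving one maximal
    line per off-main diagonal.
    """
    if len(series) < cfg.jmin:
        raise ValueError("series shorter than the minimum diagonal length")
    r = recurrence_matrix(series, cfg)
    return _diagonal_census(r, cfg.jmin)


def _diagonal_census(r: np.ndarray, jmin: int) -> dict[int, int]:
    """Count maximal diagonal runs of each length >= jmin, excluding the LOI.

    Iterative shrink-and-AND: ``alive`` at level L marks start cells of runs
    of length >= L; run-starts at level L with no level-(L+1) continuation are
    maximal runs of exactly L.  Cost is O(M^2 * Lmax) boolean work.
    """
    r = r.copy()
    np.fill_diagonal(r, False)
    m = r.shape[0]
    counts: dict[int, int] = {}
    # is_start[i,k]: no recurrence at (i-1, k-1)
    alive = r
    level = 1
    starts_ge: list[int] = []  # starts_ge[L-1] = #maximal-run starts length >= L
    while alive.size and alive.any():
        size = alive.shape[0]
        is_start = alive.copy()
        is_start[1:, 1:] &= ~r[: size - 1, : size - 1]
        starts_ge.append(int(is_start.sum()))
        alive = alive[:-1, :-1] & r[level:, level:]
        level += 1
    starts_ge.append(0)
    for length in range(jmin, len(starts_ge)):
        exact = starts_ge[length - 1] - starts_ge[length]
        if exact > 0:
            counts[length] = exact
    return counts


def diagonal_entropy(counts: dict[int, int]) -> float:
    """Shannon entropy (nats) of the diagonal length distribution p(j)."""
    if not counts:
        return 0.0
    c = np.array(list(counts.values()), dtype=float)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def rqa_entropy_scores(ds: ConformationDataset, cfg: RqaConfig = RqaConfig(),
                       top_x: int = DEFAULT_TOP_X) -> FeatureRanking:
    """ENTR per descriptor series read in frame order.

    Features whose recurrence plots contain no diagonal of length >= jmin
    score 0.  This is the only scorer that is sensitive to row order.
    """
    if ds.n < cfg.jmin:
        raise ValueError("dataset shorter than the minimum diagonal length")
    entr = np.array(
        [diagonal_entropy(recurrence_diagonals(ds.features[:, j], cfg))
         for j in range(ds.d)]
    )
    return _rank(ds, "rqa", entr, top_x)


# -- Spearman ----------------------------------------------------------------


def spearman_scores(ds: ConformationDataset, top_x: int = DEFAULT_TOP_X
                    ) -> FeatureRanking:
    """|Spearman rho| of each feature against the label (Pearson on ranks)."""
    ds.require_both_classes()
    if ds.n < 3:
        raise ValueError("need at least 3 rows for a rank correlation")
    rho = np.empty(ds.d)
    for j in range(ds.d):
        col = ds.features[:, j]
        if np.ptp(col) == 0.0:
            warnings.warn(
                f"feature {ds.feature_names[j]!r} is constant; Spearman rho "
                "undefined, scored 0",
                stacklevel=2,
            )
            rho[j] = 0.0
            continue
        rho[j] = stats.spearmanr(col, ds.labels).statistic
    return _rank(ds, "spearman", np.abs(rho), top_x)


# -- consensus ---------------------------------------------------------------


def consensus_select(rankings, threshold: int = 4) -> ConsensusScore:
    """Vote count per feature over the rankings' selected lists.

    A feature enters the consensus set when at least ``threshold`` of the
    methods retained it; the set keeps original column order.  An empty
    consensus is returned as-is — callers choose whether to relax the
    threshold (a documented option) rather than any silent fallback here.
    """
    rankings = list(rankings)
    if not 1 <= threshold <= len(rankings):
        raise ValueError(f"threshold must be in 1..{len(rankings)}")
    names = list(rankings[0].scores)
    for r in rankings[1:]:
        if list(r.scores) != names:
            raise ValueError(
                f"ranking {r.method!r} covers a different feature set"
            )
    votes = {
        name: sum(name in r.selected for r in rankings) for name in names
    }
    selected = tuple(n for n in names if votes[n] >= threshold)
    return ConsensusScore(votes=votes, threshold=threshold, selected=selected)


def project_features(ds: ConformationDataset, keep) -> ConformationDataset:
    """Restrict the dataset to the named columns (given order preserved)."""
    keep = list(keep)
    if not keep:
        raise ValueError("keep list is empty")
    unknown = [k for k in keep if k not in ds.feature_names]
    if unknown:
        raise KeyError(f"unknown feature names: {unknown}")
    idx = [ds.feature_names.index(k) for k in keep]
    return ConformationDataset(
        name=ds.name,
        features=ds.features[:, idx],
        feature_names=keep,
        labels=ds.labels,
        source_rows=ds.source_rows,
    )
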