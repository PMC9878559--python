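"""Two-stage resampling: GAN minority oversampling + K-Means undersampling.

The rebuilt training set obeys an equal-size contract — it has exactly as many
rows as the original training split — but its class balance is shifted toward
the binding (minority) class: every real minority row is kept, a generative
adversarial network trained on those rows synthesizes the rest of the minority
quota, and the majority quota is filled by cluster-based undersampling
(K-Means centroids' nearest real rows, allocated proportionally to cluster
size).  Default balance is 1:1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from ._nets import MLP, Adam, clip_grads, sigmoid
from .core_data import ConformationDataset

__all__ = [
    "GanConfig",
    "ResamplingPlan",
    "GanHandle",
    "fit_gan",
    "sample_minority",
    "kmeans_undersample",
    "rebalance",
]


@dataclass(frozen=True)
class GanConfig:
    """Adversarial training hyperparameters (fully connected G and D)."""

    latent_dim: int = 32
    generator_layers: tuple[int, int] = (64, 64)
    discriminator_layers: tuple[int, int] = (64, 64)
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 2e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.latent_dim, self.epochs, self.batch_size) < 1:
            raise ValueError("GAN config values must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class ResamplingPlan:
    """Equal-size rebuild target: ``target_total`` = original training size."""

    target_total: int
    minority_target: int | None = None  # default: target_total // 2
    kmeans_clusters: int = 10
    seed: int = 0

    def resolved_minority(self) -> int:
        m = self.minority_target
        if m is None:
            m = self.target_total // 2
        if not 0 < m <= self.target_total:
            raise ValueError("minority_target must be in (0, target_total]")
        return m


class GanHandle:
    """Trained generator plus the standardizer fitted on the minority rows."""

    def __init__(self, gen: MLP, mean: np.ndarray, sd: np.ndarray,
                 cfg: GanConfig):
        self._gen = gen
        self._mean = mean
        self._sd = sd
        self.cfg = cfg
        self._rng = np.random.default_rng(cfg.seed + 1)

    @property
    def n_features(self) -> int:
        return self._gen.W[-1].shape[1]

    def sample(self, k: int) -> np.ndarray:
        if k < 1:
            raise ValueError("k must be at least 1")
        z = self._rng.standard_normal((k, self.cfg.latent_dim)).astype(np.float32)
        x, _ = self._gen.forward(z)
        return (x.astype(float) * self._sd) + self._mean

    def save(self, path) -> None:
        np.savez(
            path,
            mean=self._mean,
            sd=self._sd,
            latent_dim=self.cfg.latent_dim,
            seed=self.cfg.seed,
            n_layers=len(self._gen.W),
            **{f"W{i}": w for i, w in enumerate(self._gen.W)},
            **{f"b{i}": b for i, b in enumerate(self._gen.b)},
        )

    @classmethod
    def load(cls, path) -> "GanHandle":
        with np.load(path) as z:
            cfg = GanConfig(latent_dim=int(z["latent_dim"]), seed=int(z["seed"]))
            gen = MLP([1, 1], np.random.default_rng(0))
            n = int(z["n_layers"])
            gen.W = [z[f"W{i}"] for i in range(n)]
            gen.b = [z[f"b{i}"] for i in range(n)]
            return cls(gen, z["mean"], z["sd"], cfg)


def fit_gan(minority_rows: np.ndarray, cfg: GanConfig = GanConfig()) -> GanHandle:
    """Adversarial fit on the binding-class rows (standardized internally).

    The discriminator maximizes real/fake discrimination (binary
    cross-entropy, real=1, fake=0); the generator minimizes it through the
    non-saturating objective (fake labeled real).  Deterministic per seed.
    """
    X = np.asarray(minority_rows, dtype=float)
    if X.ndim != 2 or len(X) < 10:
        raise ValueError("need a 2-D matrix with at least 10 minority rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("minority rows contain non-finite values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = ((X - mean) / sd).astype(np.float32)
    n, d = Xs.shape

    rng = np.random.default_rng(cfg.seed)
    gen = MLP([cfg.latent_dim, *cfg.generator_layers, d], rng, hidden="relu")
    dis = MLP([d, *cfg.discriminator_layers, 1], rng, hidden="leaky")
    opt_g = Adam(gen.params, lr=cfg.learning_rate, beta1=0.5)
    opt_d = Adam(dis.params, lr=cfg.learning_rate, beta1=0.5)

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for s in range(0, n, cfg.batch_size):
            real = Xs[order[s: s + cfg.batch_size]]
            b = len(real)
            z = rng.standard_normal((b, cfg.latent_dim)).astype(np.float32)
            fake, gcache = gen.forward(z)

            # discriminator step on real (target 1) and fake (target 0)
            lr_, cr = dis.forward(real)
            lf_, cf = dis.forward(fake)
            d_real = (sigmoid(lr_) - 1.0) / b
            d_fake = sigmoid(lf_) / b
            gr, _ = dis.backward(cr, d_real.astype(np.float32))
            gf, _ = dis.backward(cf, d_fake.astype(np.float32))
            opt_d.step(clip_grads([a + c for a, c in zip(gr, gf)], 5.0))

            # generator step: fool the discriminator (fake target 1)
            z = rng.standard_normal((b, cfg.latent_dim)).astype(np.float32)
            fake, gcache = gen.forward(z)
            lf_, cf = dis.forward(fake)
            d_out = (sigmoid(lf_) - 1.0) / b
            _, dfake = dis.backward(cf, d_out.astype(np.float32))
            ggrads, _ = gen.backward(gcache, dfake)
            opt_g.step(clip_grads(ggrads, 5.0))

    return GanHandle(gen, mean, sd, cfg)


def sample_minority(handle: GanHandle, k: int) -> np.ndarray:
    """Draw ``k`` synthetic minority rows in original feature units."""
    return handle.sample(k)


def kmeans_undersample(majority_rows: np.ndarray, target: int,
                       k_clusters: int = 10, seed: int = 0) -> np.ndarray:
    """Pick ``target`` representative majority rows via K-Means clusters.

    Rows are clustered (standardized features), the quota is split across
    clusters proportionally to cluster size by largest remainder, and within
    each cluster the rows nearest the centroid are taken.  Returns exactly
    ``target`` distinct row indices, deterministically for a fixed seed.
    """
    X = np.asarray(majority_rows, dtype=float)
    n = len(X)
    if target > n:
        raise ValueError(f"target {target} exceeds available rows {n}")
    if target == 0:
        return np.array([], dtype=int)
    if k_clusters < 1:
        raise ValueError("k_clusters must be at least 1")
    if target == n:
        return np.arange(n)
    k = min(k_clusters, n)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assign = km.fit_predict(Xs)
    sizes = np.bincount(assign, minlength=k)

    # proportional quota, largest remainder, capped at cluster size
    ideal = target * sizes / n
    alloc = np.floor(ideal).astype(int)
    rem_order = np.argsort(-(ideal - alloc), kind="stable")
    short = target - alloc.sum()
    for c in rem_order:
        if short == 0:
            break
        if alloc[c] < sizes[c]:
            alloc[c] += 1
            short -= 1
    while short > 0:  # residual capacity pass (tiny clusters saturated)
        for c in np.argsort(-(sizes - alloc), kind="stable"):
            if short == 0:
                break
            if alloc[c] < sizes[c]:
                alloc[c] += 1
                short -= 1
    alloc = np.minimum(alloc, sizes)

    chosen = []
    for c in range(k):
        if alloc[c] == 0:
            continue
        rows = np.flatnonzero(assign == c)
        dist = np.linalg.norm(Xs[rows] - km.cluster_centers_[c], axis=1)
        order = rows[np.argsort(dist, kind="stable")]
        chosen.append(order[: alloc[c]])
    out = np.concatenate(chosen)
    assert len(out) == target and len(np.unique(out)) == target
    return np.sort(out)


def rebalance(train: ConformationDataset, plan: ResamplingPlan,
              gan_cfg: GanConfig | None = None,
              majority_pool: np.ndarray | None = None,
              gan: GanHandle | None = None) -> ConformationDataset:
    """Rebuild the training split at the same total size, minority-enriched.

    All real minority rows are retained; the GAN fills the minority quota;
    :func:`kmeans_undersample` fills the majority quota (optionally from a
    restricted ``majority_pool`` of row indices, e.g. the rows a stage-1
    classifier labeled correctly).  The result carries a per-row ``provenance``
    array (``"real"`` / ``"generated"``).
    """
    train.require_both_classes()
    total = plan.target_total
    if total != train.n:
        raise ValueError(
            f"plan.target_total ({total}) must equal the training size ({train.n})"
        )
    minority_target = plan.resolved_minority()
    min_rows = np.flatnonzero(train.labels == 1)
    maj_rows = np.flatnonzero(train.labels == 0)
    if minority_target < len(min_rows):
        raise ValueError(
            f"minority_target {minority_target} would discard "
            f"{len(min_rows) - minority_target} real binding rows"
        )
    n_generate = minority_target - len(min_rows)
    majority_target = total - minority_target
    pool = maj_rows if majority_pool is None else np.asarray(majority_pool)
    if majority_target > len(pool):
        pool = maj_rows  # restricted pool too small: fall back to all majority
    if majority_target > len(pool):
        raise ValueError(
            f"majority quota {majority_target} exceeds available majority rows "
            f"{len(pool)}"
        )

    if n_generate > 0:
        if gan is None:
            gan = fit_gan(train.features[min_rows], gan_cfg or GanConfig())
        synth = sample_minority(gan, n_generate)
    else:
        synth = np.empty((0, train.d))
    keep_maj = pool[kmeans_undersample(
        train.features[pool], majority_target,
        k_clusters=plan.kmeans_clusters, seed=plan.seed)]

    features = np.vstack([train.features[min_rows], synth,
                          train.features[keep_maj]])
    labels = np.concatenate([
        np.ones(minority_target, dtype=np.int8),
        np.zeros(majority_target, dtype=np.int8),
    ])
    provenance = np.array(
        ["real"] * len(min_rows) + ["generated"] * n_generate
        + ["real"] * majority_target
    )
    out = ConformationDataset(
        name=f"{train.name}[rebalanced]",
        features=features,
        feature_names=train.feature_names,
        labels=labels,
    )
    out.provenance = provenance
    return out
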