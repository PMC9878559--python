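# Methods

This note documents the models, the defaults and the design choices behind
`confsel`, in the spirit of a methods appendix: what is computed, under what
assumptions, and what the synthetic benchmarks do and do not demonstrate.

## Data model

A dataset is a matrix of n conformations × d global physico-chemical
descriptors plus a binary label; label 1 ("binding") is always the minority
class. Row order is MD frame order and is semantically meaningful: the
recurrence scorer reads each descriptor column as a time series. I/O therefore
preserves row order exactly (CSV written at full float precision and read back
with round-trip parsing), missing values are rejected at load rather than
imputed, and only the stratified splitter reorders rows — recording the
original row indices of each split.

The 30/70 train/test split uses `round(0.30·n)` training rows with per-class
largest-remainder allocation, so each class's training count deviates from
0.30 × (class count) by less than one. Whether the original protocol
stratified its split is unknown; stratified is the default and a flag
disables it.

## The four feature scorers

* **ANOVA F** — between-group over within-group mean square for the two label
  groups. Degenerate columns are given explicit values: zero within-group
  variance with separated means scores +∞ (ranks first); a constant column
  scores 0.
* **Mutual information** — the label is discrete; the descriptor is
  discretized into 10 equal-frequency (quantile) bins, and the plug-in
  estimate I = Σ p(u,v) log[p(u,v)/(p(u)p(v))] is reported in nats. Values
  equal to a bin edge go to the upper bin; duplicate edges are merged, so a
  constant column occupies one bin and scores exactly 0. The estimator choice
  (quantile bins, 10, label kept discrete) is a package decision; no estimator
  is dictated by the problem.
* **RQA entropy (ENTR)** — per descriptor, the frame-ordered series is
  z-scored, a recurrence matrix R(i,k) = 1{|x_i − x_k| ≤ ε} is built with
  ε = 0.2 standard deviations, maximal diagonal lines of length ≥ 2 are
  censused over both triangles excluding the main diagonal (Theiler window 1),
  and ENTR = −Σ_j p(j) ln p(j) over the line-length distribution. No time-delay
  embedding is used by default (dim 1, delay 1); embedding with Chebyshev
  distance is available. A constant series is treated as all-recurrent. All
  RQA parameters are package defaults — none are dictated by the problem —
  and the sd-relative radius makes ENTR invariant to positive rescaling of a
  descriptor.
* **|Spearman ρ|** — Pearson correlation of average ranks against the label,
  ranked by absolute value. A constant column is undefined and scores 0 with
  a warning.

Each scorer retains its top 15 features by default — "x" is user-defined in
the original protocol with no published value; 15 sits comfortably above the
largest consensus sets seen in practice (5–12) and is configurable. Ties are
broken by original column order so rankings are reproducible. The consensus
set keeps features retained by all four scorers (threshold 4); threshold 3 is
an explicit option mirroring the published fallback for one target, and an
empty consensus aborts the pipeline with advice rather than silently relaxing.

## Resampling cascade

The rebuilt training set has **exactly** the size of the original training
split; only its composition changes (default 1:1 — the target balance is a
package default, as the original protocol states the goal but not the ratio).
Real binding rows are never discarded, and generated rows are always labeled 1.

* **GAN oversampling.** Generator and discriminator are two-hidden-layer
  (64, 64) fully connected networks on standardized minority rows
  (latent dim 32, Adam at 2·10⁻⁴ with β₁ = 0.5, batch 64, 200 epochs,
  non-saturating generator loss). A ~50-dimensional tabular problem does not
  need convolutional machinery; the architecture is the package's choice.
* **K-Means undersampling.** Majority rows are clustered (k = 10,
  standardized features); the majority quota is allocated across clusters
  proportionally to cluster size by largest remainder, and each cluster
  contributes its rows nearest the centroid — a deterministic representative
  choice preferred over random within-cluster sampling for reproducibility.
  By default the pool is restricted to majority rows the stage-1 classifier
  labeled correctly (its TN set), falling back to all majority rows when that
  pool is too small; a switch disables the gating. The original description
  of how stage-1 results feed the clustering is ambiguous; this reading is
  documented as the package's interpretation.
* One run = one feature mode. A full-descriptor run and a consensus-projected
  run are two independent pipeline executions (`--no-feature-selection`
  selects the former); the protocol text can also be read as one run
  processing both datasets, but independent runs keep every artifact
  unambiguous.

## Classifiers

Stage 1 is XGBoost (100 trees, depth 3, η = 0.1, λ = 1, single thread,
seeded) — defaults chosen for good generalization at n ≈ 10³, d ≈ 50.
Stage 2 contains two networks, both reading the descriptor vector as an
ordered length-d sequence (column order is arbitrary but fixed), implemented
in seeded float32 NumPy with Adam and binary cross-entropy on logits:

* **CNN**: one 1-D convolution (32 filters, kernel 3, ReLU) → dropout 0.2 →
  max-pool 2 → dense 64 (ReLU) → sigmoid output.
* **LSTM**: two stacked LSTM layers (64, 64 by default) with dropout,
  ReLU cell/output activation (gates sigmoid), dense 32 (ReLU) with dropout,
  sigmoid output. ReLU recurrent activation can be unstable; training clips
  the global gradient norm at 1.0.

Hard labels use threshold 0.5 with the ≥ convention. Epochs (100), batch
size (32) and learning rate (10⁻³) are config defaults; every run's log
records all of them, so no configuration is hidden. Determinism holds in the
tested single-threaded mode.

## Enrichment framework

base = binding fraction of the evaluation set; ML = TP/(TP+FN) within a
subset; final = ML/base, so final ≤ 1/base with equality for a perfect
classifier, and final = 1 when the subset's TP fraction equals the base rate.
Subsets are taken from the true-binding (TP ∪ FN) rows — the set the ML ratio
is defined over — ordered by a ranking key, keeping ceil(percent% · count)
rows with a floor of one and stable tie-breaks. The A–D filter definitions
(A: stage-2 probability best-first, B: stage-1 best-first, C: mean
best-first, D: stage-2 worst-first as a pessimistic control) are **this
package's conventions**: the original filters live in prior work that is not
restated in the protocol this package implements, so they are configurable,
including an external ranking key for docking interaction energies.
"Percent of data" is likewise read as percent of the TP ∪ FN set. Published
enrichment tables for the four GPCR targets are not reproducible without the
unreleased data and filter definitions, and the package does not attempt it.

## Synthetic data

The generator emulates the *statistical shape* of the study tables: exact
minority counts; Gaussian descriptors with per-feature locations and scales
spanning descriptor-like magnitudes (unit charges up to ~10³·⁵ surface
areas); class signal injected as a mean shift of `effect_size` within-class
standard deviations on the informative features; AR(1) noise
(e_t = φ·e_{t−1} + √(1−φ²)·ε_t, unit marginal variance, φ = 0.8 on the
informative features by default) so recurrence plots have genuine diagonal
structure; optional shared-factor correlation and label noise (both off by
default). Labels are generated directly, not thresholded from any docking
score, and binding frames are scattered uniformly over the trajectory.

Presets fix the four study shapes (ADORA2A 2998×50/851, ADRB2 2565×51/156,
OPRD1 3004×51/72, OPRK1 2998×50/138) and a planted-signal benchmark
(`PLANTED`: 2000×50, 200 binding = 10% base rate, five informative
descriptors at effect size 2.0, φ = 0.8) used by the end-to-end checks —
five informative descriptors matches the low end of the consensus-set sizes
seen in practice. What passing tests on these data show is that the
machinery works: planted linear mean-shift signal is recovered, the cascade
raises sensitivity, enrichment reaches its ceiling. What they cannot show is
performance on real MD descriptor tables, whose feature covariance,
non-Gaussian marginals and label mechanism the generator does not attempt to
match.

## Numerical choices and test design

* Quantile-bin edges use exact fractions i/bins so edge values are
  reproducible to the ulp; CSV round-trips are exact at 17 significant
  digits.
* The diagonal census is computed by iterative shrink-and-AND over the
  boolean recurrence matrix (O(M²·L_max)); tests check it against an explicit
  per-diagonal enumeration.
* Every scorer, the confusion tally and every enrichment cell are tested
  against independent loop-based brute-force oracles on small instances at
  1e-9.
* End-to-end and calibration tests use scaled-down network settings
  (25–40 epochs, LSTM 16–32 units) — the package's chosen problem sizes for
  its benchmark suite — while the statistical study conditions (dataset
  shapes, effect sizes, imbalance ratios, seed counts) are kept in full.
* The null-calibration check runs the cascade on *balanced* label-permuted
  data. Final enrichment compares the subset TP fraction with the base rate;
  a classifier trained on the rebalanced 1:1 set has a marginal positive rate
  near 0.5 regardless of truth, so "no spurious enrichment" (final ≈ 1) is
  the meaningful expectation only when the base rate is also ≈ 0.5. On an
  imbalanced null set the same random classifier would score final ≈ 5 purely
  by construction of the ratio — a property of the metric, not of learning.

## Known limitations

* The LSTM's ReLU recurrent activation trades faithfulness to the described
  architecture for occasional sensitivity to learning rate; gradient clipping
  mitigates but does not remove it.
* The GAN is a minimal fully connected model with no mode-collapse
  diagnostics beyond distribution-moment tests.
* Filters A–D are package conventions, not recovered definitions; published
  per-target enrichment values are out of reach without the original data.
* Descriptor order for the CNN/LSTM "sequence" is the column order of the
  input table; no physical ordering is claimed.
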