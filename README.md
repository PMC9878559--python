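# confsel

Class-imbalance-aware machine learning for **conformational selection**:
predicting which rare apo-protein conformations from a molecular-dynamics
ensemble are the "binding" conformations that ligands select.

## The problem

A protein cycles through thousands of conformations; ligands bind only a small
minority of them. Given a table with one row per MD-frame conformation,
50–51 global physico-chemical descriptors per row (MOE-style quantities such
as `pro_asa_vdw`, `pro_hyd_moment`) and a binary label (1 = binding,
0 = non-binding, at imbalances from 3:1 to 41:1), the task is to learn which
descriptors drive binding propensity and to rank unseen conformations so that
a short list is strongly enriched in true binding conformations — the input a
docking campaign actually needs.

## The method

1. **Consensus feature selection.** Each descriptor is scored four ways
   against the label: one-way ANOVA F; mutual information
   I(U;V) = Σ_u Σ_v p(u,v) log[p(u,v)/(p(u)p(v))] with quantile-binned
   descriptors; recurrence-quantification entropy
   ENTR = −Σ_j p(j) ln p(j) over the diagonal-line-length distribution of the
   descriptor's frame-ordered recurrence plot; and |Spearman ρ|. Each scorer
   keeps its top *x* (default 15); descriptors kept by all four (consensus
   score 4, or 3 as a documented fallback) form the working feature set.
2. **Two-stage imbalance-aware cascade.** Stage 1 fits gradient-boosted trees
   (XGBoost, ŷ = Σ_k t_k(x) minimizing a regularized objective) on a
   stratified 30% training split. The training split is then rebuilt at
   *exactly its original size*: every real binding row is kept, a GAN trained
   on the binding rows (min_F max_D E_u log D(u) + E_v log(1 − D(F(v))))
   synthesizes minority rows up to a 1:1 balance, and K-Means undersampling
   selects representative non-binding rows (by default from the rows stage 1
   classified correctly). Stage 2 trains a 1-D CNN and a two-layer LSTM on the
   rebuilt split; both read the descriptor vector as a sequence, use ReLU
   activations, a sigmoid output and binary cross-entropy.
3. **Enrichment-ratio evaluation.** On the held-out 70%:
   base ratio = binding fraction of the test set;
   ML ratio = TP/(TP+FN) within a filtered subset of the true-binding rows;
   final ratio = ML/base, the fold-improvement over random selection.
   Four filters (A: stage-2 probability best-first, B: stage-1 best-first,
   C: mean best-first, D: stage-2 worst-first) are each evaluated at
   0.5/1/5/10% of the ranked set.

Because the four GPCR descriptor tables the method was developed on are not
publicly deposited, the package ships a synthetic-data module that reproduces
their statistical shape (exact row/descriptor/imbalance counts, planted
informative descriptors, AR(1) frame-order correlation) so every stage is
testable end to end.

## Worked example

```python
from confsel import PipelineConfig, run_pipeline
from confsel.classifiers import NetConfig
from confsel.imbalance_sampling import GanConfig

cfg = PipelineConfig(preset="PLANTED",
                     net=NetConfig(epochs=40, lstm_units=(32, 32), batch_size=64),
                     gan=GanConfig(epochs=150), seed=7)
record = run_pipeline(cfg)
```

prints (via `examples/04_full_pipeline.py`):

```
consensus kept 5 features: pro_asa_vdw, pro_asa_hyd, pro_asa_hph, pro_volume, pro_dipole_moment
sensitivity: stage-1 0.893, CNN 0.957, RNN 0.993
CNN: base ratio 0.10, max final enrichment 10.0 (Filter A, 0.5% of data)
RNN: base ratio 0.10, max final enrichment 10.0 (Filter A, 0.5% of data)
```

The consensus vote recovered exactly the five planted informative
descriptors. Stage-1 sensitivity on the raw 10:1 split is 0.893; after
GAN + K-Means rebalancing the stage-2 classifiers reach 0.957–0.993 — the
cascade's purpose is precisely this gain in binding-conformation detection.
A final enrichment of 10.0 is the theoretical ceiling at a 10% base rate:
every conformation in the filtered short list was a correctly predicted
binder.

The same pipeline is available from the shell:

```bash
confsel generate --out data/ --seed 0          # four study-shaped CSVs
confsel select --preset ADORA2A                # scorers + consensus only
confsel run --preset PLANTED --seed 7 --out results/run/
confsel run --input data/ADORA2A.csv --no-feature-selection --out results/raw/
```

Each `examples/*.py` script is a short narrative of one capability.

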