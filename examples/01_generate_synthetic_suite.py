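"""Generate the four study-shaped synthetic descriptor tables.

Each CSV has one row per MD-frame conformation, MOE-style descriptor columns
and a binary `label` column (1 = binding, the minority class).  The shapes —
row counts, descriptor counts and class imbalance from 3:1 up to 41:1 —
mirror the four GPCR systems the method targets.
"""

from confsel import generate_suite, read_dataset

paths = generate_suite("scratch/suite", seed=0)
for path in paths:
    ds = read_dataset(path)
    ratio = (ds.n - ds.minority_count) / ds.minority_count
    print(f"{ds.name}: {ds.n} conformations x {ds.d} descriptors, "
          f"{ds.minority_count} binding ({ratio:.0f}:1 imbalance)")
# ADORA2A: 2998 x 50, 851 binding (3:1); OPRD1: 3004 x 51, 72 binding (41:1)
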