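"""Synthetic MD-descriptor tables with planted class signal.

The real study systems are four GPCR descriptor tables (one row per MD frame,
50–51 global physico-chemical descriptors, binary binding label, strong class
imbalance).  Those tables are not publicly deposited, so this module generates
datasets with the same statistical shape:

* exact class counts (minority = binding = label 1),
* a small planted set of class-informative features whose class-conditional
  means differ by ``effect_size`` pooled-standard-deviation units,
* AR(1) serial correlation along frame order on a configurable feature subset
  (MD descriptors evolve smoothly frame to frame; this gives recurrence
  analysis genuine diagonal-line structure),
* descriptor-like magnitudes and MOE-style column names.

The generated label is a statistical construct, not the output of any docking
calculation: the module emulates the shape of the data, not its physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core_data import ConformationDataset, write_dataset

__all__ = ["SyntheticSpec", "PRESETS", "preset", "generate_dataset", "generate_suite"]

# Descriptor names printed for the four study proteins, used verbatim before
# falling back to generated pro_desc_* names.
_MOE_NAMES = [
    "pro_asa_vdw", "pro_asa_hyd", "pro_asa_hph", "pro_volume",
    "pro_dipole_moment", "pro_hyd_moment", "pro_helicity", "pro_app_charge",
    "pro_net_charge", "pro_zquadrupole", "pro_patch_ion", "pro_patch_ion_n",
    "pro_patch_hyd", "pro_patch_hyd_1", "pro_patch_hyd_4", "pro_patch_hyd_5",
    "pro_patch_neg", "pro_patch_neg_1", "pro_patch_neg_5", "pro_patch_neg_n",
    "pro_patch_pos", "pro_patch_pos_2", "pro_pl_seq",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic conformation table.

    ``informative`` lists 0-based feature indices that receive a class-mean
    shift of ``effect_size`` (in units of the within-class standard
    deviation).  ``ar_features`` lists the features given AR(1) frame-order
    correlation with coefficient ``ar_coeff``; by default the informative
    features themselves.  ``correlation`` adds an optional shared latent
    factor inducing pairwise feature correlation.  ``label_noise`` flips that
    fraction of labels (default 0: labels are exact).
    """

    name: str = "synthetic"
    n: int = 3000
    d: int = 50
    minority_count: int = 300
    informative: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect_size: float = 1.0
    ar_coeff: float = 0.8
    ar_features: tuple[int, ...] | None = None
    correlation: float = 0.0
    label_noise: float = 0.0
    seed: int = 0
    moe_names: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.minority_count < self.n:
            raise ValueError("minority_count must satisfy 0 < minority < n")
        if any(not 0 <= j < self.d for j in self.informative):
            raise ValueError("informative feature index out of range")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in [0, 1)")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")

    @property
    def ar_set(self) -> tuple[int, ...]:
        return self.informative if self.ar_features is None else self.ar_features


def _feature_names(spec: SyntheticSpec) -> list[str]:
    if not spec.moe_names:
        return [f"f{j:03d}" for j in range(spec.d)]
    names = list(_MOE_NAMES[: spec.d])
    names += [f"pro_desc_{j:03d}" for j in range(len(names), spec.d)]
    return names


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) series along frame order."""
    eps = rng.standard_normal(n)
    if phi == 0.0:
        return eps
    out = np.empty(n)
    out[0] = eps[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + scale * eps[t]
    return out


def generate_dataset(spec: SyntheticSpec) -> ConformationDataset:
    """Draw one dataset; bit-reproducible for a fixed spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    names = _feature_names(spec)

    # binding frames scattered over the trajectory, exact count
    labels = np.zeros(spec.n, dtype=np.int8)
    labels[rng.choice(spec.n, size=spec.minority_count, replace=False)] = 1

    # descriptor-like location/scale per feature (surface areas ~1e4 down to
    # unit-magnitude charges), fixed by the same seed
    log_scale = rng.uniform(0.0, 3.5, size=spec.d)
    scales = 10.0 ** log_scale
    locs = rng.uniform(-2.0, 2.0, size=spec.d) * scales

    ar_set = set(spec.ar_set)
    z = np.empty((spec.n, spec.d))
    for j in range(spec.d):
        phi = spec.ar_coeff if j in ar_set else 0.0
        z[:, j] = _ar1(rng, spec.n, phi)
    if spec.correlation > 0.0:
        shared = _ar1(rng, spec.n, spec.ar_coeff)
        w = np.sqrt(spec.correlation)
        z = w * shared[:, None] + np.sqrt(1.0 - spec.correlation) * z

    for j in spec.informative:
        z[:, j] = z[:, j] + spec.effect_size * labels

    if spec.label_noise > 0.0:
        flip = rng.random(spec.n) < spec.label_noise
        labels = np.where(flip, 1 - labels, labels).astype(np.int8)

    features = locs[None, :] + scales[None, :] * z
    return ConformationDataset(
        name=spec.name, features=features, feature_names=names, labels=labels
    )


# -- presets -----------------------------------------------------------------

#: Shapes of the four study datasets (exact row / minority / descriptor
#: counts) plus the planted-signal benchmark used by the end-to-end checks.
PRESETS: dict[str, SyntheticSpec] = {
    "ADORA2A": SyntheticSpec(name="ADORA2A", n=2998, d=50, minority_count=851),
    "ADRB2": SyntheticSpec(name="ADRB2", n=2565, d=51, minority_count=156),
    "OPRD1": SyntheticSpec(name="OPRD1", n=3004, d=51, minority_count=72),
    "OPRK1": SyntheticSpec(name="OPRK1", n=2998, d=50, minority_count=138),
    "PLANTED": SyntheticSpec(
        name="PLANTED", n=2000, d=50, minority_count=200, effect_size=2.0
    ),
}

_SUITE = ("ADORA2A", "ADRB2", "OPRD1", "OPRK1")


def preset(name: str, seed: int = 0, **overrides) -> SyntheticSpec:
    """Look up a preset spec, rebinding its seed (and any other field)."""
    try:
        base = PRESETS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(base, seed=seed, **overrides)


def generate_suite(output_dir, seed: int = 0) -> list[Path]:
    """Write the four study-shaped CSVs plus a JSON manifest; returns paths."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = {}
    for i, name in enumerate(_SUITE):
        spec = preset(name, seed=seed + i)
        ds = generate_dataset(spec)
        path = out / f"{name}.csv"
        write_dataset(ds, path)
        paths.append(path)
        manifest[name] = {
            "file": path.name,
            "seed": spec.seed,
            "n": spec.n,
            "d": spec.d,
            "minority_count": spec.minority_count,
            "informative": list(spec.informative),
            "effect_size": spec.effect_size,
            "ar_coeff": spec.ar_coeff,
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
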