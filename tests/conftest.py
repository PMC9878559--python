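import numpy as np
import pytest

from confsel.core_data import ConformationDataset


def make_dataset(n=60, d=4, seed=0, effect=0.0, informative=(), minority=None,
                 name="fixture"):
    """Small ad-hoc dataset: Gaussian features, optional planted mean shift."""
    rng = np.random.default_rng(seed)
    minority = minority if minority is not None else n // 3
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, minority, replace=False)] = 1
    X = rng.normal(size=(n, d))
    for j in informative:
        X[:, j] += effect * labels
    return ConformationDataset(
        name, X, [f"f{j}" for j in range(d)], labels
    )


@pytest.fixture
def tiny_ds():
    return make_dataset(n=40, d=3, seed=1)


@pytest.fixture
def separable_ds():
    """Linearly separable two-feature fixture."""
    rng = np.random.default_rng(2)
    y = np.repeat([0, 1], 100)
    X = rng.normal(size=(200, 2))
    X[:, 0] += 8.0 * y
    return ConformationDataset("sep", X, ["f0", "f1"], y)
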