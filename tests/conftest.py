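import numpy as np
import pytest

from signgrn.labeling import ExpressionDataset
from signgrn.synthetic import make_fixture


@pytest.fixture(scope="session")
def tiny_fixture():
    """3-gene cascade dataset, gold standard and simulation run."""
    return make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def small_fixture():
    return make_fixture("small", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def mixed_dataset(rng):
    """40 pseudo-series + 20 steady cells over 4 genes, hand-rolled."""
    n_pt, n_ss, n_genes = 40, 20, 4
    pt = np.linspace(0.0, 1.0, n_pt)
    values = rng.uniform(0.5, 2.0, size=(n_pt + n_ss, n_genes))
    # gene 0 rises along pseudotime so labels are non-trivial
    values[:n_pt, 0] = 0.5 + 2.0 * pt + rng.normal(0, 0.02, n_pt)
    pseudotime = np.concatenate([pt, np.full(n_ss, np.nan)])
    ids = [f"c{i}" for i in range(n_pt + n_ss)]
    return ExpressionDataset(values, [f"G{i+1}" for i in range(n_genes)],
                             ids, pseudotime)
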