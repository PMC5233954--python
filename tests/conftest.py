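import numpy as np
import pandas as pd
import pytest

from pathrewire.io import ExpressionMatrix


def make_expression(values, genes=None, samples=None, prefix="s"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"{prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def random_pair(n_genes=30, n=20, seed=0):
    """Same-distribution case/control pair (global null)."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    case = make_expression(rng.standard_normal((n_genes, n)), genes, prefix="c")
    ctrl = make_expression(rng.standard_normal((n_genes, n)), genes, prefix="k")
    return case, ctrl


@pytest.fixture
def tiny_pair():
    return random_pair(n_genes=12, n=10, seed=3)


@pytest.fixture(scope="session")
def planted():
    """Default end-to-end fixture: one rewired + regulated pathway among
    20 decoy gene sets (shared across tests; treat as read-only)."""
    from pathrewire.simulation import planted_scenario

    return planted_scenario(seed=101)


@pytest.fixture(scope="session")
def planted_fit(planted):
    from pathrewire.model import PathwayRewiringAnalysis

    case, ctrl, coll, grn, truth = planted
    return PathwayRewiringAnalysis(case, ctrl, coll, grn).fit()
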