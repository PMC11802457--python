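import numpy as np
import pytest
import scipy.sparse as sp

from nichetrack import scoring, synthetic
from nichetrack.datatypes import ExpressionMatrix


def make_matrix(counts, gene_ids=None, cell_ids=None, meta=None, lognorm=True):
    counts = np.asarray(counts)
    g, c = counts.shape
    m = ExpressionMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        cell_ids=cell_ids or [f"c{j}" for j in range(c)],
        counts=sp.csr_matrix(counts),
        cell_meta=meta,
    )
    if lognorm:
        scoring.log_normalize(m)
    return m


@pytest.fixture(scope="session")
def lineage_atlas():
    """One simulated lineage atlas shared by read-only tests."""
    m, truth = synthetic.simulate_lineage_atlas(seed=42)
    scoring.log_normalize(m)
    return m, truth


@pytest.fixture(scope="session")
def spot_sim():
    """One simulated hotspot-bearing spot grid shared by read-only tests."""
    grid, truth = synthetic.simulate_spot_grid(seed=42)
    expr = grid.as_expression()
    scoring.log_normalize(expr)
    grid.set_lognorm(expr.lognorm)
    return grid, truth


def block_genes(truth, block):
    return truth["genes"].loc[truth["genes"]["block"] == block, "gene_id"].tolist()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
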