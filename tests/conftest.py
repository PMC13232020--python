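import numpy as np
import pytest
import scipy.sparse as sp

from remitt.st_io import GenePanels, STDataset
from remitt.synthdata import SynthConfig, simulate_dataset


@pytest.fixture(scope="session")
def panels():
    return GenePanels()


@pytest.fixture(scope="session")
def sim():
    """One simulated slide with planted trails, shared across tests."""
    return simulate_dataset(SynthConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast slide for plumbing tests."""
    cfg = SynthConfig(rows=12, cols=12, n_trails=1, trail_length=6,
                      min_trail_span_um=450.0, rng_seed=7)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_dataset(counts, xy=None, gene_names=None, pitch_um=110.0):
    """Small helper to build an STDataset from a dense count array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    if xy is None:
        xy = np.column_stack([np.arange(n) * pitch_um, np.zeros(n)])
    if gene_names is None:
        gene_names = [f"G{j}" for j in range(g)]
    return STDataset(
        counts=sp.csr_matrix(counts),
        spot_ids=np.array([f"S{i}" for i in range(n)], dtype=object),
        xy=np.asarray(xy, dtype=float),
        gene_names=np.array(gene_names, dtype=object),
        pitch_um=pitch_um,
    )
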