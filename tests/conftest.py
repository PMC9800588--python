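import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from estrocycle import synthdata
from estrocycle.deg import ExpressionProfile, TrendVector


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_config():
    """A fast study configuration used across unit tests."""
    return synthdata.SimConfig(
        seed=11,
        n_genes=300,
        n_tissues=4,
        tas_library_size=20,
        n_tfs=10,
        targets_per_tf=8,
        net_nodes=120,
        net_edges=360,
        n_hubs=6,
    )


@pytest.fixture
def profile_pair(small_config):
    return synthdata.simulate_counts(small_config, tissue="aorta")


def make_profile(tissue, phase, counts, genes=None):
    genes = genes or [f"g{i:05d}" for i in range(len(counts))]
    counts = np.atleast_2d(np.asarray(counts))
    if counts.shape[0] != len(genes):
        counts = counts.T
    cols = [f"{tissue}_{phase}_rep{r + 1}" for r in range(counts.shape[1])]
    return ExpressionProfile(
        tissue=tissue, phase=phase, counts=pd.DataFrame(counts, index=genes, columns=cols)
    )


def make_trend(tissue, mapping):
    return TrendVector(tissue=tissue, trend=mapping)
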