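import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from dtapipe.quantify import CountMatrix
from dtapipe.synthetic import SimConfig, generate_experiment


@pytest.fixture
def small_counts() -> CountMatrix:
    """A tiny deterministic seven-library count matrix."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(50)]
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(50, 7)),
        index=pd.Index(genes, name="gene_id"),
        columns=["CK0", "CK1", "CK2", "CK3", "ETH1", "ETH2", "ETH3"],
    )
    lengths = pd.Series(rng.integers(200, 3000, size=50), index=counts.index)
    return CountMatrix(counts=counts, lengths=lengths)


@pytest.fixture(scope="session")
def default_run():
    """One default synthetic experiment shared by read-only tests."""
    config = SimConfig(seed=11)
    counts, truth = generate_experiment(config)
    return config, counts, truth
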