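import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from exitscape.synthetic import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """Down-scaled simulation for fast unit tests."""
    return SimulationConfig(
        seed=7, n_genes=200, n_signature_a=25, n_signature_b=15, n_clones=12
    )


@pytest.fixture
def comparison_worked() -> pd.DataFrame:
    """Three-gene worked example: one enriched each way, one in neither set."""
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "mean_a": [1000.0, 20.0, 100.0],
            "mean_b": [50.0, 400.0, 60.0],
        }
    )


def random_profile(rng: np.random.Generator, n_genes: int) -> pd.DataFrame:
    """Random perturbation profile with q-values, for oracle comparisons."""
    genes = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(
        {
            "gene_id": genes,
            "fold_change": np.exp(rng.normal(0, 1.2, n_genes)),
            "q_value": rng.random(n_genes),
        }
    )
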