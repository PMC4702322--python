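import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from countbench import (
    CountMatrix,
    SimulationConfig,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_study():
    """Compact synthetic study shared by read-only tests."""
    cfg = SimulationConfig(
        n_genes=400,
        n_intergenic=150,
        a=4,
        b=3,
        c=2,
        n_per_cell=4,
        duplicate_library_fraction=0.1,
        rng_seed=7,
    )
    return cfg, *simulate_experiment(cfg)


@pytest.fixture()
def toy_counts():
    """Tiny hand-checkable count matrix."""
    df = pd.DataFrame(
        {"s1": [2, 8, 0, 5], "s2": [8, 32, 0, 20]},
        index=["g1", "g2", "g3", "g4"],
    )
    return CountMatrix(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
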