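import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nicheomics.simulate import SimulationConfig, simulate_counts, simulate_secretome


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_genes=300,
        n_proteins=120,
        replicates_per_group=4,
        n_clusters=4,
        n_patterns=3,
        n_coherent_pairs=10,
        n_decoy_pairs=15,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    counts, meta, truth = simulate_counts(small_cfg)
    intens, sec_meta, lr, truth = simulate_secretome(small_cfg, truth)
    return {
        "counts": counts,
        "meta": meta,
        "truth": truth,
        "intensities": intens,
        "sec_meta": sec_meta,
        "lr": lr,
    }


@pytest.fixture
def two_group_counts(rng):
    """Null NB counts: two exchangeable groups of 5 samples, 200 genes."""
    mu = 10 ** rng.uniform(1, 3, 200)
    n_nb = 1 / 0.05
    y = np.column_stack(
        [rng.negative_binomial(n_nb, n_nb / (n_nb + mu)) for _ in range(10)]
    )
    counts = pd.DataFrame(
        y, index=[f"g{i}" for i in range(200)], columns=[f"s{j}" for j in range(10)]
    )
    meta = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "stromal_type": "T",
            "condition": ["A"] * 5 + ["B"] * 5,
            "replicate": list(range(1, 6)) * 2,
        }
    )
    return counts, meta
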