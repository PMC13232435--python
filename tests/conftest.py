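import numpy as np
import pandas as pd
import pytest

from ecokit import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared by read-only tests."""
    cfg = SimulationConfig(
        n_groups=2,
        n_samples_per_group=10,
        n_subclusters=9,
        k_ecotypes=3,
        cells_per_sample=200,
        embed_dim=8,
        n_genes=200,
        n_markers_per_subcluster=5,
        marker_log_fold=3.0,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_cells():
    """Hand-built cell table with a known contingency structure."""
    rows = []
    # group X: 30 cells of A, 10 of B; group Y: 10 of A, 30 of B
    layout = [("X", "A", 30), ("X", "B", 10), ("Y", "A", 10), ("Y", "B", 30)]
    i = 0
    for group, sub, n in layout:
        for _ in range(n):
            rows.append(
                {
                    "cell_id": f"c{i}",
                    "sample_id": f"s_{group}",
                    "group": group,
                    "lineage": "L1",
                    "subcluster": sub,
                    "is_denominator": True,
                }
            )
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
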