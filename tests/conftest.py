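import numpy as np
import pandas as pd
import pytest

import gbmdecon as gd


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic reference shared across tests."""
    config = gd.SimulationConfig(seed=11)
    counts, truth = gd.simulate_reference(config)
    return config, counts, truth


@pytest.fixture(scope="session")
def default_norm(default_sim):
    _, counts, _ = default_sim
    return gd.normalize_log_cpm(counts)


@pytest.fixture
def small_counts():
    """Tiny hand-checkable count matrix (4 genes x 3 cells)."""
    values = pd.DataFrame(
        {
            "c1": [3.0, 0.0, 7.0, 0.0],
            "c2": [1.0, 1.0, 0.0, 0.0],
            "c3": [0.0, 0.0, 0.0, 0.0],
        },
        index=["MT-ND1", "g2", "g3", "RPS1"],
    )
    return gd.ExpressionMatrix(values, scale="counts")


def random_expression(rng, n_genes, n_obs, scale="log"):
    X = np.abs(rng.normal(size=(n_genes, n_obs))) + 0.01
    return gd.ExpressionMatrix(
        pd.DataFrame(
            X,
            index=[f"g{i:04d}" for i in range(n_genes)],
            columns=[f"s{j:03d}" for j in range(n_obs)],
        ),
        scale=scale,
    )
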