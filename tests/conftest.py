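"""Shared fixtures: small deterministic tables and benchmark datasets."""

import numpy as np
import pandas as pd
import pytest

from omicspanel.tables import CohortMetadata, FeatureTable


@pytest.fixture
def tiny_count_table() -> FeatureTable:
    df = pd.DataFrame(
        [[2, 2, 4], [1, 0, 3], [5, 5, 0], [0, 3, 3]],
        index=[f"S{i}" for i in range(1, 5)],
        columns=["OTU1", "OTU2", "OTU3"],
    )
    return FeatureTable("microbiota", df, "count")


@pytest.fixture
def small_metadata() -> CohortMetadata:
    df = pd.DataFrame(
        {
            "group": ["CRC", "CRC", "control", "control"],
            "age": [65.0, 70.0, 68.0, 72.0],
            "sex": ["male", "female", "male", "female"],
            "bmi": [25.0, 27.0, 24.0, 26.0],
            "smoking": ["never", "stopped", "never", "active"],
        },
        index=pd.Index([f"S{i}" for i in range(1, 5)], name="sample_id"),
    )
    return CohortMetadata(df)


def planted_benchmark(seed: int, n_per_group: int = 30, p: int = 200,
                      k_planted: int = 5, effect: float = 1.5):
    """Two balanced groups, standardized features, the first ``k_planted``
    features shifted by ``effect`` SDs in the positive class."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    X = rng.normal(size=(n, p))
    y = np.r_[np.zeros(n_per_group), np.ones(n_per_group)]
    X[y == 1, :k_planted] += effect
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    return X, y


@pytest.fixture
def benchmark_xy():
    return planted_benchmark(seed=0)
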