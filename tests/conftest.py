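import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cardiospm as c

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture()
def small_matrix() -> c.ExpressionMatrix:
    """5 genes x 6 samples, log2 scale, two samples per region."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.uniform(0, 10, size=(5, 6)),
        index=[f"G{i}" for i in range(5)],
        columns=[f"S{j}" for j in range(6)],
    )
    return c.ExpressionMatrix(values, "log2")


@pytest.fixture()
def small_design() -> c.RegionDesign:
    assignments = pd.Series(
        ["LA", "LA", "V", "V", "SA", "SA"], index=[f"S{j}" for j in range(6)]
    )
    return c.RegionDesign(assignments)


@pytest.fixture(scope="session")
def tiny_dataset() -> c.SyntheticDataset:
    """One small synthetic dataset shared by read-only tests."""
    return c.generate_dataset(c.SyntheticConfig(n_genes=600, seed=42))
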