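import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import wsea

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def globo():
    """The 14-gene glycosphingolipid (globo series) worked example."""
    stats, gene_set = wsea.table5_fixture()
    return stats, gene_set


@pytest.fixture()
def small_stats():
    """A 6-gene array with a mix of fold changes and p-values."""
    return pd.DataFrame(
        {
            "fold_change": [2.0, 0.5, 1.0, 4.0, 1.0, 8.0],
            "p_value": [0.005, 0.02, 0.9, 0.001, 0.5, 0.05],
        },
        index=[f"g{i}" for i in range(6)],
    ).assign(is_significant=lambda d: d.p_value < 0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)
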