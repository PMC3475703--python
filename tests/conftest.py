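import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from torpormir import ArrayConfig, ExpressionMatrix, generate_array

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_array():
    """1,000-probe synthetic array with two planted families (seed 7)."""
    cfg = ArrayConfig(
        n_probes=1000,
        noise_floor=50.0,
        planted_families=(("miR-200", -3.0), ("miR-182", 2.0)),
        seed=7,
    )
    return generate_array(cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-built 4-probe, 2v2 matrix for exact arithmetic checks."""
    values = pd.DataFrame(
        {
            "ACR_1": [100.0, 1.0, 60.0, 50.0],
            "ACR_2": [100.0, 3.0, 60.0, 50.0],
            "LH_1": [400.0, 2.0, 60.0, 50.0],
            "LH_2": [400.0, 2.0, 60.0, 50.0],
        },
        index=pd.Index(
            ["hsa-miR-1", "hsa-miR-2", "hsa-miR-3", "hsa-miR-4"], name="probe_id"
        ),
    )
    groups = pd.Series(
        ["ACR", "ACR", "LH", "LH"],
        index=["ACR_1", "ACR_2", "LH_1", "LH_2"],
        name="group",
    )
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
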