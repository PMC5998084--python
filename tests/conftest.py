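import numpy as np
import pytest

from grassnpp import SyntheticConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """Small intercept-only panel with known components, no missingness."""
    cfg = SyntheticConfig(
        n_counties=6, watersheds_per_county=12, random_slopes=False,
        fixed_effects={"intercept": 5.0, "T": 0.0, "T2": 0.001},
        sigma2_resid=0.25,
        tau_watershed=[[1.0]], tau_county=[[0.8]],
        missing_rate=0.0, seed=11,
    )
    panel, truth = generate_panel(cfg)
    return panel, truth, cfg


@pytest.fixture(scope="session")
def covariate_panel():
    """Panel with the full covariate set and default generative effects."""
    cfg = SyntheticConfig(
        n_counties=8, watersheds_per_county=15, random_slopes=False,
        sigma2_resid=0.16,
        tau_watershed=[[0.5]], tau_county=[[0.4]],
        missing_rate=0.0, seed=23,
    )
    panel, truth = generate_panel(cfg)
    return panel, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
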