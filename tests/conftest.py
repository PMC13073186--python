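import numpy as np
import pandas as pd
import pytest

from foodcarbon.synthetic import SyntheticConfig, generate_panel, generate_recall_records


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Small default-condition panel: 300 households x 4 waves."""
    return SyntheticConfig(n_households=300, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config) -> pd.DataFrame:
    return generate_panel(small_config)


@pytest.fixture(scope="session")
def small_recall(small_config, small_panel) -> pd.DataFrame:
    return generate_recall_records(small_config, small_panel)


@pytest.fixture(scope="session")
def clean_config() -> SyntheticConfig:
    """Low-noise threshold DGP for recovery-style checks."""
    return SyntheticConfig(
        n_households=400,
        true_gamma=6.5,
        sigma_eps=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_panel(clean_config) -> pd.DataFrame:
    return generate_panel(clean_config)


@pytest.fixture()
def toy_panel() -> pd.DataFrame:
    """Tiny deterministic two-wave panel for pencil-and-paper checks."""
    rng = np.random.default_rng(123)
    nh, T = 40, 2
    hh = np.repeat(np.arange(nh), T)
    wave = np.tile([2004, 2006], nh)
    hhinc = rng.uniform(0.5, 10.0, nh * T)
    x = rng.normal(size=nh * T)
    mu = rng.normal(size=nh)
    ghg = 0.3 * hhinc + 0.5 * x + mu[hh] + rng.normal(0, 0.2, nh * T)
    return pd.DataFrame(
        {
            "household_id": hh,
            "province_id": hh % 5,
            "wave": wave,
            "hhinc": hhinc,
            "x": x,
            "ghg": ghg,
        }
    )
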