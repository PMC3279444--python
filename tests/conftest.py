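import numpy as np
import pandas as pd
import pytest

from walkrisk.config import MonteCarloScheme, RunConfig, SyntheticCityConfig
from walkrisk.pipeline import run_pipeline
from walkrisk.synthetic_city import generate_city, generate_participants, generate_pollution_daily


@pytest.fixture(scope="session")
def small_city_config():
    return SyntheticCityConfig(
        extent_km=12.0,
        n_participants=500,
        n_monitors_per_pollutant=25,
        tract_grid_size=6,
        parcel_grid_per_tract=4,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_city(small_city_config):
    return generate_city(small_city_config)


@pytest.fixture(scope="session")
def small_cohort(small_city, small_city_config):
    return generate_participants(small_city, small_city_config)


@pytest.fixture(scope="session")
def small_monitors(small_city, small_city_config):
    return generate_pollution_daily(small_city, small_city_config)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One mid-sized end-to-end pipeline run shared across tests."""
    cfg = RunConfig(
        synthetic_city=SyntheticCityConfig(n_participants=2000, seed=7),
        monte_carlo=MonteCarloScheme(n_reps=10, seed=7),
        seed=7,
    )
    outdir = tmp_path_factory.mktemp("demo_run")
    return cfg, run_pipeline(cfg, outdir)


def make_tier_cohort(n: int, shares=(0.835, 0.056, 0.109), rng=None) -> pd.DataFrame:
    """Weekly-activity table with tiers drawn at the given (inactive,
    insufficient, active) proportions."""
    rng = rng or np.random.default_rng(0)
    tier = rng.choice(3, size=n, p=shares)
    total = np.where(tier == 0, 0.0, np.where(tier == 1, rng.uniform(1, 150, n), rng.uniform(151, 600, n)))
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "transport": total * 0.3,
            "recreation": total * 0.7,
            "total": total,
            "tier": np.array(["inactive", "insufficient", "active"])[tier],
        }
    )
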