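import warnings

import numpy as np
import pandas as pd
import pytest

import cpuecal as cc

warnings.filterwarnings("ignore", message=".*converge.*")


@pytest.fixture(scope="session")
def paper_config():
    return cc.paper_like_config(seed=11)


@pytest.fixture(scope="session")
def dataset(paper_config):
    return cc.simulate_dataset(paper_config)


@pytest.fixture(scope="session")
def census_truth(dataset, paper_config):
    return cc.census_panel(
        dataset.captures,
        dataset.growth_rates,
        removals=dataset.removals,
        censor_month=paper_config.months[-1],
        months=paper_config.months,
    )


@pytest.fixture(scope="session")
def panel(census_truth, dataset):
    return cc.build_panel(census_truth, dataset.captures, dataset.effort)


@pytest.fixture()
def small_config():
    return cc.SimConfig(
        n_months=18,
        initial_abundance=60,
        monthly_survival=0.95,
        monthly_birth_rate=0.01,
        seed=5,
    )


def static_population(n, svl=600.0, growth=1.0, config=None, sex="F"):
    """n individuals alive for the whole horizon with fixed growth."""
    config = config or cc.SimConfig()
    return [
        cc.Individual(
            id=i + 1, sex=sex, birth_month=-1,
            birth_day=-int(round((svl - 350.0) / growth)),
            birth_svl=350.0, growth_rate=growth,
        )
        for i in range(n)
    ]


@pytest.fixture()
def quad_panel():
    """Panel drawn from a known quadratic log-link density-CPUE relationship."""
    rng = np.random.default_rng(42)
    c = rng.uniform(0.01, 0.93, 40)
    mu = 5.0 * np.exp(2.45 + 3.58 * c - 0.82 * c**2)
    y = rng.poisson(mu)
    return pd.DataFrame(
        {
            "month": pd.period_range("2016-10", periods=40, freq="M"),
            "N_total": y,
            "cpue_visual": c,
            "density": y / 5.0,
        }
    )
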