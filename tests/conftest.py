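import numpy as np
import pandas as pd
import pytest

import buvspatial as bv


def make_obs(rows):
    """Build a survey obs frame from (site_id, e, n, season, status, depth,
    vis, rock, kelp, sand, coffee, presence) tuples."""
    return pd.DataFrame(rows, columns=list(bv.CSV_COLUMNS))


@pytest.fixture
def tiny_obs():
    return make_obs([
        ("A", 0.0, 0.0, "winter", "open", 10.0, 5.0, 1, 0, 0, 0, 1),
        ("A", 0.0, 0.0, "summer", "open", 10.0, 7.0, 1, 0, 0, 0, 0),
        ("B", 100.0, 50.0, "winter", "green_old", 20.0, 6.0, 0, 1, 1, 0, 1),
        ("B", 100.0, 50.0, "summer", "green_new", 20.0, 4.0, 0, 1, 1, 0, 0),
        ("C", 500.0, 20.0, "winter", "open", 30.0, 8.0, 0, 0, 1, 1, 1),
        ("C", 500.0, 20.0, "summer", "open", 30.0, 9.0, 0, 0, 1, 1, 0),
    ])


@pytest.fixture
def tiny_dataset(tiny_obs):
    return bv.SurveyDataset(tiny_obs)


@pytest.fixture(scope="session")
def small_config():
    """A fast small survey: 4 clusters x 15 sites in a 12 km band."""
    return bv.SimulationConfig(
        n_clusters=4, sites_per_cluster=15, band_length=12_000.0,
        band_width=2_000.0, cluster_spread=400.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_survey(small_config):
    data, truth = bv.simulate_survey(small_config)
    return data, truth


@pytest.fixture(scope="session")
def small_fits(small_survey):
    """One non-spatial and one spatial fit on the small survey, reused
    across read-only tests."""
    data, _ = small_survey
    priors = bv.PriorSpec()
    ns = bv.fit_model(data, priors, bv.FitConfig(
        spatial=False, n_retained=600, burn_in=200, seed=5))
    sp = bv.fit_model(data, priors, bv.FitConfig(
        spatial=True, n_retained=600, burn_in=300, thin=2, seed=5))
    return {"nonspatial": ns, "spatial": sp}
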