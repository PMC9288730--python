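import numpy as np
import pytest

import asbdemand as ad


@pytest.fixture(scope="session")
def small_config():
    """Fast, fully consistent 4-good config: everyone purchases everything,
    so both equations hold for every household and truth is well-defined."""
    return ad.default_config(seed=42).with_(
        n_clusters=150, households_per_cluster=6,
        prevalence_by_tertile=np.ones((4, 3)))


@pytest.fixture(scope="session")
def small_survey(small_config):
    return ad.generate_households(small_config)


@pytest.fixture(scope="session")
def small_prepared(small_survey):
    df, _ = small_survey
    return ad.filter_for_estimation(ad.compute_shares_unitvalues(df))


@pytest.fixture(scope="session")
def one_good_config():
    """Single-good config with no covariate effects and modest noise."""
    return ad.config_from_elasticities(
        np.array([[-0.94]]), mean_share=[0.02], beta0=[-0.003], beta1=[0.05],
        goods=("ASB",),
        n_clusters=400, households_per_cluster=8, seed=7,
        gamma0=np.zeros((1, 3)), gamma1=np.zeros((1, 3)),
        prevalence_by_tertile=np.ones((1, 3)))
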