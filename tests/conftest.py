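import numpy as np
import pytest

import perlife as pl
from perlife.config import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Small bundled datasets: 204-record cohort, 3-stratum design, toy table."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def cohort():
    """Session cohort (~20k records) simulated from the reference mechanism."""
    design = pl.DesignSpec(
        n_strata=8, psus_per_stratum=2, participants_per_psu=1250, seed=11
    )
    return pl.simulate_cohort(design)


@pytest.fixture(scope="session")
def features(cohort):
    return pl.build_features(cohort)


@pytest.fixture(scope="session")
def life_table():
    return pl.simulate_life_table()


@pytest.fixture(scope="session")
def baseline_profile(cohort, features, life_table):
    raw = pl.weighted_age_profiles(cohort, features)
    return pl.smooth_profiles(raw, ages=np.arange(20, life_table.omega("male") + 1))


@pytest.fixture(scope="session")
def reference_model():
    return pl.FittedMortalityModel.reference()


@pytest.fixture(scope="session")
def trajectory_model(cohort):
    return pl.fit_trajectories(cohort)


@pytest.fixture(scope="session")
def disease_params():
    return pl.DiseaseRiskParams.default()
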