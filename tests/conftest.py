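import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pollengap as pg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_config() -> pg.StudyConfig:
    """Full-scale study configuration on the synthetic fixture."""
    return pg.StudyConfig(synth_seed=STUDY_SEED, master_seed=STUDY_SEED)


@pytest.fixture(scope="session")
def full_study(study_config) -> pg.StudyResult:
    """One full synthetic simulation study, shared across tests."""
    return pg.run_study(study_config)


@pytest.fixture
def flat_series() -> pg.PollenSeries:
    dates = pd.date_range("2022-01-01", "2022-12-31", freq="D")
    return pg.PollenSeries("S1", "Alnus", dates, np.ones(len(dates)))


def make_series(values, start="2022-03-01", station="S1", taxon="Alnus"):
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return pg.PollenSeries(station, taxon, dates, values)
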