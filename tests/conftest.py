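import numpy as np
import pytest

from stresspipe.modeling import build_datasets
from stresspipe.pipeline import extract_session_records
from stresspipe.synthetic_data import SimParams, StudyDesign, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared by read-only tests."""
    return simulate_study(StudyDesign(), seed=20)


@pytest.fixture(scope="session")
def default_records(default_study):
    return extract_session_records(default_study)


@pytest.fixture(scope="session")
def default_datasets(default_records):
    return build_datasets(default_records)


@pytest.fixture(scope="session")
def noiseless_study():
    """Strong stress effects, zero label noise, no artifacts."""
    params = SimParams(
        selfreport_flip_p_lab=0.0,
        selfreport_flip_p_daily=0.0,
        artifact_rate_rr=0.0,
        artifact_rate_eda=0.0,
    )
    return simulate_study(StudyDesign(params=params), seed=7)


@pytest.fixture(scope="session")
def noiseless_datasets(noiseless_study):
    return build_datasets(extract_session_records(noiseless_study))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
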