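import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import toemorph as tm
from toemorph.pipeline import prepare_configurations

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scheme():
    return tm.default_scheme()


@pytest.fixture(scope="session")
def template_config(scheme):
    return tm.build_template(tm.ToeTemplateParams(), scheme)


@pytest.fixture(scope="session")
def calib_sample(scheme):
    """Moderate paper-calibrated synthetic sample shared across tests."""
    spec = tm.PopulationSpec.paper_calibrated(n_total=120, seed=11)
    return tm.sample_population(spec, scheme)


@pytest.fixture(scope="session")
def calib_configs(calib_sample, scheme):
    return prepare_configurations(calib_sample.to_dataset(), scheme)


@pytest.fixture(scope="session")
def calib_aligned(calib_configs, scheme):
    return tm.gpa_align(calib_configs, scheme, slide=True)


@pytest.fixture(scope="session")
def calib_meta(calib_sample):
    return calib_sample.metadata.reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
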