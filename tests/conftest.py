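import numpy as np
import pytest

from grstrial.snp_score import SnpWeight, load_default_weight_table
from grstrial.synthetic_data import (
    ReferenceSimConfig,
    TrialSimConfig,
    make_fixture_suite,
    simulate_reference_cohort,
    simulate_trial,
)


@pytest.fixture(scope="session")
def default_weights():
    return load_default_weight_table()


@pytest.fixture(scope="session")
def small_weights():
    return [
        SnpWeight("rs1", "A", "G", 0.1),
        SnpWeight("rs2", "C", "T", 0.2),
        SnpWeight("rs3", "G", "T", 0.3),
    ]


@pytest.fixture(scope="session")
def reference_cohort():
    return simulate_reference_cohort(ReferenceSimConfig(n=2000), seed=42)


@pytest.fixture(scope="session")
def reference(reference_cohort):
    return reference_cohort.reference


@pytest.fixture(scope="session")
def default_trial(reference):
    return simulate_trial(TrialSimConfig(), ref=reference, seed=7)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    make_fixture_suite(out, seed=5)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
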