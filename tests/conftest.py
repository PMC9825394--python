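import numpy as np
import pytest

from ipitune.reference import load_reference_params, reference_average
from ipitune.synthetic import load_default_profiles
from ipitune.tuning import TuningParams


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_params()


@pytest.fixture(scope="session")
def profiles():
    species, behavior, stimulus = load_default_profiles()
    return species


@pytest.fixture(scope="session")
def behavior_profile():
    _, behavior, _ = load_default_profiles()
    return behavior


@pytest.fixture(scope="session")
def mel_average_params():
    row = reference_average("melanogaster")
    return TuningParams(row.a, row.tau_b, row.c, row.tau_d)


@pytest.fixture(scope="session")
def sim_average_params():
    row = reference_average("simulans")
    return TuningParams(row.a, row.tau_b, row.c, row.tau_d)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
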