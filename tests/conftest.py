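import numpy as np
import pytest

from tcnmm import DriveSpec, ModelParameters, generate_fixtures, simulate


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def constant_drive():
    return DriveSpec()


@pytest.fixture(scope="session")
def default_run(params, constant_drive):
    """One 60 s constant-input run of the default (resting) circuit."""
    return simulate(params, constant_drive)


@pytest.fixture(scope="session")
def fixture_bundle():
    return generate_fixtures(seed=1234)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
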