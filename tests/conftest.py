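import numpy as np
import pytest

from cifes import patient


@pytest.fixture(scope="session")
def fd_profile():
    return patient.make_profile("foot_drop")


@pytest.fixture(scope="session")
def healthy_profile():
    return patient.make_profile("healthy")


@pytest.fixture(scope="session")
def fd_recording(fd_profile):
    """A 30-step foot-drop recording with sEMG, shared across read-only tests."""
    rec = patient.generate_gait(fd_profile, 30, 1000.0, seed=11)
    return patient.generate_semg(fd_profile, rec, seed=12)


@pytest.fixture(scope="session")
def healthy_recording(healthy_profile):
    rec = patient.generate_gait(healthy_profile, 30, 1000.0, seed=21)
    return patient.generate_semg(healthy_profile, rec, seed=22)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
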