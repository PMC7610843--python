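import numpy as np
import pytest

from hetsim import GroupSpec, TraitSpec

CHIMP_NEOPHOBIA = TraitSpec("neophobia", beta0=800, sigma_L=100, sigma_S=100, sigma_e=50)
CHIMP_SELF_CONTROL = TraitSpec("self_control", beta0=80, sigma_L=10, sigma_S=10, sigma_e=5)
BONOBO_NEOPHOBIA = TraitSpec("neophobia", beta0=950, sigma_L=100, sigma_S=100, sigma_e=50)


@pytest.fixture(scope="session")
def chimp_group() -> GroupSpec:
    return GroupSpec("chimpanzee", [CHIMP_NEOPHOBIA, CHIMP_SELF_CONTROL])


@pytest.fixture(scope="session")
def bonobo_group() -> GroupSpec:
    return GroupSpec("bonobo", [BONOBO_NEOPHOBIA, CHIMP_SELF_CONTROL])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
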