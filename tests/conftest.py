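import numpy as np
import pytest
from hypothesis import settings

from costrain import EpidemicParameters, neutral_equilibrium

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def params_r0_2():
    """beta=2, gamma+r=1 so m=1, R0=2 — the worked-example regime."""
    return EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=2)


@pytest.fixture
def eq_r0_2(params_r0_2):
    """Neutral equilibrium at R0=2, k=1: S*=T*=0.5, I*=D*=0.25, mu=1."""
    return neutral_equilibrium(params_r0_2, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
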