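import numpy as np
import pytest

from monofilm.isotherms import Isotherm


@pytest.fixture
def kink_isotherm():
    """Factory for two-segment compression branches with a planted slope
    break (collapse-like kink) at a chosen pressure."""

    def make(pi_k, s1=2.0, s2=0.4, a0=50.0, step=0.1, a_min=20.0, sigma=0.0, seed=0):
        area = np.arange(a0, a_min, -step)
        a_k = a0 - pi_k / s1
        pi = np.where(area >= a_k, s1 * (a0 - area), pi_k + s2 * (a_k - area))
        if sigma:
            pi = pi + np.random.default_rng(seed).normal(0, sigma, pi.shape)
        return Isotherm(area, pi)

    return make
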