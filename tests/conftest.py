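import numpy as np
import pytest

import rkleap as rk


@pytest.fixture
def iso_sym():
    """Symmetric isomerisation: k1 = k2 = 10, T = 200, X0 = (100, 100)."""
    return rk.isomerisation_network(rk.IsomerisationSpec(k1=10, k2=10, T=200, X0=(100, 100)))


@pytest.fixture
def iso_spec_sym():
    return rk.IsomerisationSpec(k1=10, k2=10, T=200, X0=(100, 100))


@pytest.fixture
def schlogl():
    return rk.schlogl_network(rk.SCHLOGL_BISTABLE)


@pytest.fixture
def poisson_tab():
    return rk.get_tableau("poisson")


@pytest.fixture
def midpoint_tab():
    return rk.get_tableau("gillespie-midpoint")


class CountingNetwork:
    """Delegating wrapper that counts propensity and drift evaluations."""

    def __init__(self, net):
        self._net = net
        self.propensity_calls = 0
        self.drift_calls = 0

    def __getattr__(self, name):
        return getattr(self._net, name)

    def propensities(self, x):
        self.propensity_calls += 1
        return self._net.propensities(x)

    def drift(self, x):
        self.drift_calls += 1
        return self._net.drift(x)


class CountingRNG:
    """Delegating RNG wrapper that records poisson() calls and draw counts."""

    def __init__(self, seed):
        self._rng = np.random.default_rng(seed)
        self.poisson_calls = 0
        self.poisson_draws = 0

    def __getattr__(self, name):
        return getattr(self._rng, name)

    def poisson(self, lam, *args, **kwargs):
        self.poisson_calls += 1
        out = self._rng.poisson(lam, *args, **kwargs)
        self.poisson_draws += np.size(out)
        return out


@pytest.fixture
def counting_network():
    return CountingNetwork


@pytest.fixture
def counting_rng():
    return CountingRNG
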