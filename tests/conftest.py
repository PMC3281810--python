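import numpy as np
import pytest

from cscgrowth import (
    REFERENCE_PHI,
    PopulationState,
    RateConstants,
    asymptotic_fractions,
    phi_to_rates,
    reference_composition,
)


@pytest.fixture(scope="session")
def ref_phi():
    return REFERENCE_PHI


@pytest.fixture(scope="session")
def ref_k():
    return phi_to_rates(REFERENCE_PHI)


@pytest.fixture(scope="session")
def ref_fractions(ref_k):
    """Balanced-growth composition of the reference scenario."""
    res = asymptotic_fractions(ref_k)
    assert res.ok
    return res.fractions


@pytest.fixture
def ref_init():
    """Unit-total initial state on the reference balanced-growth composition."""
    return reference_composition()


def random_nondegenerate_rates(rng, gap=1e-3, hi=3.0):
    """A random nonnegative rate set whose three exponents are pairwise
    separated by more than ``gap`` (rejection sampling)."""
    while True:
        k = RateConstants.from_array(rng.uniform(0.0, hi, 8))
        lam = np.sort(k.exponents)
        if np.min(np.diff(lam)) > gap:
            return k


def random_state(rng, lo=0.0, hi=10.0):
    return PopulationState(0.0, *rng.uniform(lo, hi, 3))
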