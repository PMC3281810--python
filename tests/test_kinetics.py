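"""Core model: rate laws, closed-form solution, asymptotic composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cscgrowth import (
    CELL_VOLUME_MM3,
    REFERENCE_PHI,
    DegenerateSpectrumError,
    KineticsError,
    PhiVector,
    PopulationState,
    RateConstants,
    Trajectory,
    analytic_solution,
    asymptotic_fractions,
    ode_rhs,
    phi_to_rates,
    rates_to_phi,
    reaction_rates,
    simulate,
    total_cells,
    tumor_volume,
)

from conftest import random_nondegenerate_rates, random_state

# Species-change stoichiometry of the eight reactions (rows CSC, P, D):
# R1 net +1 CSC; R2 +1 P; R3 -1 CSC +2 P; R4 +1 P; R5 -1 P +2 D;
# R6/R7/R8 remove one CSC/P/D.
STOICHIOMETRY = np.array(
    [
        [1, 0, -1, 0, 0, -1, 0, 0],
        [0, 1, 2, 1, -1, 0, -1, 0],
        [0, 0, 0, 0, 2, 0, 0, -1],
    ]
)


# ---------------------------------------------------------------------------
# Ratio-vector expansion
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "phi, k1_scale, expected",
    [
        # the reference scenario expands to the published rate set
        ([1.0, 0.01, 5.35, 0.8, 0.01, 0.1, 1.0], 1.0, (1, 1.0, 0.01, 5.35, 4.28, 0.01, 0.1, 1.0)),
        ([0, 0, 0, 0, 0, 0, 0], 1.0, (1, 0, 0, 0, 0, 0, 0, 0)),
        # k5 is ratioed to k4, so phi54 * phi41 * k1 = 0.8 * 5.35 = 4.28
        ([1.5, 0.005, 5.35, 0.8, 0.01, 0.1, 1.0], 1.0, (1, 1.5, 0.005, 5.35, 4.28, 0.01, 0.1, 1.0)),
        ([1.0, 0.01, 5.35, 0.8, 0.01, 0.1, 1.0], 2.0, (2, 2.0, 0.02, 10.7, 8.56, 0.02, 0.2, 2.0)),
    ],
)
def test_phi_to_rates(phi, k1_scale, expected):
    k = phi_to_rates(PhiVector.from_array(phi, k1_scale=k1_scale))
    np.testing.assert_allclose(k.as_array(), expected, rtol=1e-14)


ratio_values = st.one_of(st.just(0.0), st.floats(1e-6, 50.0))


@given(
    ratios=st.lists(ratio_values, min_size=7, max_size=7),
    k1=st.floats(1e-3, 1e3),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_phi_roundtrip_identity(ratios, k1):
    """phi -> rates -> phi is the identity whenever k1 and k4 are nonzero."""
    phi = PhiVector.from_array(ratios, k1_scale=k1)
    if phi.phi41 == 0 and phi.phi54 > 0:
        phi = phi.replace(phi54=0.0)
    back = rates_to_phi(phi_to_rates(phi))
    np.testing.assert_allclose(back.as_array(), phi.as_array(), rtol=1e-12, atol=0)
    assert back.k1_scale == pytest.approx(phi.k1_scale, rel=1e-14)


@pytest.mark.parametrize(
    "bad",
    [
        dict(phi21=-0.1),
        dict(k1_scale=0.0),
        dict(k1_scale=-1.0),
        dict(phi81=float("nan")),
    ],
)
def test_invalid_phi_rejected(bad):
    base = {n: 0.5 for n in ("phi21", "phi31", "phi41", "phi54", "phi61", "phi71", "phi81")}
    base["k1_scale"] = 1.0
    base.update(bad)
    with pytest.raises(KineticsError):
        PhiVector(**base)


def test_negative_rate_rejected():
    with pytest.raises(KineticsError):
        RateConstants(1, 1, 0.01, 5.35, -4.28, 0.01, 0.1, 1)


# ---------------------------------------------------------------------------
# Rate laws and right-hand side
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "state, expected",
    [
        ((1, 0, 0), [1, 1, 0.01, 0, 0, 0.01, 0, 0]),
        ((0, 0, 0), [0] * 8),
        ((0, 10, 0), [0, 0, 0, 53.5, 42.8, 0, 1.0, 0]),
    ],
)
def test_reaction_rates(ref_k, state, expected):
    r = reaction_rates(PopulationState(0.0, *state), ref_k)
    np.testing.assert_allclose(r, expected, rtol=1e-14)


@pytest.mark.parametrize(
    "state, expected",
    [
        ((1, 0, 0), (0.98, 1.02, 0.0)),
        ((0, 0, 0), (0.0, 0.0, 0.0)),
        ((0, 1, 0), (0.0, 0.97, 8.56)),
    ],
)
def test_ode_rhs(ref_k, state, expected):
    np.testing.assert_allclose(ode_rhs(PopulationState(0.0, *state), ref_k), expected, rtol=1e-13, atol=1e-15)


def test_rhs_is_stoichiometry_times_rates():
    """The mass balances must equal S @ r for the reaction network's
    species-change stoichiometry — an independent derivation of the rhs."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        k = RateConstants.from_array(rng.uniform(0, 3, 8))
        s = random_state(rng)
        np.testing.assert_allclose(
            ode_rhs(s, k), STOICHIOMETRY @ reaction_rates(s, k), rtol=1e-12, atol=1e-12
        )


def test_total_growth_is_sum_of_components():
    """dN/dt equals the sum of the three compartment balances."""
    rng = np.random.default_rng(3)
    k = random_nondegenerate_rates(rng)
    s = random_state(rng)
    assert sum(ode_rhs(s, k)) == pytest.approx(np.sum(STOICHIOMETRY @ reaction_rates(s, k)))


# ---------------------------------------------------------------------------
# Closed-form solution vs the numeric oracle
# ---------------------------------------------------------------------------


def max_mixed_error(traj_a: Trajectory, traj_n: Trajectory, atol_frac: float = 1e-12) -> float:
    """Worst relative error of analytic vs numeric, after discounting an
    absolute floor at the numeric oracle's own resolution (1e-12 of the
    largest value): components that have decayed below that floor carry no
    information in the oracle."""
    ya = np.vstack([traj_a.csc, traj_a.p, traj_a.d])
    yn = np.vstack([traj_n.csc, traj_n.p, traj_n.d])
    atol = atol_frac * np.abs(yn).max()
    excess = np.clip(np.abs(ya - yn) - atol, 0.0, None)
    return float(np.max(excess / np.maximum(np.abs(yn), atol)))


def test_analytic_matches_numeric_oracle():
    rng = np.random.default_rng(2024)
    grid = np.linspace(0.0, 30.0, 61)
    worst = 0.0
    for _ in range(25):
        k = random_nondegenerate_rates(rng)
        init = random_state(rng, lo=0.1)
        ta = simulate(k, init, grid, method="analytic")
        tn = simulate(k, init, grid, method="numeric")
        worst = max(worst, max_mixed_error(ta, tn))
    assert worst < 1e-6


def test_analytic_reproduces_initial_state_exactly():
    rng = np.random.default_rng(5)
    for _ in range(10):
        k = random_nondegenerate_rates(rng)
        init = random_state(rng)
        sol = analytic_solution(k, init)
        np.testing.assert_allclose(sol.evaluate(0.0)[:, 0], init.as_array(), rtol=1e-13, atol=1e-13)


def test_decoupled_pure_growth():
    """With only symmetric CSC renewal active, CSC grows as e^t while P and
    D stay frozen (b = -k8 = 0 coincide, so this exercises the numeric
    fallback)."""
    k = RateConstants(1, 0, 0, 0, 0, 0, 0, 0)
    init = PopulationState(0.0, 1.0, 5.0, 7.0)
    t = np.array([0.0, 0.5, 1.0, 2.0])
    traj = simulate(k, init, t)
    assert traj.provenance == "numeric"
    np.testing.assert_allclose(traj.csc, np.exp(t), rtol=1e-8)
    np.testing.assert_allclose(traj.p, 5.0, rtol=1e-8)
    np.testing.assert_allclose(traj.d, 7.0, rtol=1e-8)


def test_homogeneity(ref_k):
    """Linearity: scaling the initial state scales the trajectory and
    leaves fractions invariant."""
    grid = np.linspace(0.0, 20.0, 11)
    t1 = simulate(ref_k, PopulationState(0.0, 1.0, 0.0, 0.0), grid)
    t1000 = simulate(ref_k, PopulationState(0.0, 1000.0, 0.0, 0.0), grid)
    for name in ("csc", "p", "d"):
        np.testing.assert_allclose(getattr(t1000, name), 1000.0 * getattr(t1, name), rtol=1e-12)
    np.testing.assert_allclose(t1000.csc / t1000.n, t1.csc / t1.n, rtol=1e-12)


def test_nonnegativity():
    rng = np.random.default_rng(11)
    grid = np.linspace(0.0, 30.0, 31)
    for _ in range(20):
        k = random_nondegenerate_rates(rng)
        traj = simulate(k, random_state(rng), grid)
        assert np.all(traj.csc >= 0) and np.all(traj.p >= 0) and np.all(traj.d >= 0)


def test_zero_rates_constant_trajectory():
    k = RateConstants(0, 0, 0, 0, 0, 0, 0, 0)
    traj = simulate(k, PopulationState(0.0, 2.0, 3.0, 4.0), [0.0, 1.0, 5.0], method="numeric")
    np.testing.assert_allclose(traj.csc, 2.0)
    np.testing.assert_allclose(traj.p, 3.0)
    np.testing.assert_allclose(traj.d, 4.0)


def test_invalid_grid_rejected(ref_k):
    init = PopulationState(0.0, 1.0, 0.0, 0.0)
    with pytest.raises(KineticsError):
        simulate(ref_k, init, [1.0, 0.5])
    with pytest.raises(KineticsError):
        simulate(ref_k, init, [-1.0, 2.0])
    with pytest.raises(KineticsError):
        simulate(ref_k, init, [])


# ---------------------------------------------------------------------------
# Degenerate spectra
# ---------------------------------------------------------------------------


def test_degenerate_spectrum_raises_and_falls_back():
    # a = 1 - 0.01 - 0.01 = 0.98 and b = 1.08 - 0 - 0.1 = 0.98 coincide
    k = RateConstants(1, 1, 0.01, 1.08, 0.0, 0.01, 0.1, 1.0)
    init = PopulationState(0.0, 1.0, 0.0, 0.0)
    with pytest.raises(DegenerateSpectrumError):
        analytic_solution(k, init)
    traj = simulate(k, init, np.linspace(0, 5, 6))
    assert traj.provenance == "numeric"
    # secular growth t*e^{at} in P: cross-check one point against quadrature
    fine = simulate(k, init, np.linspace(0, 5, 501), method="numeric")
    assert fine.p[-1] == pytest.approx(traj.p[-1], rel=1e-8)


# ---------------------------------------------------------------------------
# Asymptotic composition
# ---------------------------------------------------------------------------


def test_asymptotic_reference(ref_k):
    res = asymptotic_fractions(ref_k)
    assert res.ok
    csc, p, d = res.fractions
    assert csc == pytest.approx(0.00184, abs=1e-5)
    assert p == pytest.approx(0.18751, abs=1e-5)
    assert d == pytest.approx(0.81065, abs=1e-5)
    assert res.growth_rate == pytest.approx(0.98)


def test_asymptotic_progenitor_dominated(ref_phi):
    """When b > a the stem compartment is outgrown entirely."""
    res = asymptotic_fractions(phi_to_rates(ref_phi.replace(phi54=0.75)))
    assert res.ok
    assert res.fractions[0] == 0.0
    assert res.fractions[1] == pytest.approx(0.2180, abs=2e-4)
    assert res.growth_rate == pytest.approx(1.2375)


def test_asymptotic_decoupled_pure_csc():
    """No CSC flux into P and a self-extinguishing P compartment leave a
    pure-CSC tumor."""
    k = RateConstants(1, 0, 0, 1.0, 4.28, 0.01, 0.1, 1.0)
    res = asymptotic_fractions(k)
    assert res.ok
    np.testing.assert_allclose(res.fractions, (1.0, 0.0, 0.0), atol=1e-15)


def test_asymptotic_flagged_not_silent():
    # shrinking system: a < 0, b < 0
    k = RateConstants(0.1, 1, 0.5, 0.1, 1.0, 0.5, 0.5, 1.0)
    res = asymptotic_fractions(k)
    assert not res.ok and res.reason is not None
    with pytest.raises(KineticsError):
        _ = res.csc_fraction


def test_simulated_fractions_converge_to_asymptotic():
    """For growing, well-separated spectra the simulated composition
    reaches the dominant-mode composition once (lambda* - lambda_2) * t > 20."""
    rng = np.random.default_rng(77)
    found = 0
    while found < 10:
        k = random_nondegenerate_rates(rng, gap=0.4)
        res = asymptotic_fractions(k)
        if not res.ok or res.growth_rate <= 0.1:
            continue
        lam = np.sort([k.a, k.b, -k.k8])
        t_star = 20.0 / (lam[2] - lam[1]) + 1.0
        sol = analytic_solution(k, random_state(rng, lo=0.5))
        frac = sol.fractions(t_star)[:, 0]
        np.testing.assert_allclose(frac, res.fractions, atol=1e-4)
        found += 1


# ---------------------------------------------------------------------------
# Totals and volume
# ---------------------------------------------------------------------------


def test_total_cells_and_volume():
    s = PopulationState(0.0, 1.0, 2.0, 3.0)
    assert total_cells(s) == 6.0
    assert tumor_volume(1e6) == pytest.approx(4.18)
    assert tumor_volume(0.0) == 0.0
    assert total_cells(PopulationState(0.0, 0, 0, 0)) == 0.0
    # the exponential-phase validity ceiling of ~1500 mm^3 corresponds to
    # about 3.59e8 cells
    assert tumor_volume(1500.0 / CELL_VOLUME_MM3) == pytest.approx(1500.0)


def test_fractions_sum_to_one():
    s = PopulationState(0.0, 1.0, 2.0, 3.0)
    assert sum(s.fractions) == pytest.approx(1.0)
    with pytest.raises(KineticsError):
        _ = PopulationState(0.0, 0, 0, 0).fractions


def test_trajectory_frame_columns(ref_k):
    traj = simulate(ref_k, PopulationState(0.0, 1.0, 0.0, 0.0), np.linspace(0, 5, 6))
    df = traj.to_frame()
    assert list(df.columns) == ["t", "CSC", "P", "D", "N", "CSC_N", "P_N", "D_N", "volume_mm3"]
    np.testing.assert_allclose(df["N"], df[["CSC", "P", "D"]].sum(axis=1))
    np.testing.assert_allclose(df[["CSC_N", "P_N", "D_N"]].sum(axis=1), 1.0)
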