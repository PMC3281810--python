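"""Core kinetics of the three-compartment cancer-stem-cell (CSC) tumor model.

The model tracks three tumor-cell subpopulations during nutrient-unlimited
exponential growth: cancer stem cells (CSC), transit-amplifying progenitors
(P) and terminally differentiated cells (D).  Every cellular event is written
as a pseudo-chemical reaction with a first-order rate law:

    R1  CSC -> 2 CSC      r1 = k1*CSC   symmetric CSC self-renewal
    R2  CSC -> CSC + P    r2 = k2*CSC   asymmetric CSC renewal
    R3  CSC -> 2 P        r3 = k3*CSC   symmetric CSC differentiation
    R4  P   -> 2 P        r4 = k4*P     progenitor self-renewal
    R5  P   -> 2 D        r5 = k5*P     progenitor differentiation
    R6  CSC -> dead       r6 = k6*CSC
    R7  P   -> dead       r7 = k7*P
    R8  D   -> dead       r8 = k8*D

Mass balances give a linear, lower-triangular ODE system

    dCSC/dt = (k1 - k3 - k6) * CSC                    = a * CSC
    dP/dt   = (k2 + 2 k3) * CSC + (k4 - k5 - k7) * P  = (k2 + 2 k3) CSC + b P
    dD/dt   = 2 k5 * P - k8 * D

whose eigenvalues are ``a = k1 - k3 - k6``, ``b = k4 - k5 - k7`` and
``-k8``.  The system is solved in closed form (three exponential modes); an
adaptive numeric integrator serves as fallback when two exponents (nearly)
coincide, and as the independent oracle in the test suite.

Rates carry units of 1/(arbitrary time unit); day-based time enters only
through the growth-curve fitting module via a global time-scale factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "CELL_VOLUME_MM3",
    "REFERENCE_PHI",
    "KineticsError",
    "DegenerateSpectrumError",
    "RateConstants",
    "PhiVector",
    "PopulationState",
    "Trajectory",
    "AnalyticSolution",
    "AsymptoticResult",
    "phi_to_rates",
    "rates_to_phi",
    "reaction_rates",
    "ode_rhs",
    "analytic_solution",
    "simulate",
    "asymptotic_fractions",
    "total_cells",
    "tumor_volume",
]

#: Effective volume contribution of one spherically shaped cell in a
#: spherical tumor of constant cellular density, mm^3/cell.
CELL_VOLUME_MM3 = 4.18e-6

#: Relative tolerance below which two exponents are treated as coincident
#: (the two-mode closed form becomes numerically unstable below this gap).
DEGENERACY_TOL = 1e-9

PHI_NAMES = ("phi21", "phi31", "phi41", "phi54", "phi61", "phi71", "phi81")
K_NAMES = ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8")


class KineticsError(ValueError):
    """Invalid kinetic parameters or states."""


class DegenerateSpectrumError(KineticsError):
    """Two exponential modes coincide and no fallback was requested."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateConstants:
    """The eight intrinsic event rates, units 1/(arbitrary time unit).

    ``k1``/``k2``/``k3`` govern CSC symmetric renewal, asymmetric renewal and
    symmetric differentiation; ``k4``/``k5`` progenitor renewal and
    differentiation; ``k6``/``k7``/``k8`` death of CSC, P and D.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float

    def __post_init__(self) -> None:
        for name in K_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise KineticsError(f"rate constant {name}={v!r} must be finite and >= 0")

    @property
    def a(self) -> float:
        """Net intrinsic CSC growth exponent, k1 - k3 - k6."""
        return self.k1 - self.k3 - self.k6

    @property
    def b(self) -> float:
        """Net intrinsic progenitor growth exponent, k4 - k5 - k7."""
        return self.k4 - self.k5 - self.k7

    @property
    def exponents(self) -> np.ndarray:
        """The three modal exponents (a, b, -k8)."""
        return np.array([self.a, self.b, -self.k8])

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in K_NAMES])

    @classmethod
    def from_array(cls, k: Sequence[float]) -> "RateConstants":
        k = list(k)
        if len(k) != 8:
            raise KineticsError(f"expected 8 rate constants, got {len(k)}")
        return cls(*map(float, k))

    def scaled(self, s: float) -> "RateConstants":
        """All eight rates multiplied by ``s`` (a pure time-unit change:
        every dimensionless ratio between rates is preserved)."""
        if s <= 0:
            raise KineticsError(f"time-scale factor must be > 0, got {s}")
        return RateConstants.from_array(self.as_array() * s)


@dataclass(frozen=True)
class PhiVector:
    """Dimensionless kinetic-ratio parameterization of a growth scenario.

    Every ratio is taken to ``k1`` except ``phi54 = k5/k4``, which expresses
    progenitor differentiation relative to progenitor renewal.  ``k1_scale``
    (default 1) sets the absolute time scale.
    """

    phi21: float
    phi31: float
    phi41: float
    phi54: float
    phi61: float
    phi71: float
    phi81: float
    k1_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in PHI_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise KineticsError(f"ratio {name}={v!r} must be finite and >= 0")
        if not math.isfinite(self.k1_scale) or self.k1_scale <= 0:
            raise KineticsError(f"k1_scale={self.k1_scale!r} must be finite and > 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PHI_NAMES])

    @classmethod
    def from_array(cls, phi: Sequence[float], k1_scale: float = 1.0) -> "PhiVector":
        phi = list(phi)
        if len(phi) != 7:
            raise KineticsError(f"expected 7 ratios, got {len(phi)}")
        return cls(*map(float, phi), k1_scale=float(k1_scale))

    def replace(self, **changes: float) -> "PhiVector":
        """A copy with the named ratios replaced."""
        values = {n: getattr(self, n) for n in PHI_NAMES + ("k1_scale",)}
        for key, val in changes.items():
            if key not in values:
                raise KineticsError(f"unknown ratio {key!r}")
            values[key] = float(val)
        return PhiVector(**values)

    def to_rates(self) -> "RateConstants":
        return phi_to_rates(self)


#: The reference scenario: the feasible vector
#: [phi21, phi31, phi41, phi54, phi61, phi71, phi81] = [1.0, 0.01, 5.35,
#: 0.8, 0.01, 0.1, 1.0] with k1 = 1, which sustains exponential growth with
#: a constant CSC fraction of about 0.18% of the tumor.
REFERENCE_PHI = PhiVector(1.0, 0.01, 5.35, 0.8, 0.01, 0.1, 1.0)


@dataclass(frozen=True)
class PopulationState:
    """Subpopulation sizes (continuous, mean-field) at one time point."""

    t: float
    csc: float
    p: float
    d: float

    def __post_init__(self) -> None:
        for name in ("csc", "p", "d"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise KineticsError(f"population {name}={v!r} must be finite and >= 0")

    @property
    def n(self) -> float:
        """Total living-tissue cell count N = CSC + P + D (dead cells are
        taken to be reabsorbed)."""
        return self.csc + self.p + self.d

    @property
    def fractions(self) -> tuple[float, float, float]:
        """(CSC/N, P/N, D/N); raises on an empty state."""
        n = self.n
        if n <= 0:
            raise KineticsError("fractions undefined for an empty state")
        return (self.csc / n, self.p / n, self.d / n)

    def as_array(self) -> np.ndarray:
        return np.array([self.csc, self.p, self.d])

    @property
    def volume_mm3(self) -> float:
        return tumor_volume(self.n)


@dataclass(frozen=True)
class Trajectory:
    """Populations on a strictly increasing time grid.

    ``provenance`` records which solver produced the values
    (``"analytic"`` or ``"numeric"``).
    """

    t: np.ndarray
    csc: np.ndarray
    p: np.ndarray
    d: np.ndarray
    provenance: Literal["analytic", "numeric"]

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
            raise KineticsError("time grid must be 1-D, non-empty and strictly increasing")
        for name in ("csc", "p", "d"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise KineticsError(f"{name} has shape {arr.shape}, expected {t.shape}")
            if np.any(arr < 0):
                raise KineticsError(f"{name} contains negative values")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n(self) -> np.ndarray:
        return self.csc + self.p + self.d

    def state(self, i: int) -> PopulationState:
        return PopulationState(float(self.t[i]), float(self.csc[i]), float(self.p[i]), float(self.d[i]))

    def states(self) -> Iterable[PopulationState]:
        return (self.state(i) for i in range(len(self)))

    def final_state(self) -> PopulationState:
        return self.state(len(self) - 1)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with totals, fractions and volume."""
        n = self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(n > 0, 1.0, np.nan) / np.where(n > 0, n, 1.0)
        return pd.DataFrame(
            {
                "t": self.t,
                "CSC": self.csc,
                "P": self.p,
                "D": self.d,
                "N": n,
                "CSC_N": self.csc * frac,
                "P_N": self.p * frac,
                "D_N": self.d * frac,
                "volume_mm3": n * CELL_VOLUME_MM3,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Rate laws and ODE right-hand side
# ---------------------------------------------------------------------------


def reaction_rates(state: PopulationState, k: RateConstants) -> np.ndarray:
    """The eight event rates (r1..r8) at ``state``.

    First-order kinetics: CSC events are proportional to CSC, progenitor
    events to P, and D death to D.
    """
    return np.array(
        [
            k.k1 * state.csc,
            k.k2 * state.csc,
            k.k3 * state.csc,
            k.k4 * state.p,
            k.k5 * state.p,
            k.k6 * state.csc,
            k.k7 * state.p,
            k.k8 * state.d,
        ]
    )


def _rhs_array(y: np.ndarray, k: RateConstants) -> np.ndarray:
    # Stoichiometry: R3 makes two P per event; R5 makes two D consuming one P.
    csc, p, d = y
    return np.array(
        [
            k.a * csc,
            (k.k2 + 2.0 * k.k3) * csc + k.b * p,
            2.0 * k.k5 * p - k.k8 * d,
        ]
    )


def ode_rhs(state: PopulationState, k: RateConstants) -> tuple[float, float, float]:
    """(dCSC/dt, dP/dt, dD/dt) — the mass balances of the reaction network."""
    dy = _rhs_array(state.as_array(), k)
    return (float(dy[0]), float(dy[1]), float(dy[2]))


# ---------------------------------------------------------------------------
# Phi <-> rate-constant conversion
# ---------------------------------------------------------------------------


def phi_to_rates(phi: PhiVector) -> RateConstants:
    """Expand a ratio vector into the eight rate constants.

    k1 = k1_scale; k2, k3, k4, k6, k7, k8 are their ratios times k1;
    k5 = phi54 * k4 (progenitor differentiation is ratioed to progenitor
    renewal, not to k1).
    """
    k1 = phi.k1_scale
    k4 = phi.phi41 * k1
    return RateConstants(
        k1=k1,
        k2=phi.phi21 * k1,
        k3=phi.phi31 * k1,
        k4=k4,
        k5=phi.phi54 * k4,
        k6=phi.phi61 * k1,
        k7=phi.phi71 * k1,
        k8=phi.phi81 * k1,
    )


def rates_to_phi(k: RateConstants) -> PhiVector:
    """Inverse of :func:`phi_to_rates`; requires k1 > 0 and, when k5 > 0,
    k4 > 0 (phi54 of an idle progenitor compartment defaults to 0)."""
    if k.k1 <= 0:
        raise KineticsError("rates_to_phi requires k1 > 0")
    if k.k4 > 0:
        phi54 = k.k5 / k.k4
    elif k.k5 == 0:
        phi54 = 0.0
    else:
        raise KineticsError("phi54 undefined: k4 = 0 with k5 > 0")
    return PhiVector(
        phi21=k.k2 / k.k1,
        phi31=k.k3 / k.k1,
        phi41=k.k4 / k.k1,
        phi54=phi54,
        phi61=k.k6 / k.k1,
        phi71=k.k7 / k.k1,
        phi81=k.k8 / k.k1,
        k1_scale=k.k1,
    )


# ---------------------------------------------------------------------------
# Closed-form solution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyticSolution:
    """Closed-form solution of the linear system for one (rates, initial
    state) pair.

    The solution is a sum of three exponential modes with exponents
    ``a``, ``b`` and ``-k8``::

        CSC(t) = CSC0 e^{at}
        P(t)   = A e^{at} + (P0 - A) e^{bt},        A = (k2+2k3) CSC0/(a-b)
        D(t)   = B e^{at} + C e^{bt}
                 + (D0 - B - C) e^{-k8 t},          B = 2k5 A/(a+k8)
                                                    C = 2k5 (P0-A)/(b+k8)

    ``coefficients`` holds the 3x3 mode matrix (rows CSC, P, D; columns the
    three exponents), so evaluation is a matrix product with the modal
    exponentials.  ``degenerate`` flags (near-)coincident exponents, where
    the expressions above lose validity and the model must be integrated
    numerically instead.
    """

    k: RateConstants
    init: PopulationState
    exponents: np.ndarray  # (a, b, -k8)
    coefficients: np.ndarray  # 3x3 mode matrix
    degenerate: bool

    def _modal(self, t: np.ndarray, shift: np.ndarray | None = None) -> np.ndarray:
        """exp(lambda_m * t), optionally shifted per time point for overflow-
        free relative evaluation."""
        expo = np.outer(self.exponents, t)
        if shift is not None:
            expo = expo - shift
        return np.exp(expo)

    def evaluate(self, t) -> np.ndarray:
        """Populations at times ``t``; shape (3, len(t)) ordered CSC, P, D."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self.coefficients @ self._modal(t)

    def state_at(self, t: float) -> PopulationState:
        y = self.evaluate(t)[:, 0]
        y = _clip_roundoff_negatives(y)
        return PopulationState(float(t), *map(float, y))

    def fractions(self, t) -> np.ndarray:
        """Population fractions (CSC/N, P/N, D/N) at times ``t``, shape
        (3, len(t)).  Evaluated relative to the leading mode, so it remains
        finite at times where the raw populations would overflow."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        shift = np.max(np.outer(self.exponents, t), axis=0)
        y = self.coefficients @ self._modal(t, shift)
        return y / y.sum(axis=0)

    def csc_fraction_derivative(self, t: float) -> float:
        """d(CSC/N)/dt at time ``t``, from the exact modal derivative.

        With overflow-free shifted modes E, f' = (C'N - CN')/N^2 where the
        common exponential scale cancels.
        """
        t_arr = np.atleast_1d(float(t))
        shift = np.max(np.outer(self.exponents, t_arr), axis=0)
        e = self._modal(t_arr, shift)[:, 0]
        y = self.coefficients @ e
        dy = self.coefficients @ (self.exponents * e)
        n = y.sum()
        dn = dy.sum()
        return float((dy[0] * n - y[0] * dn) / n**2)


def _clip_roundoff_negatives(y: np.ndarray, scale: float | None = None) -> np.ndarray:
    """Zero out negative magnitudes attributable to round-off; genuinely
    negative values propagate (and fail Trajectory validation)."""
    y = np.asarray(y, dtype=float).copy()
    if scale is None:
        scale = float(np.max(np.abs(y), initial=0.0))
    floor = -1e-10 * max(scale, 1.0)
    y[(y < 0) & (y >= floor)] = 0.0
    return y


def _degenerate_pairs(k: RateConstants, tol: float) -> list[tuple[str, str]]:
    lam = {"a": k.a, "b": k.b, "-k8": -k.k8}
    names = list(lam)
    out = []
    for i in range(3):
        for j in range(i + 1, 3):
            x, y = lam[names[i]], lam[names[j]]
            if abs(x - y) < tol * max(1.0, abs(x), abs(y)):
                out.append((names[i], names[j]))
    return out


def analytic_solution(
    k: RateConstants,
    init: PopulationState,
    *,
    degeneracy_tol: float = DEGENERACY_TOL,
    allow_degenerate: bool = False,
) -> AnalyticSolution:
    """Closed-form solution for rates ``k`` starting from ``init``.

    Raises :class:`DegenerateSpectrumError` when two exponents coincide
    within ``degeneracy_tol`` (relative), unless ``allow_degenerate`` is
    set, in which case the returned solution carries ``degenerate=True``
    and must not be evaluated — :func:`simulate` uses the flag to switch
    to numeric integration.
    """
    a, b, mk8 = k.a, k.b, -k.k8
    pairs = _degenerate_pairs(k, degeneracy_tol)
    if pairs:
        if not allow_degenerate:
            raise DegenerateSpectrumError(
                f"coincident exponents {pairs} (a={a:g}, b={b:g}, -k8={mk8:g}); "
                "use simulate() for the numeric fallback"
            )
        return AnalyticSolution(k, init, np.array([a, b, mk8]), np.zeros((3, 3)), True)

    csc0, p0, d0 = init.csc, init.p, init.d
    A = (k.k2 + 2.0 * k.k3) * csc0 / (a - b)
    B = 2.0 * k.k5 * A / (a + k.k8)
    C = 2.0 * k.k5 * (p0 - A) / (b + k.k8)
    coeff = np.array(
        [
            [csc0, 0.0, 0.0],
            [A, p0 - A, 0.0],
            [B, C, d0 - B - C],
        ]
    )
    return AnalyticSolution(k, init, np.array([a, b, mk8]), coeff, False)


def _simulate_numeric(k: RateConstants, init: PopulationState, t_grid: np.ndarray) -> Trajectory:
    t0 = float(t_grid[0])
    sol = solve_ivp(
        lambda _t, y: _rhs_array(y, k),
        (t0, float(t_grid[-1])),
        init.as_array(),
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - LSODA handles this linear system
        raise KineticsError(f"numeric integration failed: {sol.message}")
    y = sol.y
    scale = float(np.max(np.abs(y), initial=0.0))
    y = np.vstack([_clip_roundoff_negatives(row, scale) for row in y])
    return Trajectory(t_grid, y[0], y[1], y[2], "numeric")


def simulate(
    k: RateConstants,
    init: PopulationState,
    t_grid,
    *,
    method: Literal["auto", "analytic", "numeric"] = "auto",
    degeneracy_tol: float = DEGENERACY_TOL,
) -> Trajectory:
    """Populations on ``t_grid`` (strictly increasing, t_grid[0] >= 0).

    ``method="auto"`` uses the closed form and falls back to adaptive
    numeric integration for a degenerate spectrum; the choice is recorded
    in ``Trajectory.provenance``.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise KineticsError("time grid must be a non-empty 1-D sequence")
    if t_grid[0] < 0 or (len(t_grid) > 1 and np.any(np.diff(t_grid) <= 0)):
        raise KineticsError("time grid must be strictly increasing with t[0] >= 0")
    if init.t != t_grid[0]:
        init = PopulationState(float(t_grid[0]), init.csc, init.p, init.d)

    if method == "numeric":
        return _simulate_numeric(k, init, t_grid)
    sol = analytic_solution(k, init, degeneracy_tol=degeneracy_tol, allow_degenerate=(method == "auto"))
    if sol.degenerate:
        return _simulate_numeric(k, init, t_grid)
    # The coefficient matrix is anchored at t=0; shift the grid so that the
    # initial state is reproduced exactly at t_grid[0].
    y = sol.evaluate(t_grid - t_grid[0])
    scale = float(np.max(np.abs(y), initial=0.0))
    y = np.vstack([_clip_roundoff_negatives(row, scale) for row in y])
    return Trajectory(t_grid, y[0], y[1], y[2], "analytic")


# ---------------------------------------------------------------------------
# Asymptotic (balanced-growth) composition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AsymptoticResult:
    """Balanced-growth composition of the dominant exponential mode.

    ``fractions`` is ``(CSC/N, P/N, D/N)`` when the dominant mode is a
    growing population mode, else ``None`` with ``reason`` set.  The
    composition is a property of the rate constants only: any initial state
    with mass on the dominant mode converges to it.
    """

    fractions: tuple[float, float, float] | None
    growth_rate: float
    degenerate: bool = False
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.fractions is not None

    @property
    def csc_fraction(self) -> float:
        if self.fractions is None:
            raise KineticsError(f"asymptotic fractions unavailable: {self.reason}")
        return self.fractions[0]


def asymptotic_fractions(k: RateConstants, *, degeneracy_tol: float = DEGENERACY_TOL) -> AsymptoticResult:
    """Long-time population fractions and dominant growth exponent.

    During balanced growth the dominant eigenmode sets the composition:

    * if a > b, CSC : P : D = 1 : p : p*d with p = (k2+2k3)/(a-b) and
      d = 2 k5/(a+k8); lambda* = a;
    * if b > a the CSC compartment is outgrown (CSC/N -> 0) and
      P : D = 1 : 2 k5/(b+k8); lambda* = b.

    Non-growing systems (lambda* <= 0 or dominated by the death mode
    -k8) and degenerate spectra yield a flagged result, never silent
    numbers.
    """
    a, b = k.a, k.b
    lam = max(a, b)
    if abs(a - b) < degeneracy_tol * max(1.0, abs(a), abs(b)):
        return AsymptoticResult(None, lam, degenerate=True, reason="a and b coincide")
    if lam <= 0:
        return AsymptoticResult(None, lam, reason=f"dominant exponent {lam:g} <= 0 (no growth)")
    if lam <= -k.k8 + degeneracy_tol * max(1.0, k.k8):
        return AsymptoticResult(None, lam, reason="death mode dominates the spectrum")
    if a > b:
        p = (k.k2 + 2.0 * k.k3) / (a - b)
        d = 2.0 * k.k5 / (a + k.k8)
        v = np.array([1.0, p, p * d])
    else:
        d = 2.0 * k.k5 / (b + k.k8)
        v = np.array([0.0, 1.0, d])
    v = v / v.sum()
    return AsymptoticResult((float(v[0]), float(v[1]), float(v[2])), float(lam))


# ---------------------------------------------------------------------------
# Totals and tumor volume
# ---------------------------------------------------------------------------


def total_cells(state: PopulationState) -> float:
    """N = CSC + P + D (dead cells are reabsorbed, not counted)."""
    return state.n


def tumor_volume(n: float) -> float:
    """Tumor volume in mm^3 at constant cellular density:
    ``4.18e-6 mm^3/cell * N``."""
    if n < 0:
        raise KineticsError(f"cell count must be >= 0, got {n}")
    return CELL_VOLUME_MM3 * n
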