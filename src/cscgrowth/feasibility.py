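"""Biological feasibility of kinetic scenarios and feasible-family tracing.

A ratio vector defines a growth scenario; only a narrow region of ratio
space is biologically admissible for a solid tumor in exponential phase:

* death rates ordered by differentiation stage, k6 < k7 < k8;
* a small, *constant* stem-cell fraction: CSC/N < 0.01 with
  d(CSC/N)/dt ~ 0 throughout growth;
* bulk composition near the experimentally estimated P/N ~ 0.2 and
  D/N ~ 0.8.

This module classifies scenarios by the behavior of the CSC fraction at a
fixed horizon (steady / increasing / decreasing, the ``ss``/``(+)``/``(-)``
labels of the perturbation table), checks the constraint set, and traces the
one-parameter families of feasible solutions along which a perturbation of
one ratio is exactly compensated by another (e.g. progenitor renewal vs
asymmetric CSC renewal), which appear as straight lines in ratio space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import (
    DEGENERACY_TOL,
    REFERENCE_PHI,
    PHI_NAMES,
    AsymptoticResult,
    KineticsError,
    PhiVector,
    PopulationState,
    analytic_solution,
    asymptotic_fractions,
    phi_to_rates,
)

__all__ = [
    "FeasibilityError",
    "SolverError",
    "ConstraintReport",
    "SteadyStateReport",
    "FamilyTrace",
    "reference_composition",
    "classify_fraction_dynamics",
    "check_constraints",
    "solve_ratio_for_fraction",
    "trace_linear_family",
    "grid_scan",
    "load_table1",
    "classify_table",
]

#: Classification horizon, arbitrary time units.
DEFAULT_HORIZON = 30.0
#: Absolute tolerance on the CSC fraction for the steady-state call.
DEFAULT_EPSILON = 1e-4
#: Relative tolerance on the CSC fraction for the steady-state call.
DEFAULT_REL_TOL = 1e-2
#: Absolute tolerance on |P/N - 0.2| and |D/N - 0.8|.
DEFAULT_FRACTION_TOL = 0.05
#: Refuse cartesian scans larger than this.
DEFAULT_GRID_CAP = 200_000

Classification = Literal["ss", "increasing", "decreasing"]


class FeasibilityError(ValueError):
    """Invalid feasibility-analysis inputs."""


class SolverError(FeasibilityError):
    """A one-dimensional constraint solve failed."""


# ---------------------------------------------------------------------------
# Reference initial composition
# ---------------------------------------------------------------------------


def reference_composition(n0: float = 1.0) -> PopulationState:
    """Initial state on the balanced-growth composition of the reference
    scenario, scaled to total ``n0`` cells.

    Perturbation experiments start from the reference steady state: the
    question the classification answers is whether the perturbed kinetics
    hold, raise or erode the stem-cell fraction of an established tumor.
    """
    res = asymptotic_fractions(phi_to_rates(REFERENCE_PHI))
    f = res.fractions
    assert f is not None
    return PopulationState(0.0, n0 * f[0], n0 * f[1], n0 * f[2])


# ---------------------------------------------------------------------------
# Steady-state classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteadyStateReport:
    """Behavior of the CSC fraction at the classification horizon.

    ``classification`` is ``"ss"`` when the fraction has converged to its
    balanced-growth value by the horizon (within ``max(epsilon,
    rel_tol * f_inf)``); otherwise the sign of the exact derivative
    d(CSC/N)/dt at the horizon gives ``"increasing"`` or ``"decreasing"``.
    """

    classification: Classification
    derivative: float
    fraction_at_horizon: float
    asymptotic: AsymptoticResult
    converged_fractions: tuple[float, float, float] | None

    @property
    def label(self) -> str:
        """Compact table label: ss / (+) / (-)."""
        return {"ss": "ss", "increasing": "(+)", "decreasing": "(-)"}[self.classification]


def classify_fraction_dynamics(
    phi: PhiVector,
    init: PopulationState | None = None,
    horizon: float = DEFAULT_HORIZON,
    epsilon: float = DEFAULT_EPSILON,
    rel_tol: float = DEFAULT_REL_TOL,
) -> SteadyStateReport:
    """Classify d(CSC/N)/dt behavior at ``horizon`` (default 30 time units).

    ``init`` defaults to :func:`reference_composition`.  The CSC fraction
    and its derivative at the horizon come from the closed-form solution;
    the asymptotic fraction from the dominant-mode composition.  For
    non-growing or degenerate spectra the fraction target is taken as the
    simulated horizon value itself (classification then rests on the
    derivative alone).
    """
    if horizon <= 0:
        raise FeasibilityError(f"horizon must be > 0, got {horizon}")
    if init is None:
        init = reference_composition()
    k = phi_to_rates(phi)
    asym = asymptotic_fractions(k)

    try:
        sol = analytic_solution(k, init)
        f_h = float(sol.fractions(horizon)[0, 0])
        deriv = sol.csc_fraction_derivative(horizon)
    except KineticsError:
        # degenerate spectrum: numeric fallback
        from .kinetics import simulate

        grid = np.linspace(0.0, horizon, 601)
        traj = simulate(k, init, grid, method="numeric")
        fr = traj.csc / traj.n
        f_h = float(fr[-1])
        dt = grid[1] - grid[0]
        deriv = float((fr[-1] - fr[-2]) / dt)

    f_target = asym.fractions[0] if asym.ok else f_h
    gap = abs(f_h - f_target)
    if gap <= max(epsilon, rel_tol * f_target) and (asym.ok or abs(deriv) <= epsilon):
        cls: Classification = "ss"
        converged = asym.fractions if asym.ok else None
    elif deriv > 0:
        cls, converged = "increasing", None
    elif deriv < 0:
        cls, converged = "decreasing", None
    else:
        cls, converged = "ss", (asym.fractions if asym.ok else None)
    return SteadyStateReport(cls, deriv, f_h, asym, converged)


# ---------------------------------------------------------------------------
# Constraint checking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintReport:
    """Outcome of the biological constraint set for one ratio vector."""

    passes_death_ordering: bool
    passes_csc_cap: bool
    passes_fraction_targets: bool
    passes_steady_fraction: bool
    feasible: bool
    fractions: tuple[float, float, float] | None
    classification: Classification
    reason: str | None = None


def check_constraints(
    phi: PhiVector,
    init: PopulationState | None = None,
    horizon: float = DEFAULT_HORIZON,
    epsilon: float = DEFAULT_EPSILON,
    fraction_tol: float = DEFAULT_FRACTION_TOL,
    csc_cap: float = 0.01,
    strict: bool = False,
) -> ConstraintReport:
    """Check the constraint set against the balanced-growth solution.

    Death ordering (k6 < k7 < k8, strict) and the CSC cap (CSC/N <
    ``csc_cap``) are hard requirements, as is a steady CSC fraction.  The
    bulk-composition targets (|P/N - 0.2| and |D/N - 0.8| within
    ``fraction_tol``) are reported always but only gate ``feasible`` in
    ``strict`` mode: published steady states span a wider band of bulk
    compositions than the nominal targets.
    """
    k = phi_to_rates(phi)
    death_ok = k.k6 < k.k7 < k.k8

    report = classify_fraction_dynamics(phi, init=init, horizon=horizon, epsilon=epsilon)
    steady_ok = report.classification == "ss"
    asym = report.asymptotic
    if not asym.ok:
        return ConstraintReport(
            passes_death_ordering=death_ok,
            passes_csc_cap=False,
            passes_fraction_targets=False,
            passes_steady_fraction=steady_ok,
            feasible=False,
            fractions=None,
            classification=report.classification,
            reason=asym.reason or "no balanced growth",
        )

    csc_n, p_n, d_n = asym.fractions
    cap_ok = csc_n < csc_cap
    frac_ok = abs(p_n - 0.2) <= fraction_tol and abs(d_n - 0.8) <= fraction_tol
    feasible = death_ok and cap_ok and steady_ok and (frac_ok or not strict)
    return ConstraintReport(
        passes_death_ordering=death_ok,
        passes_csc_cap=cap_ok,
        passes_fraction_targets=frac_ok,
        passes_steady_fraction=steady_ok,
        feasible=feasible,
        fractions=asym.fractions,
        classification=report.classification,
    )


# ---------------------------------------------------------------------------
# One-dimensional constraint solves and family tracing
# ---------------------------------------------------------------------------


def _csc_fraction_of(phi: PhiVector, name: str, value: float) -> float:
    """Asymptotic CSC/N with ratio ``name`` set to ``value``; raises
    SolverError outside the balanced-growth regime."""
    res = asymptotic_fractions(phi_to_rates(phi.replace(**{name: value})))
    if not res.ok:
        raise SolverError(f"{name}={value:g}: {res.reason}")
    return res.csc_fraction


def solve_ratio_for_fraction(
    phi: PhiVector,
    free_ratio_name: str,
    target_csc_fraction: float,
    bracket: tuple[float, float],
    rtol: float = 1e-12,
) -> float:
    """Value of one ratio at which the asymptotic CSC fraction equals the
    target, all other ratios held fixed.

    Deterministic Brent root find on a bracket over which
    ``CSC/N(asymptotic) - target`` changes sign; the solve is well-posed on
    any monotone segment of the a > b regime.
    """
    if free_ratio_name not in PHI_NAMES:
        raise FeasibilityError(f"unknown ratio {free_ratio_name!r}")
    if not 0.0 < target_csc_fraction < 1.0:
        raise FeasibilityError(f"target CSC fraction must lie in (0, 1), got {target_csc_fraction}")
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise FeasibilityError(f"invalid bracket {bracket}")

    def g(x: float) -> float:
        return _csc_fraction_of(phi, free_ratio_name, x) - target_csc_fraction

    g_lo, g_hi = g(lo), g(hi)
    if np.sign(g_lo) == np.sign(g_hi):
        raise SolverError(
            f"no sign change of CSC/N - target on [{lo:g}, {hi:g}] for {free_ratio_name}: "
            f"g({lo:g})={g_lo:.3e}, g({hi:g})={g_hi:.3e}"
        )
    root = brentq(g, lo, hi, xtol=1e-15, rtol=max(rtol, 4e-16))
    return float(root)


@dataclass(frozen=True)
class FamilyTrace:
    """A traced one-parameter family of feasible scenarios.

    ``points`` has one row per grid value of the free ratio with the solved
    companion ratio, the achieved balanced-growth fractions and the P/CSC
    number ratio; failed inner solves are marked in ``failures``.  The
    solved-vs-free relation is summarized by an ordinary least-squares line
    (slope/intercept) and its relative RMS residual.
    """

    free_name: str
    solved_name: str
    points: pd.DataFrame
    slope: float | None
    intercept: float | None
    residual: float | None
    failures: tuple[float, ...] = ()

    @property
    def degenerate_fit(self) -> bool:
        return self.slope is None


def trace_linear_family(
    phi: PhiVector,
    free_ratio_name: str,
    solved_ratio_name: str,
    free_values: Sequence[float],
    target_csc_fraction: float | None = None,
    *,
    offset: float | None = None,
    bracket: tuple[float, float] = (1e-6, 200.0),
) -> FamilyTrace:
    """Trace a compensation family in ratio space.

    Two modes:

    * target mode (``target_csc_fraction`` given): for each value of the
      free ratio, solve the companion ratio so the balanced-growth CSC
      fraction equals the target (defaults to the reference scenario's
      value when ``None`` and ``offset`` is ``None``);
    * offset mode (``offset`` given): companion = free + offset with no
      solve — the family of death-rate pairs (phi61, phi71) with fixed
      separation keeps a - b, and hence the P/CSC ratio, exactly invariant.

    The traced pairs are summarized by an OLS line; a single-point trace is
    flagged degenerate with no slope.
    """
    for name in (free_ratio_name, solved_ratio_name):
        if name not in PHI_NAMES:
            raise FeasibilityError(f"unknown ratio {name!r}")
    if free_ratio_name == solved_ratio_name:
        raise FeasibilityError("free and solved ratios must differ")
    free_values = [float(v) for v in free_values]
    if not free_values:
        raise FeasibilityError("free_values must be non-empty")
    if offset is None and target_csc_fraction is None:
        target_csc_fraction = asymptotic_fractions(phi_to_rates(REFERENCE_PHI)).csc_fraction

    rows, failures = [], []
    for v in free_values:
        base = phi.replace(**{free_ratio_name: v})
        try:
            if offset is not None:
                solved = v + offset
            else:
                solved = solve_ratio_for_fraction(
                    base, solved_ratio_name, target_csc_fraction, bracket
                )
            cand = base.replace(**{solved_ratio_name: solved})
            res = asymptotic_fractions(phi_to_rates(cand))
            if not res.ok:
                raise SolverError(res.reason or "no balanced growth")
            csc_n, p_n, d_n = res.fractions
            rows.append(
                {
                    free_ratio_name: v,
                    solved_ratio_name: solved,
                    "csc_n": csc_n,
                    "p_n": p_n,
                    "d_n": d_n,
                    "p_over_csc": p_n / csc_n if csc_n > 0 else np.inf,
                    "growth_rate": res.growth_rate,
                }
            )
        except SolverError:
            failures.append(v)

    points = pd.DataFrame(rows)
    if len(points) >= 2:
        x = points[free_ratio_name].to_numpy()
        y = points[solved_ratio_name].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        fit = slope * x + intercept
        residual = float(np.sqrt(np.mean((y - fit) ** 2)) / max(np.std(y), np.abs(y).max(), 1e-300))
        slope, intercept = float(slope), float(intercept)
    else:
        slope = intercept = residual = None
    return FamilyTrace(
        free_ratio_name, solved_ratio_name, points, slope, intercept, residual, tuple(failures)
    )


# ---------------------------------------------------------------------------
# Grid scanning and the published perturbation table
# ---------------------------------------------------------------------------


def grid_scan(
    ranges: Mapping[str, Sequence[float]],
    base: PhiVector = REFERENCE_PHI,
    *,
    feasible_only: bool = True,
    strict: bool = False,
    horizon: float = DEFAULT_HORIZON,
    epsilon: float = DEFAULT_EPSILON,
    max_points: int = DEFAULT_GRID_CAP,
) -> pd.DataFrame:
    """Exhaustive cartesian scan of ratio space against the constraint set.

    ``ranges`` maps ratio names to value sequences; unlisted ratios stay at
    ``base``.  Rows come out in deterministic lexicographic grid order with
    one column per ratio, the classification label, the balanced-growth
    fractions and the individual constraint verdicts.  Scans larger than
    ``max_points`` are refused.
    """
    for name in ranges:
        if name not in PHI_NAMES:
            raise FeasibilityError(f"unknown ratio {name!r}")
    names = [n for n in PHI_NAMES if n in ranges]
    axes = [[float(v) for v in ranges[n]] for n in names]
    n_pts = int(np.prod([len(ax) for ax in axes])) if axes else 1
    if n_pts > max_points:
        raise FeasibilityError(f"grid of {n_pts} points exceeds the cap of {max_points}")

    rows = []
    for combo in itertools.product(*axes) if axes else [()]:
        cand = base.replace(**dict(zip(names, combo)))
        rep = check_constraints(cand, horizon=horizon, epsilon=epsilon, strict=strict)
        if feasible_only and not rep.feasible:
            continue
        row = {n: getattr(cand, n) for n in PHI_NAMES}
        row["classification"] = rep.classification
        csc_n, p_n, d_n = rep.fractions if rep.fractions else (np.nan, np.nan, np.nan)
        row.update(
            csc_n=csc_n,
            p_n=p_n,
            d_n=d_n,
            death_ordering=rep.passes_death_ordering,
            csc_cap=rep.passes_csc_cap,
            fraction_targets=rep.passes_fraction_targets,
            steady_fraction=rep.passes_steady_fraction,
            feasible=rep.feasible,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def load_table1() -> pd.DataFrame:
    """The 18-row perturbation-experiment fixture around the reference
    scenario: ratio vectors, published classification labels and published
    steady-state fractions (blank where the run did not reach steady state)."""
    with resources.files("cscgrowth.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def classify_table(
    table: pd.DataFrame | None = None,
    *,
    horizon: float = DEFAULT_HORIZON,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Re-run the classification for every row of a perturbation table.

    ``table`` defaults to :func:`load_table1`.  Returns the table with
    computed ``label``, ``csc_n``, ``p_n`` and ``d_n`` columns appended
    (computed fractions only for rows classified steady)."""
    if table is None:
        table = load_table1()
    out = table.copy()
    labels, csc_l, p_l, d_l = [], [], [], []
    for _, row in table.iterrows():
        phi = PhiVector(*[float(row[n]) for n in PHI_NAMES])
        rep = classify_fraction_dynamics(phi, horizon=horizon, epsilon=epsilon)
        labels.append(rep.label)
        if rep.converged_fractions is not None:
            c, p, d = rep.converged_fractions
        else:
            c = p = d = np.nan
        csc_l.append(c)
        p_l.append(p)
        d_l.append(d)
    out["label_computed"] = labels
    out["csc_n_computed"] = csc_l
    out["p_n_computed"] = p_l
    out["d_n_computed"] = d_l
    return out
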