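"""Scaled fitting of the model to tumor-volume growth curves.

The intrinsic rates are defined per *arbitrary* time unit; a real xenograft
curve measured in days determines only the global time scale.  A single
positive factor ``s`` (model time units per day) multiplies all eight rate
constants — a pure change of time unit that leaves every kinetic ratio and
every balanced-growth fraction untouched and merely compresses the time
axis.  Fitting a volume curve therefore reduces to a one-dimensional (or,
with a free initial population, effectively still one-dimensional) least
squares problem.

Since the published xenograft datasets are external, a seeded synthetic
generator emulates exponential-phase volume trajectories with multiplicative
lognormal measurement noise, making the fitter testable end to end.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kinetics import (
    CELL_VOLUME_MM3,
    KineticsError,
    PhiVector,
    PopulationState,
    analytic_solution,
    asymptotic_fractions,
    phi_to_rates,
    simulate,
)

__all__ = [
    "GrowthCurveError",
    "GrowthCurve",
    "InitialSpec",
    "FitResult",
    "load_growth_curve",
    "write_growth_curve",
    "predict_volume",
    "fit_scaling",
    "synthesize_growth_curve",
]


class GrowthCurveError(ValueError):
    """Malformed growth-curve input."""


@dataclass(frozen=True)
class GrowthCurve:
    """An observed (time in days, volume in mm^3) series."""

    times_days: np.ndarray
    volumes_mm3: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_days, dtype=float)
        v = np.asarray(self.volumes_mm3, dtype=float)
        if t.ndim != 1 or len(t) == 0 or t.shape != v.shape:
            raise GrowthCurveError("need matching non-empty 1-D time and volume arrays")
        if np.any(np.diff(t) <= 0):
            raise GrowthCurveError("times must be strictly increasing")
        if np.any(v < 0) or not np.all(np.isfinite(v)) or not np.all(np.isfinite(t)):
            raise GrowthCurveError("volumes must be finite and >= 0")
        object.__setattr__(self, "times_days", t)
        object.__setattr__(self, "volumes_mm3", v)

    def __len__(self) -> int:
        return len(self.times_days)


@dataclass(frozen=True)
class InitialSpec:
    """Initial tumor composition at t = 0 for a fit.

    Either absolute compartment counts, or a total cell count ``n0`` split
    by an initial CSC fraction (the remainder assigned to P and D by the
    balanced-growth composition of the scenario — for implanted pure stem
    populations set ``csc_fraction=1``).
    """

    csc: float | None = None
    p: float | None = None
    d: float | None = None
    n0: float | None = None
    csc_fraction: float | None = None

    def resolve(self, phi: PhiVector) -> PopulationState:
        if self.csc is not None:
            return PopulationState(0.0, self.csc, self.p or 0.0, self.d or 0.0)
        if self.n0 is None or self.csc_fraction is None:
            raise GrowthCurveError("InitialSpec needs counts or (n0, csc_fraction)")
        if not 0.0 <= self.csc_fraction <= 1.0:
            raise GrowthCurveError("csc_fraction must lie in [0, 1]")
        csc = self.n0 * self.csc_fraction
        rest = self.n0 - csc
        if rest == 0:
            return PopulationState(0.0, csc, 0.0, 0.0)
        res = asymptotic_fractions(phi_to_rates(phi))
        if res.ok and (res.fractions[1] + res.fractions[2]) > 0:
            p_w = res.fractions[1] / (res.fractions[1] + res.fractions[2])
        else:
            p_w = 0.5
        return PopulationState(0.0, csc, rest * p_w, rest * (1.0 - p_w))


@dataclass(frozen=True)
class FitResult:
    """Outcome of the time-scale fit.

    ``s`` is in model time units per day (the day-based rates are
    ``s * k``).  ``r_squared`` is 1 - SSE/SStot about the mean observed
    volume; ``None`` for a degenerate (constant) curve.
    """

    s: float
    init: PopulationState
    n0_fitted: bool
    sse: float
    r_squared: float | None
    residuals: np.ndarray
    log_space: bool = False

    def to_dict(self) -> dict:
        return {
            "s_model_units_per_day": self.s,
            "init": {"csc": self.init.csc, "p": self.init.p, "d": self.init.d},
            "n0_fitted": self.n0_fitted,
            "sse": self.sse,
            "r_squared": self.r_squared,
            "log_space": self.log_space,
            "residuals": [float(r) for r in self.residuals],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_growth_curve(source: str | Path | TextIO, label: str = "") -> GrowthCurve:
    """Read a two-column delimited (comma/tab/whitespace) text curve.

    A single non-numeric header row is tolerated; any later malformed row
    is an error reported with its line number.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
        label = label or Path(source).name
    times, vols = [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) == 1:
            parts = line.replace(",", "\t").split("\t")
        try:
            t, v = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            if lineno == 1 and not times:
                continue  # header
            raise GrowthCurveError(f"line {lineno}: cannot parse {raw!r} as two numbers")
        times.append(t)
        vols.append(v)
    if not times:
        raise GrowthCurveError("no data rows found")
    try:
        return GrowthCurve(np.array(times), np.array(vols), label=label)
    except GrowthCurveError as exc:
        raise GrowthCurveError(f"invalid curve: {exc}") from exc


def write_growth_curve(curve: GrowthCurve, path: str | Path) -> None:
    """Write as `time_days,volume_mm3` CSV; round-trips exactly through
    :func:`load_growth_curve` (17 significant digits)."""
    with open(path, "w") as fh:
        fh.write("time_days,volume_mm3\n")
        for t, v in zip(curve.times_days, curve.volumes_mm3):
            fh.write(f"{t:.17g},{v:.17g}\n")


# ---------------------------------------------------------------------------
# Forward prediction and synthesis
# ---------------------------------------------------------------------------


def predict_volume(
    phi: PhiVector,
    init: PopulationState,
    s: float,
    times_days,
) -> np.ndarray:
    """Model tumor volume (mm^3) at day times under time scale ``s``.

    All eight rates are multiplied by ``s``; equivalently the dimensionless
    solution is evaluated at ``s * t``.  Overflowing populations saturate
    to inf rather than raising, so optimizers can reject absurd scales.
    """
    if s <= 0:
        raise GrowthCurveError(f"time scale s must be > 0, got {s}")
    t = np.atleast_1d(np.asarray(times_days, dtype=float))
    k_day = phi_to_rates(phi).scaled(s)
    try:
        sol = analytic_solution(k_day, init)
        with np.errstate(over="ignore", invalid="ignore"):
            n = sol.evaluate(t).sum(axis=0)
    except KineticsError:
        traj = simulate(k_day, init, t if len(t) > 1 else np.array([0.0, t[0] + 1e-9]), method="numeric")
        n = traj.n[: len(t)]
    return CELL_VOLUME_MM3 * n


def synthesize_growth_curve(
    phi: PhiVector,
    init: PopulationState,
    s: float,
    times_days,
    noise_cv: float = 0.0,
    seed: int | None = None,
    label: str = "synthetic",
) -> GrowthCurve:
    """Seeded synthetic exponential-phase volume curve.

    Volumes are the model prediction times mean-one multiplicative
    lognormal noise with coefficient of variation ``noise_cv``
    (measurement error on tumor volume is proportional and volumes must
    stay positive).  ``seed`` is required whenever ``noise_cv > 0``.
    """
    if noise_cv < 0:
        raise GrowthCurveError(f"noise_cv must be >= 0, got {noise_cv}")
    t = np.atleast_1d(np.asarray(times_days, dtype=float))
    v = predict_volume(phi, init, s, t)
    if noise_cv > 0:
        if seed is None:
            raise GrowthCurveError("seed is required when noise_cv > 0")
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        factors = np.exp(rng.normal(0.0, sigma, size=len(t)) - sigma**2 / 2.0)
        v = v * factors
    return GrowthCurve(t, v, label=label)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _sse_for_scale(
    s: float,
    curve: GrowthCurve,
    phi: PhiVector,
    init: PopulationState,
    fit_n0: bool,
    log_space: bool,
) -> tuple[float, float]:
    """(SSE, N0 multiplier) at scale ``s``; the optimal initial-population
    multiplier is a closed-form linear least squares solve because the
    model is linear in the initial state."""
    with np.errstate(over="ignore", invalid="ignore"):
        pred = predict_volume(phi, init, s, curve.times_days)
    obs = curve.volumes_mm3
    if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
        return math.inf, 1.0
    if log_space:
        mask = obs > 0
        if fit_n0:
            c = float(np.exp(np.mean(np.log(obs[mask]) - np.log(pred[mask]))))
        else:
            c = 1.0
        resid = np.log(obs[mask]) - np.log(c * pred[mask])
        return float(resid @ resid), c
    with np.errstate(over="ignore"):
        if fit_n0:
            denom = float(pred @ pred)
            c = float(pred @ obs) / denom if denom > 0 and math.isfinite(denom) else 1.0
            if c <= 0:
                return math.inf, 1.0
        else:
            c = 1.0
        resid = obs - c * pred
        sse = float(resid @ resid)
    return (sse if math.isfinite(sse) else math.inf), c


def fit_scaling(
    curve: GrowthCurve,
    phi: PhiVector,
    init_spec: InitialSpec | PopulationState,
    *,
    fit_n0: bool = False,
    log_space: bool = False,
    s_bounds: tuple[float, float] = (1e-4, 1e3),
    n_starts: int = 61,
) -> FitResult:
    """Least-squares time-scale fit of the model to a volume curve.

    Deterministic multi-start: SSE is evaluated on a log-spaced grid of
    ``n_starts`` scales across ``s_bounds``; the best grid cell is refined
    by bounded scalar minimization.  With ``fit_n0`` the initial total
    population is a free multiplier solved in closed form at each scale.
    SSE is on volumes by default (``log_space`` switches to log-volumes).
    """
    if len(curve) < 3:
        raise GrowthCurveError(f"need at least 3 points to fit, got {len(curve)}")
    obs = curve.volumes_mm3
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    init = init_spec.resolve(phi) if isinstance(init_spec, InitialSpec) else init_spec
    if init.n <= 0:
        raise GrowthCurveError("initial population must be positive")

    grid = np.geomspace(s_bounds[0], s_bounds[1], n_starts)
    sse_grid = [_sse_for_scale(s, curve, phi, init, fit_n0, log_space)[0] for s in grid]
    i_best = int(np.argmin(sse_grid))
    if not math.isfinite(sse_grid[i_best]):
        raise GrowthCurveError("no admissible time scale in the search bounds")
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda x: _sse_for_scale(math.exp(x), curve, phi, init, fit_n0, log_space)[0],
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    s_hat = float(math.exp(res.x))
    sse, c = _sse_for_scale(s_hat, curve, phi, init, fit_n0, log_space)
    init_hat = PopulationState(0.0, c * init.csc, c * init.p, c * init.d)

    pred = predict_volume(phi, init_hat, s_hat, curve.times_days)
    residuals = obs - pred
    sse_vol = float(residuals @ residuals)
    r2 = None if sstot == 0 else 1.0 - sse_vol / sstot
    return FitResult(
        s=s_hat,
        init=init_hat,
        n0_fitted=fit_n0,
        sse=sse if log_space else sse_vol,
        r_squared=r2,
        residuals=residuals,
        log_space=log_space,
    )
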