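# Methods

## Model

The package implements a deterministic, mean-field compartment model of
exponential-phase solid-tumor growth under the cancer-stem-cell hypothesis.
Three subpopulations are tracked — cancer stem cells (CSC), transit-amplifying
progenitors (P) and terminally differentiated cells (D) — and every cellular
event is a pseudo-chemical reaction with a first-order rate law:

| event | reaction | rate |
|---|---|---|
| symmetric CSC self-renewal | CSC → 2 CSC | k₁·CSC |
| asymmetric CSC renewal | CSC → CSC + P | k₂·CSC |
| symmetric CSC differentiation | CSC → 2 P | k₃·CSC |
| progenitor self-renewal | P → 2 P | k₄·P |
| progenitor differentiation | P → 2 D | k₅·P |
| death | CSC, P, D → ∅ | k₆·CSC, k₇·P, k₈·D |

Mass balances yield the lower-triangular linear system

    dCSC/dt = a·CSC,                       a = k₁ − k₃ − k₆
    dP/dt   = (k₂ + 2k₃)·CSC + b·P,        b = k₄ − k₅ − k₇
    dD/dt   = 2k₅·P − k₈·D

with eigenvalues a, b and −k₈.  The closed form is

    CSC(t) = CSC₀ e^{at}
    P(t)   = A e^{at} + (P₀ − A) e^{bt},            A = (k₂+2k₃)CSC₀/(a−b)
    D(t)   = B e^{at} + C e^{bt} + (D₀−B−C) e^{−k₈t},
             B = 2k₅A/(a+k₈),  C = 2k₅(P₀−A)/(b+k₈)

validated throughout against adaptive numeric integration (LSODA,
rtol 1e-10, atol 1e-12) rather than against any printed coefficient
expressions.  Total cell number is N = CSC+P+D (dead cells are reabsorbed);
volume is 4.18×10⁻⁶ mm³ per cell, i.e. constant cellular density — the model
describes the nutrient-unlimited exponential phase only, up to roughly
1500 mm³, and does not distinguish living from necrotic tissue.

Assumptions worth keeping in mind: first-order (density-independent) rates;
no space, diffusion, nutrient limitation or angiogenesis dynamics; no
cell-cycle structure; populations are continuous (no demographic
stochasticity); D cells never divide.

## Parameterization

Scenarios are specified by dimensionless ratios
Φ = (Φ₂/₁, Φ₃/₁, Φ₄/₁, Φ₅/₄, Φ₆/₁, Φ₇/₁, Φ₈/₁) together with the absolute
scale k₁ (default 1 per arbitrary time unit).  All ratios refer to k₁ except
Φ₅/₄ = k₅/k₄, which expresses progenitor differentiation relative to
progenitor renewal.  The reference vector [1.0, 0.01, 5.35, 0.8, 0.01, 0.1,
1.0] is the canonical feasible scenario (a = 0.98, b = 0.97); the balanced
growth composition it implies is CSC/N ≈ 0.00184, P/N ≈ 0.1875,
D/N ≈ 0.8107.

Asymptotic composition: for a > b, CSC:P:D = 1 : p : p·d with
p = (k₂+2k₃)/(a−b) and d = 2k₅/(a+k₈), growing at λ* = a; for b > a the
stem compartment is outgrown (CSC/N → 0) and P:D = 1 : 2k₅/(b+k₈) at
λ* = b.  Non-growing spectra (λ* ≤ 0, or dominated by the death mode) and
degenerate spectra return a flagged result instead of numbers.

## Steady-state classification

A scenario is classified by the behavior of the CSC fraction f = CSC/N at a
horizon of 30 time units: `ss` when f has converged to its balanced-growth
value, `increasing`/`decreasing` otherwise by the sign of the exact modal
derivative f′(30).  Two numerical choices matter:

* **Initial condition.**  The default IC for classification is the
  balanced-growth composition of the *reference* scenario.  This encodes the
  question being asked — does a perturbation of an established, feasible
  tumor hold, raise or erode its stem fraction?  From a pure-CSC implant the
  fraction starts at 1 and is still relaxing downward at the horizon for
  every scenario in the reference neighborhood (the slow fraction-relaxation
  rate is |a−b| ≈ 0.01, time constant ≈ 100), so every perturbation would
  look "decreasing" and the increasing class would be unreachable.
* **Convergence test.**  `ss` requires |f(30) − f∞| ≤ max(ε, 0.01·f∞) with
  ε = 1e-4 (absolute).  A pure derivative threshold cannot separate the
  classes here: a fast-converging scenario still two e-foldings from its
  (distant) asymptote carries a larger |f′| than a slow scenario drifting
  near its own asymptote.  The convergence criterion matches the intended
  semantics — "reaches steady state before the horizon" — and reproduces all
  18 published perturbation classifications with ≥1.45× margin on both
  tolerances.

## Feasibility constraints

`check_constraints` evaluates: death ordering k₆ < k₇ < k₈ (strict); steady
CSC fraction (classification `ss`); CSC/N < 0.01; and the bulk-composition
targets |P/N − 0.2| ≤ 0.05, |D/N − 0.8| ≤ 0.05.  The first three are hard;
the bulk targets are reported but gate feasibility only in strict mode,
since published steady scenarios span P/N ≈ 0.11–0.56 while remaining of
interest.

Family tracing works on the asymptotic closed form, not on time integration
(exact and fast); the inner solve is Brent root finding on a monotone
segment (no randomness anywhere in the feasibility module).  Two family
types are built in: target families, where a companion ratio is solved so
the asymptotic CSC/N holds a target value as a free ratio moves (the
(Φ₄/₁, Φ₂/₁) family over Φ₄/₁ ∈ [5.18, 5.40] has slope ≈ −21 here; the
regime edge is a = b at Φ₄/₁ = 5.40, where the required Φ₂/₁ turns negative
and the solve correctly fails); and offset families (Φ₇/₁ = Φ₆/₁ + δ,
δ = 0.09), along which a − b and hence the P/CSC ratio are exactly
invariant.  Published slope/intercept values for the target family depend
on the exact target fraction used to generate them, which is not recoverable
to better than a few percent; they are treated as approximate landmarks, not
assertions.

## Therapy

Interventions are instantaneous point events: multiplicative survival
fractions per compartment and/or a permanent ratio-vector replacement from
the event time on.  Relapse is defined as N regaining its exact
pre-treatment value (simplest monotone-comparable criterion; the offset for
a uniform kill with survival s in the dominant-mode regime is
ln(1/s)/λ* exactly).  The progenitor-extinction criterion — selective CSC
eradication stops the tumor only if k₄ < k₅ + k₇, strictly — follows from
the P balance with CSC ≡ 0.  A differentiation-promoting shift of Φ₅/₄
from 0.8 to 0.9 leaves a = 0.98 as the dominant exponent, so in this model
it changes the composition but not the long-run growth rate; reported
relapse offsets simply record this.

## Growth-curve fitting

Real curves are measured in days while the model is unit-agnostic; a single
factor s (model time units per day) multiplies all eight rates — a pure
change of time unit that preserves every ratio and every asymptotic
fraction.  This is the interpretation adopted for "scaling" a common ratio
vector onto different tumors; it is an interpretation, since multiplying
the dimensionless ratios themselves by a scalar would change the model.
Vertical scaling is a free initial population, fit jointly when requested
(closed-form linear least squares at each s, because the system is linear
in its initial state).  The fit minimizes SSE on volumes (matching the
usual R² framing; R² = 1 − SSE/SStot about the mean observed volume), with
log-volume SSE available as a flag.  The optimizer is a deterministic
multi-start: SSE on a 61-point log-spaced grid of s over [1e-4, 1e3],
followed by bounded scalar refinement of the best cell — exponential SSE
landscapes are too narrow for a single local search.

The synthetic-curve generator emulates exponential-phase xenograft volume
series: model volumes times mean-one multiplicative lognormal noise
(σ² = ln(1+cv²)), seeded.  Default study conditions in the tests: a
2000-cell pure-CSC implant, 12–13 measurements over 60 days, s = 0.12
(volume rises from ~8×10⁻³ mm³ to ~10³ mm³, i.e. a realistic exponential
window), noise cv = 5%.  What the noise model does not emulate: growth-rate
heterogeneity between animals, measurement times with jitter, saturation
near the necrotic transition — so passing recovery tests demonstrates the
fitter, not the realism of late-stage tumor data.

## Numerical choices

* Degenerate spectra: two exponents closer than 1e-9 (relative) make the
  two-mode form unstable; the closed form refuses and `simulate` falls back
  to LSODA, recording provenance.  Secular (t·e^{λt}) forms were considered
  and rejected in favor of one well-tested fallback path.
* Trajectory values with negative magnitudes below 1e-10 of the largest
  component are clipped to zero (round-off); genuine negativity raises.
* Fraction evaluation at large t factors out the dominant exponential, so
  compositions remain finite where raw populations would overflow.
* Analytic/numeric agreement is asserted at 1e-6 relative with an absolute
  floor of 1e-12 × the largest population: below that floor the numeric
  oracle itself carries no information (its absolute tolerance), so relative
  comparison of fully decayed components is not meaningful.
* Root finds and the fit refinement are deterministic (Brent / bounded
  Golden-section); all stochastic paths take an explicit seed.

## Known limitations

The model cannot represent growth slow-down, dormancy, immune interaction,
or resistance evolution; interventions are instantaneous (no
pharmacokinetics); day-unit claims about relapse times depend entirely on
the fitted time scale s.  Classification labels near the tolerance
boundaries (scenarios whose fraction drift at the horizon is ~1e-4) are
sensitive to the choice of horizon and IC; both are configurable.
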