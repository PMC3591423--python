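# Methods

## Model

A cell population is maintained at steady state by constant production.
Each cell faces two competing, independent fates:

* **senescent death** at the end of a natural lifespan `L` drawn from a law
  that is either lognormal with log-mean `m` and log-s.d. `s` (LS/DLS
  models) or degenerate at a fixed `T` (Dornhorst model);
* **random loss** as the first event of a Poisson process with rate
  constant `r` (hr⁻¹), independent of age.

Survival to age `a` is `P(a) = e^{-ra} Pr(L > a)`; the steady-state age
density is `P(a)/Θ` with `Θ = ∫₀^∞ P(u) du`; the pulse-label survival curve
is `D(t) = ∫ₜ^∞ P / Θ`. Integration by parts gives `Θ = f/r` where
`f = 1 − E[e^{-rL}]` is the random loss fraction (the `r → 0` limit is the
mean lifespan `μ`). Steady-state bookkeeping then yields `N = S·Θ`,
`R = rN`, and the identity `f = R/S`.

Assumptions worth stating: production is constant (no feedback from count
to production on the experiment's timescale); the blood volume is constant;
the two fates are independent; labeling does not perturb survival. None of
these are tested by this package — they are the model's premises.

## Units and parameter conventions

Time is in hours everywhere internally. Counts are carried in units of
10³ µL⁻¹ as conventionally reported; the absolute loss rate `R = 24·r·N`
is reported per day, because consumption requirements are conventionally
quoted per day. `r` is a first-order rate constant in hr⁻¹. The lognormal
law is parameterized internally by `(m, s)` (log-hours); arithmetic moments
`(μ, σ)` in hours are accepted at every interface via the standard
conversion `s² = ln(1 + σ²/μ²)`, `m = ln μ − s²/2`. Survival curves are
expressed in percent (0–100) on the observation scale, scaled by the
first-label efficiency: `100·e1·D(t)`.

## Numerics

* **Quadrature**: composite trapezoid on a uniform grid of 1000 points
  (configurable) over `[0, exp(m+4s)]` for lognormal laws and `[0, T]` for
  the delta law. At the default grid the age density normalizes to 1 within
  ~1e-4 and `f` is accurate to well under the two decimals at which it is
  reported. Closed forms are used where they exist: the Dornhorst survival
  curve `D(t) = (e^{-rt} − e^{-rT})/(1 − e^{-rT})` (limit `1 − t/T` as
  `r → 0`), and `f = 1 − e^{-rT}` for the delta law. The pure-lognormal
  (r = 0) curve also has an analytic form via the lognormal truncated mean;
  it is kept as an independent oracle in the tests rather than as a fast
  path, so one numeric route serves all models.
* **Steady-state identities**: `mean_realized_lifespan` is computed as
  `f/r` (analytically `μ` when `r = 0`) with `f` from the quadrature, so
  `f = R/S` and `N = S·Θ` hold to machine precision by construction; the
  agreement of `f/r` with the direct quadrature of `∫P` is asserted in
  tests (~1e-3 relative at the default grid).
* **`r = 0` is legal everywhere**; all `f/r` expressions switch to the `μ`
  limit rather than dividing by zero.

## Cohort (double-label) prediction

The cohort age density `p(a, t)` (per unit steady-state population, `t`
from the second labeling) satisfies the transport equation
`∂p/∂t + ∂p/∂a = −(h(a)+r)p` with senescent hazard
`h(a) = L(a)/Pr(L>a)`. The initial condition weights the steady age
density by `e2` below the inter-label delay `d` and by `e2(1−e1)` above it
(cells that escaped the first label); the boundary inflow at age 0 decays
as `e2·2^{−t/b_half}` times the birth-rate density, modelling carry-over
labeling of newborns. The solution is by the method of characteristics —
exact transport, the hazard integrating to a ratio of survival functions —
on the same 1000-point age grid; an explicit upwind finite-difference
solver (CFL 0.5, hazard clipped where the survival function underflows) is
retained purely as a cross-check and agrees within 1e-3. Predicted cohort
curves are absolute percent-of-all-platelets (no renormalization to 100%
at t = 0); the initial density is discontinuous at age `d`, so tests that
integrate across it refine the grid.

## Fitting

Unweighted least squares in percent units against every replicate point
(not the replicate mean), minimized with a bound-constrained trust-region
reflective solver. Bounds/start-draw intervals: `m ∈ [ln 12, ln 400]`,
`s ∈ [0.01, 1]` (bound floor 1e-3), `r ∈ [0, 0.05] hr⁻¹`,
`T ∈ [12, 400] hr`, `e1, e2 ∈ [0.5, 1]` (bounds [0, 1]),
`b_half ∈ [1, 48] hr`; these bracket all plausible fits with wide margin
and are configurable. Multi-start: random uniform draws until no
improvement for 100 consecutive starts (population fits) or 10 (population
+ cohort fits). DLS fits are additionally seeded from the LS and Dornhorst
optima (the delta law entering as the `s → 0` lognormal limit), which
enforces the nesting inequality `ssr(DLS) ≤ min(ssr(LS), ssr(Dornhorst))`
by construction. Ties resolve to the lowest SSR, then the earliest start;
the RNG seed is recorded in the result. Parameter counts: 3 for LS and
Dornhorst population fits, 4 for DLS; +2 (`e2`, `b_half`) with the cohort.

## Monte Carlo confidence intervals

The scatter about the best fit is modelled as i.i.d. Gaussian noise with
s.d. `σ_e = sqrt(ssr/df)` (percent). Each iteration simulates
`n_replicates` (default 6) noisy curves around the best-fit prediction at
the observed time points, refits the same model, and records the
parameters plus the derived `f`, `R = 24·r·N`, `S`. Defaults: 1000
iterations; 95% CI = 2.5–97.5 percentiles; box summaries use
2.5/25/50/75/97.5. Simulated percents are deliberately **not** clipped to
[0, 100] — the refit target is least squares and clipping would bias it.
Refits start from the original optimum plus a small number of random
restarts (default 3) rather than the full multi-start schedule; with the
optimum as a start this is reliable and ~30× cheaper, and the restart count
is configurable for stress-testing. Refit failures are excluded with a
logged count.

## Synthetic data and the stochastic oracle

`generate_dataset` emulates the double-label experiments: 6 replicate
curves, first-label efficiency ~0.9, observation times spanning
`[0, μ+4σ]` in 12 steps (the real designs sample 48–78 population points
over ~5 days), Gaussian noise. The noise argument is the **s.e.m. of the
replicate mean**; per-replicate noise gets s.d. `sem·√n` so the mean curve
has the stated s.e.m. (a `denominator="n-1"` switch is exposed because the
`sd/√(n−1)` convention also circulates). What the generator does *not*
emulate: flow-cytometry gating error structure, inter-animal parameter
heterogeneity, or correlated errors within a curve — so passing recovery
tests show identifiability under ideal i.i.d. noise, not robustness to
those real-data features.

The individual-based oracle simulates births uniform over a window with
1.5×(age-range) burn-in, per-cell lognormal (or fixed) lifespans and
exponential random-loss times, Bernoulli labeling at both events, and
carry-over labeling of newborns with probability `e2·2^{−Δ/b_half}`. It
validates `D(t)`, the cohort curve and `f` to binomial Monte Carlo error
with 2×10⁵ cells, independently of every quadrature in the package.

## Identifiability study

`constraint_study` sweeps true `f ∈ {0, 0.2, 0.4, 0.6, 0.8}` (lifespan
fixed at mean 100 hr, s.d. 25 hr, `r` solved from `f` by root-finding) and
a list of noise s.e.m. levels; each cell simulates one dataset, fits DLS,
runs the Monte Carlo procedure and records the IQR and 95% interval of the
refit `f`. Two robust findings: constraint degrades rapidly with noise,
and high loss fractions are better constrained than low ones at matched
noise — small `f` trades off almost perfectly against the mean lifespan
(the `f`–`μ` ensemble correlation is r² ≈ 0.9+).

## Problem sizes in the test suite

Tests run the full machinery at reduced sizes chosen as the smallest that
still exercise each property cleanly: multi-start patience 10–25 for most
fits (the default 100 is used nowhere tests don't need it; the schedule is
seed-invariant on the fixtures either way), 40–60 Monte Carlo iterations
inside coverage and trend checks with 20 repeated studies, a 2×2 study
grid, and 2×10⁵ oracle cells. The F-test's null-distribution calibration
uses 500 simulated nested *linear* least-squares problems — the
distributional claim concerns the statistic, not the survival fitter, and
linear fits make 500 simulations cheap.

## Known limitations

* No weighted or heteroscedastic least squares; variance is assumed equal
  across time points, as in the reference procedure.
* No time-varying production or non-steady-state dynamics.
* The lognormal is a modelling choice; other right-skewed laws fit
  comparably and are not implemented (only the delta law, for nesting).
* Best-fit parameters from real survival data are only as identifiable as
  the noise allows; at realistic s.e.m. (~0.5%) the 95% CI on `f` can span
  most of [0, 0.5] — that is a property of the problem, not the optimizer.
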