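# platekin

Steady-state survival-curve modelling for cell populations with two
competing fates: **age-dependent senescent death** at the end of a
distributed natural lifespan, and **age-independent random loss** at a
constant rate. The motivating system is the blood platelet, where the
random component measures the ongoing hemostatic consumption of platelets,
but the machinery applies to any cell type cleared by these two routes.

It is written for quantitative biologists analysing in-vivo pulse-label
(and double-label) survival curves who want to ask: *what fraction of cells
is lost to the random process, and how well do my data actually constrain
that number?*

## The model

Let `L(l)` be the natural-lifespan density and `r` (hr⁻¹) the random-loss
rate constant. The probability of surviving to age `a` is

    P(a) = exp(-r a) · Pr(L > a)

and at steady state (constant production `S`, constant count `N`) the
population age density is proportional to `P`, giving the pulse-label
survival curve

    D(t) = ∫ₜ^∞ P(u) du / ∫₀^∞ P(u) du .

Three named models:

| model       | lifespan law          | random loss | parameters |
|-------------|-----------------------|-------------|------------|
| `LS`        | lognormal (m, s)      | none        | m, s       |
| `DORNHORST` | fixed at T            | rate r      | T, r       |
| `DLS`       | lognormal (m, s)      | rate r      | m, s, r    |

The **random loss fraction** `f = 1 − E[exp(−r L)]` is the proportion of
cells removed by the random route before their natural lifespan ends
(`f = 1 − e^{−rT}` for the fixed-lifespan case). Steady-state bookkeeping
ties it to observables: `N = S · (f/r)`, and with the absolute loss rate
`R = r N` one gets the identity `f = R/S` — the loss fraction is the ratio
of the consumption requirement to the production rate.

On top of the curves the package provides: multi-start bounded
least-squares fitting to replicate survival data (population and optional
double-label cohort curves, with label efficiencies `e1`, `e2` and
second-label carry-over half-life `b_half`), Monte Carlo confidence
intervals by refitting simulated experiments, extra-sum-of-squares F-tests
for the nested model pairs (LS ⊂ DLS, Dornhorst ⊂ DLS), an individual-based
stochastic simulator used as an independent oracle, and an identifiability
study mapping constraint of `f` against experimental noise.

## Worked example

```python
import platekin as pk

# hybrid model at wild-type mouse platelet best-fit parameters
model = pk.LifespanModel(pk.lognormal_from_moments(99.5, 26.1), r=0.0038)
ss = pk.steady_state(model, N=1183.0)   # count in 1e3 per uL
print(f"f = {ss.f:.2f}, S = {ss.S:.1f} x10^3/uL/hr, R = {ss.R:.0f} x10^3/uL/day")
```

prints

```
f = 0.31, S = 14.4 x10^3/uL/hr, R = 108 x10^3/uL/day
```

i.e. at these parameters ~31% of platelets are consumed before senescence,
production runs at 14.4×10³ platelets/µL/hr, and the absolute consumption
requirement is ~108×10³ platelets/µL/day. The `examples/` directory has
one narrative script per capability (steady-state arithmetic, fitting,
Monte Carlo CIs, cohort prediction, identifiability study); each prints its
numbers with a line on what they mean. A thin CLI mirrors the library:

```sh
platekin fit --data curves.csv --model dls --out fit.json
platekin mc --fit fit.json --data curves.csv --iters 1000 --seed 1 --out ens.csv
platekin ftest --null fit_ls.json --alt fit_dls.json
```

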