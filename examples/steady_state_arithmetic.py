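"""Steady-state survival math: loss fractions, production and consumption rates.

Builds the three lifespan models at published best-fit parameters for
wild-type mouse platelets and prints the quantities the steady-state theory
ties together: the random loss fraction f, the production rate S, and the
absolute random loss rate R = r N (the "fixed requirement" for platelets).
"""

import platekin as pk

# Lognormal-senescent (LS): lognormal natural lifespan, no random loss
ls = pk.LifespanModel(pk.lognormal_from_moments(89.5, 28.2), r=0.0)
# Dornhorst: fixed lifespan T with constant random loss rate r
dorn = pk.LifespanModel(pk.DeltaLaw(109.4), r=0.0072)
# Hybrid DLS: lognormal lifespan plus random loss
dls = pk.LifespanModel(pk.lognormal_from_moments(99.5, 26.1), r=0.0038)

N = 1183.0  # wild-type platelet count, 1e3 per uL
for name, model in [("LS", ls), ("Dornhorst", dorn), ("DLS", dls)]:
    ss = pk.steady_state(model, N)
    print(f"{name:>9}: f = {ss.f:.2f}   S = {ss.S:5.1f} x10^3/uL/hr   "
          f"R = {ss.R:5.1f} x10^3/uL/day   mean residence = "
          f"{ss.mean_realized_lifespan:5.1f} hr")

# The Dornhorst model's fixed-lifespan approximation inflates f (0.55 here);
# letting the lifespan be distributed (DLS) brings it down to ~0.31.

# Cross-species comparison via S ~ N/mu and f = R/S (R in 1e3/uL/day):
human = pk.steady_state(pk.LifespanModel(pk.lognormal_from_moments(9 * 24.0, 1.0)), 250.0)
mouse = pk.steady_state(pk.LifespanModel(pk.lognormal_from_moments(4 * 24.0, 1.0)), 1200.0)
R_requirement = 7.0  # estimated human hemostatic platelet requirement, 1e3/uL/day
print(f"\nhuman: S = {human.S * 24:.0f} x10^3/uL/day -> f = R/S = "
      f"{R_requirement / (human.S * 24):.2f}")
print(f"mouse: S = {mouse.S * 24:.0f} x10^3/uL/day -> same requirement would "
      f"give f = {R_requirement / (mouse.S * 24):.2f}")
# Mice turn platelets over ~10x faster per uL, so an equal absolute
# requirement implies a much smaller random loss fraction.
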