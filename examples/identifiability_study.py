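"""How experimental noise limits constraint of the random loss fraction.

Simulates survival data from the DLS model (mean 100 hr, s.d. 25 hr) at two
true loss fractions and two noise levels, fits and runs the Monte Carlo CI
procedure for each cell, and reports the interquartile range of the refit f.
Problem sizes are reduced (50 Monte Carlo iterations) to keep this desk-scale;
the qualitative trends do not depend on that.
"""

import platekin as pk
from platekin.fitting import FitOptions

grid = pk.StudyGrid(f_values=(0.2, 0.8), sem_values=(0.1, 0.4),
                    mc_iterations=50)
table = pk.constraint_study(grid, seed=9,
                            fit_options=FitOptions(seed=9, starts_patience=10),
                            mc_restarts=2)
print(table[["f_true", "sem", "f_hat", "iqr", "ci_lo", "ci_hi"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Two trends: the IQR of the refit f grows with the noise s.e.m., and at
# matched noise the high-f regime is better constrained than the low-f one —
# large loss fractions bend the survival curve visibly, small ones trade off
# against the mean lifespan.
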