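"""Monte Carlo confidence intervals by refitting simulated survival curves.

The experimental scatter about the best-fit curve is modeled as Gaussian
noise with standard deviation

    sigma_e = sqrt(ssr / df)

(in percent units).  Each Monte Carlo iteration simulates a fresh experiment
— ``n_replicates`` noisy survival curves around the best-fit prediction —
and refits the same model; the empirical distribution of refit parameters
over (by default) 1000 iterations gives percentile confidence intervals and
parameter-correlation diagnostics.  Refits start from the original optimum
plus a small number of random restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import (
    COHORT,
    POPULATION,
    FitConvergenceError,
    FitOptions,
    FitResult,
    SurvivalDataset,
    _draw_start,
    _param_names,
    fit,
    predict_observed,
)
from .models import LognormalLaw, lognormal_to_moments, random_loss_fraction

__all__ = [
    "MonteCarloEnsemble",
    "noise_sd_from_fit",
    "monte_carlo",
    "parameter_correlation",
]

logger = logging.getLogger(__name__)

PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


@dataclass
class MonteCarloEnsemble:
    """Refit parameter matrix (one row per iteration) with percentile summaries."""

    samples: pd.DataFrame
    n_iterations: int
    n_replicates: int
    sigma_e: float
    n_failed: int = 0

    @property
    def percentiles(self) -> pd.DataFrame:
        return self.samples.quantile([p / 100.0 for p in PERCENTILES])

    def ci(self, name: str, level: float = 95.0) -> tuple[float, float]:
        """Equal-tailed percentile confidence interval for one parameter."""
        tail = (100.0 - level) / 2.0
        col = self.samples[name]
        return float(col.quantile(tail / 100.0)), float(col.quantile(1 - tail / 100.0))

    def iqr(self, name: str) -> float:
        col = self.samples[name]
        return float(col.quantile(0.75) - col.quantile(0.25))


def noise_sd_from_fit(fit_result: FitResult) -> float:
    """Per-point Gaussian noise s.d. implied by the fit: sqrt(ssr/df), percent."""
    if fit_result.df <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(np.sqrt(fit_result.ssr / fit_result.df))


def _derived_row(params: dict, model_kind: str, ssr: float,
                 platelet_count) -> dict:
    from .fitting import _unpack  # packing shared with the fitter

    row = dict(params)
    names = _param_names(model_kind, False)
    x = np.array([params[n] for n in names if n in params])
    model, _, _ = _unpack(model_kind, False, x, 24.0)
    if isinstance(model.law, LognormalLaw):
        mu, sigma = lognormal_to_moments(model.law)
        row["mu"], row["sigma"] = mu, sigma
    else:
        row["mu"], row["sigma"] = model.law.T, 0.0
    row["f"] = random_loss_fraction(model)
    if platelet_count is not None:
        N = platelet_count[0]
        row["R"] = 24.0 * model.r * N
        row["S"] = N / (row["mu"] if model.r == 0
                        else row["f"] / model.r)
    row["ssr"] = ssr
    return row


def simulate_replicates(
    fit_result: FitResult,
    dataset: SurvivalDataset,
    sigma_e: float,
    n_replicates: int,
    rng: np.random.Generator,
    *,
    grid_points: int | None = None,
) -> SurvivalDataset:
    """One simulated experiment: noisy replicate curves around the fitted prediction."""
    gp = grid_points or 1000
    curves = (POPULATION, COHORT) if fit_result.use_cohort else (POPULATION,)
    rows = []
    for kind in curves:
        times = np.unique(dataset.subset(kind)["time_hr"].to_numpy())
        pred = predict_observed(fit_result.model, fit_result.lab, times, kind,
                                grid_points=gp)
        for rep in range(1, n_replicates + 1):
            noisy = pred + rng.normal(0.0, sigma_e, size=times.shape)
            rows.append(pd.DataFrame({
                "time_hr": times, "percent": noisy,
                "replicate": rep, "curve": kind,
            }))
    return SurvivalDataset(pd.concat(rows, ignore_index=True),
                           platelet_count=dataset.platelet_count,
                           label=dataset.label)


def monte_carlo(
    fit_result: FitResult,
    dataset: SurvivalDataset,
    n_iterations: int = 1000,
    n_replicates: int = 6,
    seed: int = 0,
    *,
    n_restarts: int = 3,
    options: FitOptions | None = None,
) -> MonteCarloEnsemble:
    """Monte Carlo parameter ensemble for a converged fit.

    Noise is added independently per replicate per time point and is not
    clipped to [0, 100] (the refit target is unweighted least squares).
    Refit failures are logged and excluded from the ensemble.
    """
    sigma_e = noise_sd_from_fit(fit_result)
    rng = np.random.default_rng(seed)
    names = _param_names(fit_result.model_kind, fit_result.use_cohort)
    x_best = np.array([fit_result.params[n] for n in names])
    base = options or FitOptions(grid_points=1000)

    rows, n_failed = [], 0
    for _ in range(n_iterations):
        sim = simulate_replicates(fit_result, dataset, sigma_e, n_replicates,
                                  rng, grid_points=base.grid_points)
        starts = [x_best] + [_draw_start(rng, names) for _ in range(n_restarts)]
        opts = replace(base, extra_starts=starts, random_starts=False,
                       seed_nested=False)
        try:
            refit = fit(sim, fit_result.model_kind,
                        use_cohort=fit_result.use_cohort, options=opts)
        except FitConvergenceError:
            n_failed += 1
            continue
        rows.append(_derived_row(refit.params, refit.model_kind, refit.ssr,
                                 dataset.platelet_count))
    if n_failed:
        logger.warning("%d/%d Monte Carlo refits failed and were excluded",
                       n_failed, n_iterations)
    samples = pd.DataFrame(rows)
    return MonteCarloEnsemble(samples=samples, n_iterations=n_iterations,
                              n_replicates=n_replicates, sigma_e=sigma_e,
                              n_failed=n_failed)


def parameter_correlation(
    ensemble: MonteCarloEnsemble, x: str, y: str
) -> tuple[float, float, tuple[float, float]]:
    """OLS regression of ensemble parameter ``y`` on ``x``.

    Returns ``(r_squared, slope, (slope_lo, slope_hi))`` with a 95%
    confidence interval on the slope.
    """
    xs = ensemble.samples[x].to_numpy()
    ys = ensemble.samples[y].to_numpy()
    if len(xs) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    res = stats.linregress(xs, ys)
    tcrit = stats.t.ppf(0.975, len(xs) - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return float(res.rvalue**2), float(res.slope), (float(ci[0]), float(ci[1]))
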