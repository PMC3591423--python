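"""Multi-start bounded least-squares fitting of lifespan models to survival data.

The objective is the unweighted sum of squared residuals, in percent units,
between every replicate observation and the model prediction
``100 * e1 * D(t)`` (population label) or ``100 * C(t)`` (cohort label).
Because the fitted surface is multi-modal, local optimizations are restarted
from random parameter draws until no improvement has been seen for a
patience window (100 consecutive starts for population-only fits, 10 when
the cohort curve is fitted as well).  The hybrid senescent+random-loss (DLS)
model nests both simpler models, so its start list is additionally seeded
from the best fits of the lognormal-senescent (LS) and fixed-lifespan
(Dornhorst) models — this guarantees ssr(DLS) <= min(ssr(LS), ssr(Dornhorst))
on every dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .cohort import LabelingConfig, cohort_curve
from .models import (
    DEFAULT_GRID_POINTS,
    DeltaLaw,
    LifespanModel,
    LognormalLaw,
    population_survival_curve,
)

__all__ = [
    "SurvivalDataset",
    "FitOptions",
    "FitResult",
    "FitConvergenceError",
    "predict_observed",
    "fit",
    "MODEL_KINDS",
]

MODEL_KINDS = ("LS", "DORNHORST", "DLS")

POPULATION = "population"
COHORT = "cohort"


class FitConvergenceError(RuntimeError):
    """Raised when no multi-start local optimization converges."""


@dataclass
class SurvivalDataset:
    """Observed labeled-fraction time series with replicates.

    Parameters
    ----------
    observations : pandas.DataFrame
        Columns ``time_hr`` (hours, >= 0), ``percent`` (labeled percent),
        ``replicate`` (id), ``curve`` (``"population"`` or ``"cohort"``).
    platelet_count : tuple, optional
        ``(N, sem)`` in 1e3 uL^-1.
    label : str
        Free-text genotype / sample label.
    """

    observations: pd.DataFrame
    platelet_count: tuple[float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        obs = self.observations
        required = {"time_hr", "percent", "replicate", "curve"}
        missing = required - set(obs.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        if (obs["time_hr"] < 0).any():
            raise ValueError("times must be >= 0")
        bad = set(obs["curve"]) - {POPULATION, COHORT}
        if bad:
            raise ValueError(f"unknown curve kinds: {sorted(bad)}")
        for kind, sub in obs.groupby("curve"):
            if sub["time_hr"].nunique() < 2:
                raise ValueError(f"{kind} curve needs >= 2 distinct times")

    @property
    def has_cohort(self) -> bool:
        return (self.observations["curve"] == COHORT).any()

    def subset(self, curve_kind: str) -> pd.DataFrame:
        return self.observations[self.observations["curve"] == curve_kind]

    def n_points(self, use_cohort: bool) -> int:
        if use_cohort:
            return len(self.observations)
        return len(self.subset(POPULATION))


@dataclass
class FitOptions:
    """Multi-start schedule and numerics.

    ``starts_patience`` defaults to 100 for population-only fits and 10 when
    the cohort curve is included; ``extra_starts`` are parameter vectors (in
    the fit's packing order) tried before any random start.
    """

    starts_patience: int | None = None
    max_starts: int = 3000
    grid_points: int = DEFAULT_GRID_POINTS
    seed: int = 0
    extra_starts: list = field(default_factory=list)
    random_starts: bool = True
    seed_nested: bool = True
    ftol: float = 1e-10
    xtol: float = 1e-10


@dataclass
class FitResult:
    """Best fit: model + labeling parameters, SSR, degrees of freedom, predictions."""

    model: LifespanModel
    lab: LabelingConfig
    ssr: float
    df: int
    n_params: int
    params: dict[str, float]
    predicted: pd.DataFrame
    model_kind: str
    use_cohort: bool
    seed: int
    n_starts: int
    dataset_label: str = ""

    @property
    def sigma_e(self) -> float:
        return math.sqrt(self.ssr / self.df)


# ---------------------------------------------------------------------------
# parameter packing

_LN12, _LN400 = math.log(12.0), math.log(400.0)

#: (name, lower bound, upper bound, start-draw low, start-draw high)
_PARAM_TABLE = {
    "m": ("m", _LN12, _LN400, _LN12, _LN400),
    "s": ("s", 1e-3, 1.5, 0.01, 1.0),
    "T": ("T", 12.0, 400.0, 12.0, 400.0),
    "r": ("r", 0.0, 0.05, 0.0, 0.05),
    "e1": ("e1", 0.0, 1.0, 0.5, 1.0),
    "e2": ("e2", 0.0, 1.0, 0.5, 1.0),
    "b_half": ("b_half", 0.5, 72.0, 1.0, 48.0),
}


def _param_names(model_kind: str, use_cohort: bool) -> list[str]:
    base = {
        "LS": ["m", "s", "e1"],
        "DORNHORST": ["T", "r", "e1"],
        "DLS": ["m", "s", "r", "e1"],
    }[model_kind]
    if use_cohort:
        base = base + ["e2", "b_half"]
    return base


def _unpack(model_kind: str, use_cohort: bool, x: np.ndarray, d: float):
    names = _param_names(model_kind, use_cohort)
    p = dict(zip(names, x))
    if model_kind == "DORNHORST":
        model = LifespanModel(DeltaLaw(p["T"]), p["r"])
    else:
        model = LifespanModel(LognormalLaw(p["m"], p["s"]), p.get("r", 0.0))
    lab = LabelingConfig(
        e1=p["e1"], e2=p.get("e2", 0.6), b_half=p.get("b_half", 6.0), d=d
    )
    return model, lab, p


# ---------------------------------------------------------------------------
# prediction & residuals

def predict_observed(
    model: LifespanModel,
    lab: LabelingConfig,
    times,
    curve_kind: str = POPULATION,
    *,
    grid_points: int = DEFAULT_GRID_POINTS,
):
    """Model prediction on the observation scale (percent of all platelets)."""
    times = np.asarray(times, dtype=float)
    if curve_kind == POPULATION:
        return 100.0 * lab.e1 * population_survival_curve(
            model, times, grid_points=grid_points
        )
    if curve_kind == COHORT:
        return 100.0 * np.asarray(
            cohort_curve(model, lab, times, grid_points=grid_points)
        )
    raise ValueError(f"unknown curve kind {curve_kind!r}")


def _residual_fn(dataset: SurvivalDataset, model_kind: str, use_cohort: bool,
                 grid_points: int, d: float):
    pop = dataset.subset(POPULATION)
    pop_times = pop["time_hr"].to_numpy()
    pop_obs = pop["percent"].to_numpy()
    pop_uniq, pop_inv = np.unique(pop_times, return_inverse=True)
    if use_cohort:
        coh = dataset.subset(COHORT)
        coh_times = coh["time_hr"].to_numpy()
        coh_obs = coh["percent"].to_numpy()
        coh_uniq, coh_inv = np.unique(coh_times, return_inverse=True)

    def residuals(x: np.ndarray) -> np.ndarray:
        model, lab, _ = _unpack(model_kind, use_cohort, x, d)
        pred_pop = 100.0 * lab.e1 * population_survival_curve(
            model, pop_uniq, grid_points=grid_points
        )
        res = [pred_pop[pop_inv] - pop_obs]
        if use_cohort:
            pred_coh = 100.0 * np.asarray(
                cohort_curve(model, lab, coh_uniq, grid_points=grid_points)
            )
            res.append(pred_coh[coh_inv] - coh_obs)
        return np.concatenate(res)

    return residuals


def _draw_start(rng: np.random.Generator, names: Sequence[str]) -> np.ndarray:
    return np.array(
        [rng.uniform(_PARAM_TABLE[n][3], _PARAM_TABLE[n][4]) for n in names]
    )


def _nested_starts(dataset, use_cohort, options, d) -> list[np.ndarray]:
    """Best LS and Dornhorst fits re-expressed as DLS start points."""
    starts = []
    sub = replace(options, seed_nested=False, extra_starts=[])
    for kind in ("LS", "DORNHORST"):
        try:
            res = fit(dataset, kind, use_cohort=use_cohort, options=sub)
        except FitConvergenceError:
            continue
        p = res.params
        if kind == "LS":
            x = [p["m"], p["s"], 0.0, p["e1"]]
        else:
            s0 = _PARAM_TABLE["s"][1]  # delta law as the s -> 0 lognormal limit
            x = [math.log(p["T"]), s0, p["r"], p["e1"]]
        if use_cohort:
            x += [p.get("e2", 0.6), p.get("b_half", 6.0)]
        starts.append(np.array(x))
    return starts


def fit(
    dataset: SurvivalDataset,
    model_kind: str,
    *,
    use_cohort: bool = False,
    options: FitOptions | None = None,
    d: float = 24.0,
) -> FitResult:
    """Fit a lifespan model to a survival dataset by multi-start least squares.

    Parameters
    ----------
    dataset : SurvivalDataset
        Replicate observations; residuals are computed against every point,
        not the replicate mean.
    model_kind : {"LS", "DORNHORST", "DLS"}
    use_cohort : bool
        Also fit the cohort curve (adds the ``e2`` and ``b_half`` parameters).
    options : FitOptions
    d : float
        Inter-label delay in hours (fixed, not fitted).

    Raises
    ------
    FitConvergenceError
        If no local optimization converges from any start.
    ValueError
        If the fit would have non-positive degrees of freedom.
    """
    model_kind = model_kind.upper()
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    options = options or FitOptions()
    names = _param_names(model_kind, use_cohort)
    n_params = len(names)
    n_points = dataset.n_points(use_cohort)
    df = n_points - n_params
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({n_points} points, "
                         f"{n_params} params)")

    residuals = _residual_fn(dataset, model_kind, use_cohort, options.grid_points, d)
    lb = np.array([_PARAM_TABLE[n][1] for n in names])
    ub = np.array([_PARAM_TABLE[n][2] for n in names])

    patience = options.starts_patience
    if patience is None:
        patience = 10 if use_cohort else 100

    rng = np.random.default_rng(options.seed)

    def local(x0: np.ndarray):
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lb, ub), method="trf",
                ftol=options.ftol, xtol=options.xtol,
            )
        except Exception:
            return None
        if not np.all(np.isfinite(sol.x)):
            return None
        return sol

    seeds: list[np.ndarray] = [np.asarray(x, dtype=float) for x in options.extra_starts]
    if model_kind == "DLS" and options.seed_nested:
        seeds = _nested_starts(dataset, use_cohort, options, d) + seeds

    best = None
    best_ssr = np.inf
    n_starts = 0
    since_improved = 0
    improve_tol = 1e-9

    def consider(sol):
        nonlocal best, best_ssr, since_improved
        if sol is None:
            since_improved += 1
            return
        ssr = float(np.sum(sol.fun**2))
        if best is None or ssr < best_ssr - improve_tol * (1.0 + best_ssr):
            best, best_ssr = sol, ssr
            since_improved = 0
        else:
            since_improved += 1

    for x0 in seeds:
        n_starts += 1
        consider(local(x0))

    if options.random_starts:
        since_improved = 0  # patience counts random starts only
        while since_improved < patience and n_starts < options.max_starts:
            n_starts += 1
            consider(local(_draw_start(rng, names)))

    if best is None:
        raise FitConvergenceError(
            f"no start converged after {n_starts} attempts ({model_kind})"
        )

    model, lab, params = _unpack(model_kind, use_cohort, best.x, d)
    pred_rows = []
    for kind in (POPULATION, COHORT) if use_cohort else (POPULATION,):
        uniq = np.unique(dataset.subset(kind)["time_hr"].to_numpy())
        pred = predict_observed(model, lab, uniq, kind,
                                grid_points=options.grid_points)
        pred_rows.append(pd.DataFrame(
            {"time_hr": uniq, "predicted_percent": pred, "curve": kind}))
    predicted = pd.concat(pred_rows, ignore_index=True)

    return FitResult(
        model=model, lab=lab, ssr=best_ssr, df=df, n_params=n_params,
        params={k: float(v) for k, v in params.items()},
        predicted=predicted, model_kind=model_kind, use_cohort=use_cohort,
        seed=options.seed, n_starts=n_starts, dataset_label=dataset.label,
    )
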