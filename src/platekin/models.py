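"""Steady-state survival mathematics for cell populations with two competing fates.

A cell (the motivating system is the blood platelet) can die of *senescence*
at the end of a natural lifespan drawn from a distribution ``L``, or be
removed earlier by an age-independent *random loss* process with first-order
rate constant ``r`` (hr^-1).  At steady state with constant production this
yields, for the probability ``P(a)`` of surviving to age ``a``,

    P(a) = exp(-r a) * Pr(L > a),

a population age density proportional to ``P``, and a pulse-label survival
curve

    D(t) = \\int_t^inf P(u) du / \\int_0^inf P(u) du.

Three named models are supported:

* ``LS``        — lognormal natural lifespan, no random loss (r = 0);
* ``DORNHORST`` — fixed natural lifespan ``T`` with random loss;
* ``DLS``       — lognormal natural lifespan *and* random loss.

Units: time in hours throughout; platelet counts in 1e3 per microlitre;
the absolute random loss rate ``R = r * N`` is reported per day (x24).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "LognormalLaw",
    "DeltaLaw",
    "LifespanModel",
    "SteadyState",
    "survival_to_age",
    "steady_age_density",
    "population_survival_curve",
    "random_loss_fraction",
    "steady_state",
    "lognormal_from_moments",
    "lognormal_to_moments",
    "model_to_dict",
    "model_from_dict",
    "model_to_json",
    "model_from_json",
    "DEFAULT_GRID_POINTS",
]

DEFAULT_GRID_POINTS = 1000


@dataclass(frozen=True)
class LognormalLaw:
    """Lognormal natural-lifespan law.

    Parameters
    ----------
    m : float
        Mean of log-lifespan (log-hours).
    s : float
        Standard deviation of log-lifespan (log-hours), > 0.
    """

    m: float
    s: float

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"s must be > 0, got {self.s}")

    @property
    def _dist(self) -> stats.rv_continuous:
        return stats.lognorm(self.s, scale=math.exp(self.m))

    def pdf(self, l):
        """Lifespan density L(l)."""
        return self._dist.pdf(l)

    def sf(self, a):
        """Pr(lifespan > a)."""
        return self._dist.sf(a)

    @property
    def mean(self) -> float:
        """Mean lifespan mu = exp(m + s^2/2), hours."""
        return math.exp(self.m + self.s**2 / 2.0)

    @property
    def sd(self) -> float:
        """Standard deviation of lifespan, hours."""
        return self.mean * math.sqrt(math.expm1(self.s**2))

    def support_upper(self) -> float:
        # integration range per the standard numerical scheme
        return math.exp(self.m + 4.0 * self.s)


@dataclass(frozen=True)
class DeltaLaw:
    """Degenerate lifespan law: every cell dies of senescence at exactly ``T`` hours."""

    T: float

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"T must be > 0, got {self.T}")

    def sf(self, a):
        a = np.asarray(a, dtype=float)
        return np.where(a < self.T, 1.0, 0.0)

    @property
    def mean(self) -> float:
        return self.T

    @property
    def sd(self) -> float:
        return 0.0

    def support_upper(self) -> float:
        return self.T


Law = Union[LognormalLaw, DeltaLaw]


@dataclass(frozen=True)
class LifespanModel:
    """A natural-lifespan law plus a random-loss rate constant ``r`` (hr^-1, >= 0).

    The model kind is derivable: a :class:`LognormalLaw` with ``r == 0`` is
    the LS model, a :class:`DeltaLaw` is the Dornhorst model, and a
    :class:`LognormalLaw` with ``r > 0`` is the DLS hybrid.
    """

    law: Law
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"r must be >= 0, got {self.r}")

    @property
    def kind(self) -> str:
        if isinstance(self.law, DeltaLaw):
            return "DORNHORST"
        return "LS" if self.r == 0 else "DLS"


@dataclass(frozen=True)
class SteadyState:
    """Steady-state summary of a population of count ``N``.

    Attributes
    ----------
    N : float
        Platelet count (1e3 uL^-1).
    S : float
        Production rate (1e3 uL^-1 hr^-1).
    R : float
        Absolute random loss rate (1e3 uL^-1 day^-1), R = 24 r N.
    f : float
        Random loss fraction, equal to R/S when both are per day.
    mean_realized_lifespan : float
        Mean time a cell actually spends in circulation (hours), = N/S.
    """

    N: float
    S: float
    R: float
    f: float
    mean_realized_lifespan: float


# ---------------------------------------------------------------------------
# conversions

def lognormal_from_moments(mu: float, sigma: float) -> LognormalLaw:
    """Build a lognormal law from its arithmetic mean and s.d. (hours)."""
    if mu <= 0 or sigma <= 0:
        raise ValueError("mu and sigma must be positive")
    s2 = math.log1p((sigma / mu) ** 2)
    return LognormalLaw(m=math.log(mu) - s2 / 2.0, s=math.sqrt(s2))


def lognormal_to_moments(law: LognormalLaw) -> tuple[float, float]:
    """Return (mean, s.d.) of the lifespan in hours."""
    return law.mean, law.sd


# ---------------------------------------------------------------------------
# core operations

def _check_age(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    return a


def age_grid(model: LifespanModel, n: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Uniform quadrature grid: [0, exp(m+4s)] for lognormal laws, [0, T] for the delta law."""
    return np.linspace(0.0, model.law.support_upper(), n)


def survival_to_age(model: LifespanModel, a):
    """Probability P(a) of a cell surviving to age ``a``: exp(-r a) Pr(L > a)."""
    a = _check_age(a)
    return np.exp(-model.r * a) * model.law.sf(a)


def random_loss_fraction(model: LifespanModel, *, grid_points: int = DEFAULT_GRID_POINTS) -> float:
    """Fraction f of cells removed by random loss before senescent death.

    f = 1 - E[exp(-r L)].  For the delta law this is the closed form
    1 - exp(-r T); for a lognormal law the expectation is computed by
    composite-trapezoid quadrature on the standard grid.
    """
    if model.r == 0:
        return 0.0
    if isinstance(model.law, DeltaLaw):
        return -math.expm1(-model.r * model.law.T)
    grid = age_grid(model, grid_points)
    integrand = np.exp(-model.r * grid) * model.law.pdf(grid)
    return 1.0 - float(np.trapezoid(integrand, grid))


def mean_realized_lifespan(model: LifespanModel, *, grid_points: int = DEFAULT_GRID_POINTS) -> float:
    """Mean residence time \\int_0^inf P(u) du = f/r (mu in the r -> 0 limit)."""
    if model.r == 0:
        return model.law.mean
    return random_loss_fraction(model, grid_points=grid_points) / model.r


def _survival_integral(model: LifespanModel, grid_points: int):
    """Grid, P on the grid, and the running integral of P (trapezoid)."""
    grid = age_grid(model, grid_points)
    P = survival_to_age(model, grid)
    cumI = cumulative_trapezoid(P, grid, initial=0.0)
    return grid, P, cumI


def steady_age_density(model: LifespanModel, a, *, grid_points: int = DEFAULT_GRID_POINTS):
    """Steady-state probability density of cell age at ``a`` (per hour).

    Proportional to ``survival_to_age``; the normalizer \\int_0^inf P(u) du
    equals f/r when r > 0 and the mean lifespan mu when r = 0.
    """
    a = _check_age(a)
    grid, _, cumI = _survival_integral(model, grid_points)
    theta = cumI[-1]
    return survival_to_age(model, a) / theta


def population_survival_curve(
    model: LifespanModel, t, *, grid_points: int = DEFAULT_GRID_POINTS
):
    """Pulse-label survival curve D(t) = \\int_t^inf P / \\int_0^inf P.

    The fraction of cells labeled at time 0 (all extant cells) still in
    circulation at time ``t``.  D(0) = 1, nonincreasing, -> 0.
    """
    t = _check_age(t)
    if isinstance(model.law, DeltaLaw):
        return _dornhorst_curve(model.law.T, model.r, t)
    grid, _, cumI = _survival_integral(model, grid_points)
    theta = cumI[-1]
    D = 1.0 - np.interp(t, grid, cumI, right=theta) / theta
    return np.clip(D, 0.0, 1.0)


def _dornhorst_curve(T: float, r: float, t: np.ndarray):
    """Closed-form survival curve for the fixed-lifespan model.

    D(t) = (e^{-rt} - e^{-rT}) / (1 - e^{-rT}) for t < T, 0 after; the
    r -> 0 limit is the straight line 1 - t/T.
    """
    t = np.asarray(t, dtype=float)
    if r * T < 1e-12:
        D = 1.0 - t / T
    else:
        D = (np.exp(-r * t) - math.exp(-r * T)) / -math.expm1(-r * T)
    return np.where(t < T, np.clip(D, 0.0, 1.0), 0.0)


def steady_state(
    model: LifespanModel, N: float, *, grid_points: int = DEFAULT_GRID_POINTS
) -> SteadyState:
    """Steady-state production and loss rates implied by count ``N``.

    The count must balance production times mean residence:
    ``N = S * (f/r)`` in general, reducing to ``N = S * mu`` when r = 0 and
    to ``N = S (1 - e^{-rT})/r`` for the fixed-lifespan model.  ``R = r N``
    is reported per day.
    """
    if N <= 0:
        raise ValueError("N must be > 0")
    f = random_loss_fraction(model, grid_points=grid_points)
    theta = model.law.mean if model.r == 0 else f / model.r
    S = N / theta
    R = model.r * N * 24.0
    return SteadyState(N=N, S=S, R=R, f=f, mean_realized_lifespan=theta)


# ---------------------------------------------------------------------------
# JSON descriptors

def model_to_dict(model: LifespanModel) -> dict:
    d: dict = {"model": model.kind, "r": model.r}
    if isinstance(model.law, DeltaLaw):
        d["T"] = model.law.T
    else:
        d.update(m=model.law.m, s=model.law.s)
    return d


def model_from_dict(d: dict) -> LifespanModel:
    """Parse a model descriptor.

    Accepts ``{"model": "LS"|"DORNHORST"|"DLS", ...}`` with either log-scale
    parameters ``m``/``s`` or arithmetic moments ``mu``/``sigma`` for the
    lognormal laws, and ``T`` for the fixed-lifespan model.
    """
    kind = str(d.get("model", "")).upper()
    r = float(d.get("r", 0.0))
    if kind == "DORNHORST":
        return LifespanModel(DeltaLaw(float(d["T"])), r)
    if kind not in ("LS", "DLS"):
        raise ValueError(f"unknown model kind {d.get('model')!r}")
    if "m" in d and "s" in d:
        law = LognormalLaw(float(d["m"]), float(d["s"]))
    elif "mu" in d and "sigma" in d:
        law = lognormal_from_moments(float(d["mu"]), float(d["sigma"]))
    else:
        raise ValueError("lognormal model needs (m, s) or (mu, sigma)")
    if kind == "LS" and r != 0:
        raise ValueError("LS model requires r = 0")
    return LifespanModel(law, r)


def model_to_json(model: LifespanModel) -> str:
    return json.dumps(model_to_dict(model))


def model_from_json(text: str) -> LifespanModel:
    return model_from_dict(json.loads(text))
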