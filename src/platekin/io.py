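"""CSV/JSON input-output and human-readable reports.

Survival data travel as CSV with the header ``time_hr,percent,replicate,curve``
(UTF-8, dot decimal); percent is the canonical curve unit.  Fit results and
Monte Carlo ensembles serialize to JSON; parameter reports render as
``value [lo,hi]`` rows mirroring the published table layout.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict

import numpy as np
import pandas as pd

from .cohort import LabelingConfig
from .fitting import FitResult, SurvivalDataset
from .models import LognormalLaw, lognormal_to_moments, model_to_dict, model_from_dict
from .selection import FTestResult
from .uncertainty import MonteCarloEnsemble

__all__ = [
    "SchemaError",
    "read_survival_csv",
    "write_survival_csv",
    "fit_to_dict",
    "fit_result_to_json",
    "report",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("time_hr", "percent", "replicate", "curve")
SOFT_BAND = (0.0, 100.0)
HARD_BAND = (-10.0, 110.0)


class SchemaError(ValueError):
    """Malformed survival-curve CSV."""


def read_survival_csv(
    path,
    platelet_count: tuple[float, float] | None = None,
    label: str = "",
) -> SurvivalDataset:
    """Read a survival dataset, reporting malformed rows with line numbers.

    Percents outside [0, 100] draw a warning; outside [-10, 110] they are a
    hard error.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected header "
                          f"{','.join(REQUIRED_COLUMNS)}") from exc
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")

    bad_lines = []
    for col in ("time_hr", "percent"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] + 2  # header is line 1
        bad_lines.extend((int(i), col) for i in bad)
        df[col] = coerced
    nan_rows = df.index[df[["time_hr", "percent"]].isna().any(axis=1)] + 2
    bad_lines.extend((int(i), "missing") for i in nan_rows
                     if not any(i == b[0] for b in bad_lines))
    if bad_lines:
        detail = ", ".join(f"line {i} ({col})" for i, col in sorted(set(bad_lines)))
        raise SchemaError(f"{path}: non-numeric or missing values at {detail}")

    out_hard = df.index[(df["percent"] < HARD_BAND[0]) |
                        (df["percent"] > HARD_BAND[1])] + 2
    if len(out_hard):
        raise SchemaError(f"{path}: percents outside {list(HARD_BAND)} at lines "
                          f"{list(map(int, out_hard))}")
    out_soft = ((df["percent"] < SOFT_BAND[0]) | (df["percent"] > SOFT_BAND[1])).sum()
    if out_soft:
        warnings.warn(f"{path}: {out_soft} percents outside [0, 100]",
                      stacklevel=2)
    return SurvivalDataset(df[list(REQUIRED_COLUMNS)].copy(),
                           platelet_count=platelet_count, label=label)


def write_survival_csv(dataset: SurvivalDataset, path) -> None:
    dataset.observations.to_csv(path, index=False,
                                columns=list(REQUIRED_COLUMNS))


# ---------------------------------------------------------------------------
# JSON serialization of results

def fit_to_dict(fit_result: FitResult) -> dict:
    d = {
        "model": model_to_dict(fit_result.model),
        "lab": asdict(fit_result.lab),
        "params": fit_result.params,
        "ssr": fit_result.ssr,
        "df": fit_result.df,
        "n_params": fit_result.n_params,
        "model_kind": fit_result.model_kind,
        "use_cohort": fit_result.use_cohort,
        "seed": fit_result.seed,
        "n_starts": fit_result.n_starts,
        "dataset_label": fit_result.dataset_label,
        "predicted": fit_result.predicted.to_dict(orient="list"),
    }
    return d


def fit_result_to_json(fit_result: FitResult, path=None) -> str:
    text = json.dumps(fit_to_dict(fit_result), indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def fit_result_from_json(path) -> dict:
    """Load a fit-result JSON (as a plain dict; the model is reconstructable)."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    d["model_obj"] = model_from_dict(d["model"])
    d["lab_obj"] = LabelingConfig(**d["lab"])
    return d


# ---------------------------------------------------------------------------
# reports

def _bracket(value: float, ci: tuple[float, float] | None, fmt: str = "{:.3g}") -> str:
    txt = fmt.format(value)
    if ci is not None:
        txt += f" [{fmt.format(ci[0])},{fmt.format(ci[1])}]"
    return txt


def report(
    fit_result: FitResult,
    ensemble: MonteCarloEnsemble | None = None,
    ftest: FTestResult | None = None,
) -> tuple[str, dict]:
    """Render a fit (optionally with Monte Carlo CIs and an F-test row).

    Returns ``(text, payload)`` where ``text`` shows parameter rows as
    ``value [lo,hi]`` and ``payload`` is the machine-readable mirror.
    """
    payload: dict = {"fit": fit_to_dict(fit_result)}
    lines = [f"model: {fit_result.model_kind}"
             + (f"  ({fit_result.dataset_label})" if fit_result.dataset_label else ""),
             f"ssr: {fit_result.ssr:.4g}   df: {fit_result.df}   "
             f"n_params: {fit_result.n_params}"]

    def ci_for(name):
        if ensemble is not None and name in ensemble.samples.columns:
            return ensemble.ci(name)
        return None

    rows: list[tuple[str, float]] = []
    if isinstance(fit_result.model.law, LognormalLaw):
        mu, sigma = lognormal_to_moments(fit_result.model.law)
        rows += [("mu", mu), ("sigma", sigma),
                 ("m", fit_result.model.law.m), ("s", fit_result.model.law.s)]
    else:
        rows += [("T", fit_result.model.law.T)]
    if fit_result.model_kind != "LS":
        from .models import random_loss_fraction

        rows += [("r", fit_result.model.r),
                 ("f", random_loss_fraction(fit_result.model))]
    rows += [("e1", fit_result.lab.e1)]
    if fit_result.use_cohort:
        rows += [("e2", fit_result.lab.e2), ("b_half", fit_result.lab.b_half)]

    payload["parameters"] = {}
    for name, value in rows:
        ci = ci_for(name)
        lines.append(f"  {name:>7}: {_bracket(value, ci)}")
        payload["parameters"][name] = {"value": value, "ci95": ci}

    if ensemble is not None:
        payload["percentiles"] = ensemble.percentiles.to_dict()
        lines.append(f"Monte Carlo: {len(ensemble.samples)} kept / "
                     f"{ensemble.n_iterations} iterations, sigma_e = "
                     f"{ensemble.sigma_e:.3g}%")
    if ftest is not None:
        row = ftest.row()
        lines.append("F-test: " + "  ".join(
            f"{k}={row[k]:.4g}" if isinstance(row[k], float) else f"{k}={row[k]}"
            for k in ("df_null", "df_alt", "ssr_null", "ssr_alt")))
        lines.append(f"        F = {ftest.F:.2f}   p = {ftest.p:.2g}")
        payload["ftest"] = {**row, "degenerate": ftest.degenerate}
    return "\n".join(lines), payload
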