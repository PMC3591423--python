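"""Nested-model comparison by the F-test on sums of squared residuals.

Both simpler survival models are special cases of the hybrid DLS model —
the LS model fixes the random-loss rate constant at zero, and the Dornhorst
model fixes the lifespan standard deviation at zero — so the extra
parameter's worth can be assessed with the classic extra-sum-of-squares
F-test:

    F = ((ssr_null - ssr_alt) / (df_null - df_alt)) / (ssr_alt / df_alt)

with the p-value taken from the upper tail of the F(df_null - df_alt,
df_alt) distribution.  Degrees of freedom are data points minus fitted
parameters.  The conventional significance threshold is p = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["FTestResult", "f_test"]


@dataclass(frozen=True)
class FTestResult:
    F: float
    p: float
    df_num: int
    df_den: int
    ssr_null: float
    ssr_alt: float
    #: True when ssr_alt == 0 made the statistic infinite
    degenerate: bool = False

    def row(self) -> dict:
        """Table-style row mirroring the published layout."""
        return {
            "df_null": self.df_num + self.df_den,
            "df_alt": self.df_den,
            "ssr_null": self.ssr_null,
            "ssr_alt": self.ssr_alt,
            "F": self.F,
            "P": self.p,
        }


def f_test(ssr_null: float, df_null: int, ssr_alt: float, df_alt: int) -> FTestResult:
    """Extra-sum-of-squares F-test of a nested pair of fits.

    The null (simpler) model must have more degrees of freedom than the
    alternative and, by nesting, at least as large an SSR; an alternative
    SSR of exactly zero yields an infinite statistic, flagged as degenerate.
    """
    if not (df_null > df_alt > 0):
        raise ValueError(f"need df_null > df_alt > 0, got {df_null}, {df_alt}")
    if ssr_null < 0 or ssr_alt < 0:
        raise ValueError("sums of squared residuals must be >= 0")
    if ssr_null < ssr_alt:
        raise ValueError(
            "ssr_null < ssr_alt: fits are not nested (the richer model must "
            "fit at least as well)"
        )
    df_num = df_null - df_alt
    if ssr_alt == 0.0:
        return FTestResult(F=float("inf"), p=0.0, df_num=df_num, df_den=df_alt,
                           ssr_null=ssr_null, ssr_alt=ssr_alt, degenerate=True)
    F = ((ssr_null - ssr_alt) / df_num) / (ssr_alt / df_alt)
    p = float(stats.f.sf(F, df_num, df_alt))
    return FTestResult(F=float(F), p=p, df_num=df_num, df_den=df_alt,
                       ssr_null=ssr_null, ssr_alt=ssr_alt)
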