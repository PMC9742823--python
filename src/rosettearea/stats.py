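"""Validation and diversity-panel statistics.

Two operations: ordinary least-squares regression of paired area
measurements (method-validation scatterplots), and fixed-effects ANOVA of
rosette area against genotype and nitrogen factors, from which broad-sense
heritability is taken as the genotype share of the total sum of squares:

    H^2 = SS_genotype / SS_total

This is deliberately the sum-of-squares definition, not a variance-component
(REML) estimator.  The ANOVA is sequential (type I) with genotype entered
first, then nitrogen source, then nitrogen treatment (the source x
concentration combination, which after source contributes the concentration
degrees of freedom).  Type II is available for unbalanced designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = ["RegressionResult", "AnovaResult", "ols_fit", "anova_h2"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass
class AnovaResult:
    """Per-factor ANOVA rows plus the heritability summary.

    ``table`` has one row per factor and a Residual row with columns
    ``df, sum_sq, F, PR(>F)``; ``h_squared`` is SS_genotype / SS_total.
    ``degenerate`` marks the all-constant-response case where every SS is
    zero and H^2 is reported as 0 by convention.
    """

    table: pd.DataFrame
    total_ss: float
    h_squared: float
    degenerate: bool = False


def ols_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Simple linear least-squares fit y = slope * x + intercept.

    Closed-form normal-equation solution; R^2 = 1 - SS_res / SS_tot.
    Requires n >= 3 and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("x is constant; slope undefined")
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return RegressionResult(slope=float(slope), intercept=float(intercept),
                            r_squared=float(r2), n=n)


def anova_h2(table: pd.DataFrame, typ: int = 1) -> AnovaResult:
    """Fixed-effects ANOVA of area on genotype and nitrogen factors.

    ``table`` must have columns ``area, genotype, n_source, n_conc``.  The
    model is sequential (type I by default):

        area ~ C(genotype) + C(n_source) + C(treatment)

    where ``treatment`` is the n_source:n_conc combination; entered after
    source it adds the concentration-within-source degrees of freedom.
    H^2 = SS_genotype / SS_total.  Requires >= 2 genotypes and >= 2 levels
    of each nitrogen factor.  Unbalanced tables (failed germination) are
    used as-is.
    """
    df = table.copy()
    required = {"area", "genotype", "n_source", "n_conc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = df.dropna(subset=["area"])
    if not np.isfinite(df["area"]).all():
        raise ValueError("non-finite area values")
    if df["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes; H^2 undefined")
    if df["n_source"].nunique() < 2 or df["n_conc"].nunique() < 2:
        raise ValueError("need >= 2 levels of each nitrogen factor")
    df["treatment"] = df["n_source"].astype(str) + ":" + df["n_conc"].astype(str)

    total_ss = float(np.sum((df["area"] - df["area"].mean()) ** 2))
    if total_ss == 0.0:
        # all responses identical: every SS is zero, H^2 = 0 by convention
        factors = ["C(genotype)", "C(n_source)", "C(treatment)", "Residual"]
        tab = pd.DataFrame(
            {"df": [np.nan] * 4, "sum_sq": [0.0] * 4, "F": [np.nan] * 4,
             "PR(>F)": [np.nan] * 4},
            index=factors,
        )
        return AnovaResult(table=tab, total_ss=0.0, h_squared=0.0, degenerate=True)

    # The treatment term (source x concentration combination) is entered as
    # the source:conc interaction after the source main effect; patsy's
    # redundancy elimination makes it the concentration-within-source
    # contrast (full rank), whose sequential SS equals treatment-after-source.
    fit = smf.ols(
        "area ~ C(genotype) + C(n_source) + C(n_source):C(n_conc)", data=df
    ).fit()
    tab = anova_lm(fit, typ=typ)
    tab = tab.rename(index={"C(n_source):C(n_conc)": "C(treatment)"})
    h2 = float(tab.loc["C(genotype)", "sum_sq"] / total_ss)
    return AnovaResult(table=tab, total_ss=total_ss, h_squared=h2)
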