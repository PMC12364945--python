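"""Covariate screening: multivariable linear regression of total
symptom severity on person-level predictors.

The dependent variable is the row sum of the severity ratings.  The
model reports unstandardized B, standardized beta (B * sd_x / sd_y),
two-sided p-values, 95% CIs, and per-predictor variance inflation
factors VIF_j = 1 / (1 - R^2_j).  Predictors significant at a stringent
screening alpha (0.001 in the reference workflow) feed the
covariate-adjusted network as extra nodes.  A post hoc power analysis
for the fixed-effects F test uses the noncentral F distribution with
noncentrality lambda = f^2 * N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .core import RegressionReport, SymptomTable, ValidationError


def total_severity(table: SymptomTable) -> np.ndarray:
    """Per-person total severity: row sum of all item ratings (p..5p)."""
    return table.ratings.sum(axis=1)


def fit_severity_model(table: SymptomTable, predictors: list | None = None
                       ) -> RegressionReport:
    """OLS of total severity on the named covariate columns.

    Raises on a rank-deficient design, naming the aliased columns.
    Diagnostics (slope of |residual| on fitted values as a
    heteroscedasticity proxy, Jarque-Bera residual normality, max VIF)
    are reported as flags, never as hard failures.
    """
    if table.covariates is None or table.covariates.empty:
        raise ValidationError("no covariate columns available as predictors")
    predictors = list(predictors or table.covariates.columns)
    missing = [c for c in predictors if c not in table.covariates.columns]
    if missing:
        raise ValidationError(f"unknown predictors: {missing}")
    X = table.covariates[predictors].to_numpy(dtype=float)
    y = total_severity(table).astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X]))
    if rank < X.shape[1] + 1:
        aliased = _aliased_columns(X, predictors)
        raise ValidationError(f"design matrix is rank deficient; aliased: {aliased}")
    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    sdx = X.std(axis=0, ddof=1)
    sdy = y.std(ddof=1)
    vifs = [variance_inflation_factor(Xc, j + 1) for j in range(X.shape[1])]
    coef = pd.DataFrame(
        {
            "B": fit.params[1:],
            "beta": fit.params[1:] * sdx / sdy,
            "p": fit.pvalues[1:],
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
            "vif": vifs,
        },
        index=predictors,
    )
    resid = fit.resid
    fitted = fit.fittedvalues
    slope_fit = sm.OLS(np.abs(resid), sm.add_constant(fitted)).fit()
    jb_stat, jb_p, *_ = sm.stats.jarque_bera(resid)
    diagnostics = {
        "abs_resid_slope_p": float(slope_fit.pvalues[1]),
        "heteroscedasticity_flag": bool(slope_fit.pvalues[1] < 0.05),
        "normality_p": float(jb_p),
        "non_normal_residuals_flag": bool(jb_p < 0.05),
        "max_vif": float(max(vifs)),
        "high_vif_flag": bool(max(vifs) > 10),
        "n_obs": int(len(y)),
    }
    return RegressionReport(
        coef_table=coef, r_squared=float(fit.rsquared), diagnostics=diagnostics
    )


def _aliased_columns(X: np.ndarray, names: list) -> list:
    """Columns whose removal restores full rank (linearly dependent)."""
    aliased = []
    base_rank = np.linalg.matrix_rank(X)
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == base_rank:
            aliased.append(names[j])
    return aliased


def screen_covariates(report: RegressionReport, alpha_screen: float = 0.001) -> list:
    """Predictors with p below the screening threshold; these become
    extra nodes in the covariate-adjusted network."""
    return report.selected(alpha_screen)


@dataclass
class PowerSpec:
    """Fixed-model multiple-regression power scenario (R^2 deviation
    from zero): u predictors, Cohen's f^2 effect size, test level
    alpha, total sample N."""

    u: int
    f2: float
    alpha: float
    N: int

    def __post_init__(self) -> None:
        if self.N <= self.u + 1:
            raise ValidationError(f"need N > u+1, got N={self.N}, u={self.u}")
        if self.f2 < 0:
            raise ValidationError("f^2 must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0,1)")


def power_f_test(spec: PowerSpec) -> float:
    """Post hoc power of the overall F test.

    P(F' > F_crit) where F_crit is the (1-alpha) quantile of the
    central F(u, N-u-1) and F' is noncentral F with noncentrality
    lambda = f^2 * N (the G*Power fixed-model convention).
    """
    df1 = spec.u
    df2 = spec.N - spec.u - 1
    fcrit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    nc = spec.f2 * spec.N
    if nc == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(fcrit, df1, df2, nc))
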