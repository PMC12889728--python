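"""Bivariate and multivariable statistics linking loneliness to
socio-demographic factors.

Continuous factors are tested with Pearson correlation (Fisher-z
confidence interval); group factors with one-way ANOVA or, where group
variances differ, Welch's heteroscedastic ANOVA with a
Satterthwaite-type fractional denominator df, followed by Games-Howell
pairwise comparisons. The multivariable model is an OLS regression
with z-scored continuous predictors (family income natural-log
transformed first), reference-coded categorical predictors, and
listwise deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "BivariateResult",
    "RegressionResult",
    "pearson_cor",
    "anova_oneway",
    "welch_anova",
    "games_howell",
    "standardized_ols",
]

#: reference levels for categorical predictors (dropped dummy)
REFERENCE_LEVELS = {
    "sex": "female",
    "marital": "married",
    "household": "with_others",
    "employment": "employed",
    "education": "hs_or_below",
}


@dataclass(frozen=True)
class BivariateResult:
    variable: str
    kind: str  # pearson_r | F | welch_F
    value: float
    df: tuple[float, float]
    p: float
    ci: tuple[float, float] | None = None
    group_stats: pd.DataFrame | None = None


@dataclass(frozen=True)
class RegressionResult:
    coefficients: pd.DataFrame  # predictor, beta, se, t, p, ci_low, ci_high
    r2_adj: float
    f: float
    df: tuple[float, float]
    f_p: float
    n_used: int


def pearson_cor(x, y, alpha: float = 0.05) -> BivariateResult:
    """Pearson correlation with two-sided p and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    zr = np.arctanh(r)
    half = zcrit / math.sqrt(n - 3)
    ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    return BivariateResult(
        variable="", kind="pearson_r", value=float(r), df=(float(n - 2), 0.0),
        p=float(p), ci=ci,
    )


def _group_arrays(values, groups) -> tuple[list[np.ndarray], list]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values) & pd.notna(groups)
    values, groups = values[ok], groups[ok]
    labels = sorted(pd.unique(groups).tolist())
    arrays = [values[groups == g] for g in labels]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g, a in zip(labels, arrays):
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        if a.std(ddof=1) == 0:
            raise ValueError(f"group {g!r} has zero variance")
    return arrays, labels


def _group_table(arrays, labels) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": labels,
            "n": [a.size for a in arrays],
            "mean": [a.mean() for a in arrays],
            "sd": [a.std(ddof=1) for a in arrays],
        }
    )


def anova_oneway(values, groups) -> BivariateResult:
    """Classical equal-variance one-way ANOVA."""
    arrays, labels = _group_arrays(values, groups)
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return BivariateResult(
        variable="", kind="F", value=float(f), df=(float(k - 1), float(n - k)),
        p=float(p), group_stats=_group_table(arrays, labels),
    )


def welch_anova(values, groups) -> BivariateResult:
    """Welch's heteroscedastic one-way ANOVA.

    The denominator df is the Satterthwaite-type quantity
    (k^2 - 1) / (3 * sum((1 - w_i/W)^2 / (n_i - 1))) and may be
    fractional. For two groups the statistic equals the squared Welch
    t exactly.
    """
    arrays, labels = _group_arrays(values, groups)
    k = len(arrays)
    n = np.array([a.size for a in arrays], dtype=float)
    m = np.array([a.mean() for a in arrays])
    v = np.array([a.var(ddof=1) for a in arrays])
    w = n / v
    w_sum = w.sum()
    m_w = (w * m).sum() / w_sum
    a_term = (w * (m - m_w) ** 2).sum() / (k - 1)
    lam = ((1 - w / w_sum) ** 2 / (n - 1)).sum()
    b_term = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    f = a_term / b_term
    df2 = (k**2 - 1) / (3.0 * lam)
    p = stats.f.sf(f, k - 1, df2)
    return BivariateResult(
        variable="", kind="welch_F", value=float(f), df=(float(k - 1), float(df2)),
        p=float(p), group_stats=_group_table(arrays, labels),
    )


def games_howell(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Games-Howell pairwise comparisons under unequal variances.

    Each pair gets a mean difference, a Welch-Satterthwaite df, a
    studentized-range-based p-value and a CI:
    diff +/- q_crit(alpha, k, df) * sqrt((s_i^2/n_i + s_j^2/n_j) / 2).
    """
    arrays, labels = _group_arrays(values, groups)
    k = len(arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            diff = a.mean() - b.mean()
            se2 = va + vb
            df = se2**2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
            q = abs(diff) / math.sqrt(se2 / 2.0)
            p = stats.studentized_range.sf(q, k, df)
            qc = stats.studentized_range.ppf(1 - alpha, k, df)
            half = qc * math.sqrt(se2 / 2.0)
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "diff": diff,
                    "se": math.sqrt(se2),
                    "df": df,
                    "q": q,
                    "p": float(min(p, 1.0)),
                    "ci_low": diff - half,
                    "ci_high": diff + half,
                }
            )
    return pd.DataFrame(rows)


DEFAULT_PREDICTORS = (
    "age",
    "sex",
    "marital",
    "household",
    "employment",
    "income",
    "education",
)
_CONTINUOUS = ("age", "income", "moca", "gmv", "mean_fd", "loneliness_t")
_LOG_TRANSFORMED = ("income",)


def standardized_ols(
    cohort: pd.DataFrame,
    outcome: str = "loneliness_t",
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    alpha: float = 0.05,
) -> RegressionResult:
    """OLS with standardized continuous variables and reference-coded
    categoricals; returns standardized coefficients with SE, t, p and
    CI, plus adjusted R^2 and the model F test.

    Continuous predictors and the outcome are z-scored (income is
    natural-log transformed first); binary/categorical predictors enter
    as 0/1 dummies against their reference level and are not
    standardized. Rows with any missing value are dropped listwise.
    """
    used = [outcome, *predictors]
    df = cohort[used].dropna().reset_index(drop=True)
    design: dict[str, np.ndarray] = {}
    for name in predictors:
        col = df[name]
        if name in REFERENCE_LEVELS:
            levels = sorted(col.astype(str).unique())
            ref = REFERENCE_LEVELS[name]
            if ref not in levels:
                ref = levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                design[f"{name}[{lev}]"] = (col.astype(str) == lev).to_numpy(float)
        else:
            v = col.to_numpy(dtype=float)
            if name in _LOG_TRANSFORMED:
                if (v <= 0).any():
                    raise ValueError(f"{name} must be positive for log transform")
                v = np.log(v)
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"predictor {name} has zero variance")
            design[name] = (v - v.mean()) / sd
    y = df[outcome].to_numpy(dtype=float)
    y = (y - y.mean()) / y.std(ddof=1)
    Xd = pd.DataFrame(design)
    if len(df) < Xd.shape[1] + 2:
        raise ValueError("too few complete rows for the requested model")
    X = sm.add_constant(Xd)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear predictors in the regression design")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=alpha)
    coef = pd.DataFrame(
        {
            "predictor": fit.params.index,
            "beta": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
        }
    )
    return RegressionResult(
        coefficients=coef,
        r2_adj=float(fit.rsquared_adj),
        f=float(fit.fvalue),
        df=(float(fit.df_model), float(fit.df_resid)),
        f_p=float(fit.f_pvalue),
        n_used=int(fit.nobs),
    )
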