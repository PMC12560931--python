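"""Correlation and simple-regression layer of the analysis.

Implements the per-sample NIRS triplet aggregation (arithmetic mean,
geometric mean, maximum), closed-form simple linear regression summaries
(slope ± SE, R², two-sided p from the t distribution with n − 2 df, RMSE),
Pearson correlation matrices with pairwise-complete observations, two-group
muscle contrasts, and the between-muscle trait regressions (topside on
loin).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import TRAITS
from .datatypes import MuscleContrast, NirsAggregate, RegressionSummary

__all__ = [
    "aggregate_nirs",
    "add_nirs_aggregates",
    "ols_regression",
    "pearson_matrix",
    "muscle_contrast",
    "cross_muscle_regression",
]


class DegenerateDesignError(ValueError):
    """Raised when a regression design is not identifiable."""


def aggregate_nirs(readings) -> NirsAggregate:
    """Summaries of the three device readings taken on one sample."""
    r = np.asarray(readings, dtype=float)
    if r.shape != (3,):
        raise ValueError(f"expected exactly 3 readings, got shape {r.shape}")
    for i, v in enumerate(r):
        if not (v > 0):
            raise ValueError(f"reading {i + 1} is non-positive ({v}); geometric mean undefined")
    return NirsAggregate(
        mean=float(r.mean()),
        geometric_mean=float(np.cbrt(r.prod())),
        highest=float(r.max()),
    )


def add_nirs_aggregates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append nirs_mean / nirs_geomean / nirs_max columns to a cohort table."""
    df = cohort.copy()
    readings = df[["nirs_1", "nirs_2", "nirs_3"]].to_numpy(dtype=float)
    if (readings <= 0).any():
        bad = np.argwhere(readings <= 0)[0]
        raise ValueError(f"non-positive NIRS reading at row {bad[0]}, replicate {bad[1] + 1}")
    df["nirs_mean"] = readings.mean(axis=1)
    df["nirs_geomean"] = np.cbrt(readings.prod(axis=1))
    df["nirs_max"] = readings.max(axis=1)
    return df


def ols_regression(x, y, df_adjusted_rmse: bool = True) -> RegressionSummary:
    """Closed-form simple linear regression of ``y`` on ``x``.

    RMSE defaults to the residual standard error √(SSE/(n−2)); pass
    ``df_adjusted_rmse=False`` for the plain √(SSE/n) convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateDesignError("predictor is constant")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    sst = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    s2 = sse / (n - 2)
    slope_se = float(np.sqrt(s2 / sxx))
    if slope_se > 0:
        tstat = slope / slope_se
        p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
    else:
        p = 0.0
    rmse = float(np.sqrt(s2)) if df_adjusted_rmse else float(np.sqrt(sse / n))
    return RegressionSummary(
        slope=float(slope),
        slope_se=slope_se,
        intercept=intercept,
        r2=float(min(max(r2, 0.0), 1.0)),
        p_value=max(p, np.finfo(float).tiny),
        rmse=rmse,
        n=int(n),
    )


def pearson_matrix(table: pd.DataFrame, columns) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation and p-value matrices.

    p-values come from the t transform of r with n − 2 degrees of freedom.
    """
    columns = list(columns)
    k = len(columns)
    r = np.ones((k, k))
    p = np.full((k, k), np.finfo(float).tiny)
    for i in range(k):
        for j in range(i + 1, k):
            xi = table[columns[i]].to_numpy(dtype=float)
            xj = table[columns[j]].to_numpy(dtype=float)
            ok = np.isfinite(xi) & np.isfinite(xj)
            n = int(ok.sum())
            if n < 3:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rij, pij = stats.pearsonr(xi[ok], xj[ok])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = max(pij, np.finfo(float).tiny)
    return (
        pd.DataFrame(r, index=columns, columns=columns),
        pd.DataFrame(p, index=columns, columns=columns),
    )


def muscle_contrast(table: pd.DataFrame, trait: str) -> MuscleContrast:
    """Two-muscle linear-model contrast of one trait.

    With muscle as the only fixed term this is the pooled-variance two-sample
    comparison; per-muscle SEMs are sd/√n within muscle.
    """
    groups = {m: g[trait].to_numpy(dtype=float) for m, g in table.groupby("muscle")}
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 muscles, got {sorted(groups)}")
    means = {m: float(v.mean()) for m, v in groups.items()}
    sems = {
        m: float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        for m, v in groups.items()
    }
    a, b = groups.values()
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.allclose(a.mean(), b.mean()):
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        if not np.isfinite(p):
            p = 1.0
    return MuscleContrast(
        trait=trait,
        means=means,
        sems=sems,
        p_value=max(p, np.finfo(float).tiny),
    )


def cross_muscle_regression(cohort: pd.DataFrame, traits=TRAITS) -> dict:
    """Per-trait regression of the topside (SM) value on the loin (LTL) value."""
    out = {}
    wide = cohort.pivot(index="carcass_id", columns="muscle")
    for trait in traits:
        out[trait] = ols_regression(
            wide[(trait, "LTL")].to_numpy(), wide[(trait, "SM")].to_numpy()
        )
    return out
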