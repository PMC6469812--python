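"""Association statistics for cohort tables.

Implements the statistical stage of a cortical-bone cohort analysis:
Shapiro-Wilk normality gating, paired left/right comparisons (paired t-test
when the differences are normal, Wilcoxon signed-rank otherwise), Pearson
correlation with Fisher-z 95% confidence intervals, linear partial
correlation controlling for a covariate (typically femoral-neck aBMD), and
multivariate linear models with standardized coefficients and adjusted R².

All tests are two-sided at alpha = 0.05 by default and no multiple-testing
correction is applied (flagged in the output metadata); missing values are
handled pairwise-complete with n reported per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "NormalityResult",
    "PairedTestResult",
    "AssociationResult",
    "ModelFit",
    "normality_gate",
    "paired_side_test",
    "pearson_with_ci",
    "partial_correlation",
    "fit_linear_model",
    "build_association_table",
    "average_sides",
]


@dataclass(frozen=True)
class NormalityResult:
    W: float
    p: float
    normal: bool


@dataclass(frozen=True)
class PairedTestResult:
    test: str
    statistic: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class AssociationResult:
    x: str
    y: str
    n: int
    r: float
    p: float
    ci_lo: float
    ci_hi: float
    partial_r: float = np.nan
    partial_p: float = np.nan


@dataclass(frozen=True)
class ModelFit:
    response: str
    predictors: tuple[str, ...]
    betas: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    n: int


def _clean(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def normality_gate(x, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk normality classification at the given alpha."""
    v = _clean(x)
    v = v[~np.isnan(v)]
    if not (3 <= v.size <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={v.size}")
    if np.ptp(v) == 0:
        raise ValueError("constant vector: Shapiro-Wilk W undefined")
    w, p = sps.shapiro(v)
    return NormalityResult(W=float(w), p=float(p), normal=bool(p >= alpha))


def paired_side_test(left, right, alpha: float = 0.05) -> PairedTestResult:
    """Compare paired left/right measurements.

    Uses a paired t-test when the differences pass the normality gate and
    the Wilcoxon signed-rank test otherwise. Identical sides yield the
    degenerate result (p = 1).
    """
    l = _clean(left)
    r = _clean(right)
    if l.shape != r.shape:
        raise ValueError("left and right must have equal length (paired by subject)")
    keep = ~(np.isnan(l) | np.isnan(r))
    l, r = l[keep], r[keep]
    diff = l - r
    if np.allclose(diff, 0.0):
        return PairedTestResult("degenerate", 0.0, 1.0, degenerate=True)
    try:
        normal = normality_gate(diff, alpha).normal
    except ValueError:
        normal = True  # constant non-zero differences: t-test is exact
    if normal:
        t, p = sps.ttest_rel(l, r)
        return PairedTestResult("paired t-test", float(t), float(p))
    w, p = sps.wilcoxon(l, r)
    return PairedTestResult("Wilcoxon signed-rank", float(w), float(p))


def pearson_with_ci(x, y, alpha: float = 0.05) -> AssociationResult:
    """Pearson r with p-value and Fisher-z confidence interval.

    The CI is ``tanh(atanh(r) ± z_{1-alpha/2}/sqrt(n-3))``, endpoints
    clamped to [-1, 1]; for |r| = 1 the interval degenerates to the point.
    """
    xv, yv = _clean(x), _clean(y)
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    n = xv.size
    if n < 3:
        raise ValueError("need n >= 3 complete pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(xv, yv)
    r = float(r)
    if abs(r) >= 1.0 - 1e-15:
        lo = hi = float(np.sign(r))
    elif n > 3:
        z = np.arctanh(r)
        half = sps.norm.ppf(1.0 - alpha / 2.0) / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    else:
        lo, hi = -1.0, 1.0
    return AssociationResult(
        x="x", y="y", n=n, r=r, p=float(p),
        ci_lo=float(np.clip(lo, -1, 1)), ci_hi=float(np.clip(hi, -1, 1)),
    )


def partial_correlation(x, y, z) -> tuple[float, float]:
    """Linear partial correlation of x and y controlling for z.

    Computed as the Pearson correlation between the residuals of the
    regressions x~z and y~z (equivalently the closed form
    ``(r_xy - r_xz r_yz)/sqrt((1-r_xz²)(1-r_yz²))``); the p-value uses
    ``t = r sqrt((n-3)/(1-r²))`` with n-3 degrees of freedom.
    """
    xv, yv, zv = _clean(x), _clean(y), _clean(z)
    keep = ~(np.isnan(xv) | np.isnan(yv) | np.isnan(zv))
    xv, yv, zv = xv[keep], yv[keep], zv[keep]
    n = xv.size
    if n < 4:
        raise ValueError("need n >= 4 complete triples")
    if np.ptp(zv) == 0:
        raise ValueError("constant covariate: residualization undefined")
    Z = np.column_stack([np.ones(n), zv])
    rx = xv - Z @ np.linalg.lstsq(Z, xv, rcond=None)[0]
    ry = yv - Z @ np.linalg.lstsq(Z, yv, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("covariate collinear with x or y (zero residual variance)")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def partial_correlation_closed_form(x, y, z) -> float:
    """Closed-form partial correlation from the three marginal r's."""
    r_xy = sps.pearsonr(x, y)[0]
    r_xz = sps.pearsonr(x, z)[0]
    r_yz = sps.pearsonr(y, z)[0]
    return float(
        (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    )


def fit_linear_model(
    response,
    predictors: pd.DataFrame,
    standardize: bool = True,
    response_name: str = "y",
) -> ModelFit:
    """Least-squares linear model with standardized betas and adjusted R².

    With ``standardize=True`` all variables are z-scored (sample SD,
    ddof=1) before fitting, so a single-predictor beta equals the Pearson
    correlation. Raises on rank-deficient designs, naming the collinear
    columns.
    """
    X = pd.DataFrame(predictors).astype(float)
    yv = _clean(response)
    keep = ~(np.isnan(yv) | X.isna().any(axis=1).to_numpy())
    X = X.loc[keep]
    yv = yv[keep]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p+1 observations (n={n}, p={p})")
    if standardize:
        yv = (yv - yv.mean()) / yv.std(ddof=1)
        X = (X - X.mean()) / X.std(ddof=1)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy()])) < p + 1:
        corr = X.corr().abs()
        pairs = [
            f"{a}~{b}"
            for i, a in enumerate(corr.columns)
            for b in corr.columns[i + 1 :]
            if corr.loc[a, b] > 1 - 1e-9
        ]
        raise ValueError(
            "rank-deficient design; collinear columns: "
            + (", ".join(pairs) if pairs else "see design matrix")
        )
    design = sm.add_constant(X)
    fit = sm.OLS(yv, design).fit()
    betas = fit.params.drop("const")
    pvals = fit.pvalues.drop("const")
    return ModelFit(
        response=response_name,
        predictors=tuple(X.columns),
        betas=betas,
        pvalues=pvals,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=n,
    )


def average_sides(cohort: pd.DataFrame, column: str) -> pd.Series:
    """Mean of the left and right instance of an outcome column.

    The left/right averaging analysis: returns a per-subject vector of the
    same length as the cohort, so downstream correlations never mix
    mismatched n.
    """
    l, r = f"{column}_left", f"{column}_right"
    missing = [c for c in (l, r) if c not in cohort.columns]
    if missing:
        raise KeyError(f"missing side columns: {missing}")
    return (cohort[l] + cohort[r]) / 2.0


def build_association_table(
    cohort: pd.DataFrame,
    covariate: str,
    outcomes: Sequence[str],
    predictors: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Marginal and partial correlations of morphometry with outcomes.

    For every predictor x outcome pair: Pearson r, p and CI, and the
    partial correlation given the covariate. Mirroring the convention of
    reporting coefficients only when significant, ``r_masked`` and
    ``partial_r_masked`` are missing where p >= alpha. A degenerate
    (constant) covariate leaves the partial block missing while the
    marginal block is still reported.
    """
    if predictors is None:
        predictors = [
            c
            for c in cohort.columns
            if c not in outcomes and c != covariate and c != "subject"
            and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    missing = [c for c in [covariate, *outcomes, *predictors] if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table is missing columns: {missing}")

    rows = []
    for xcol in predictors:
        for ycol in outcomes:
            x = cohort[xcol].to_numpy(float)
            y = cohort[ycol].to_numpy(float)
            z = cohort[covariate].to_numpy(float)
            try:
                res = pearson_with_ci(x, y, alpha)
            except ValueError:
                # constant or insufficient data: report the pair as missing
                n_pair = int(np.sum(~(np.isnan(x) | np.isnan(y))))
                res = AssociationResult(xcol, ycol, n_pair, np.nan, np.nan,
                                        np.nan, np.nan)
            try:
                pr, pp = partial_correlation(x, y, z)
            except ValueError:
                pr, pp = np.nan, np.nan
            rows.append(
                {
                    "predictor": xcol,
                    "outcome": ycol,
                    "n": res.n,
                    "r": res.r,
                    "p": res.p,
                    "ci_lo": res.ci_lo,
                    "ci_hi": res.ci_hi,
                    "r_masked": res.r if res.p < alpha else np.nan,
                    "partial_r": pr,
                    "partial_p": pp,
                    "partial_r_masked": pr if pp < alpha else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["alpha"] = alpha
    table.attrs["covariate"] = covariate
    table.attrs["multiple_testing_correction"] = "none"
    return table
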