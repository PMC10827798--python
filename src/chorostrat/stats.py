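"""The study statistics: reliability, agreement, correlation, regression.

Two-way random-effects absolute-agreement ICCs (single and average
measure) are computed from the two-way ANOVA mean squares — the standard
choice for interchangeable human raters.  Bland–Altman agreement reports
the fixed bias (mean difference with a t-based 95% CI) and the
proportional bias (Pearson correlation of differences on means).
Spearman correlation, Kruskal–Wallis, and ordinary least squares on
z-scored variables (standardized betas) delegate to scipy/statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class ReliabilityResult:
    icc_single: float
    icc_single_p: float
    icc_mean: float
    icc_mean_p: float
    fixed_bias: float
    fixed_bias_ci: tuple[float, float]
    fixed_bias_p: float
    proportional_r: float
    proportional_p: float
    loa: tuple[float, float] = (float("nan"), float("nan"))
    n: int = 0


@dataclass
class RegressionResult:
    response: str
    betas: dict[str, float]
    p_values: dict[str, float]
    n: int


@dataclass
class GroupTestResult:
    h: float
    df: int
    p: float
    medians: list[float] = field(default_factory=list)


def _paired(rater1, rater2) -> tuple[np.ndarray, np.ndarray]:
    r1 = np.asarray(rater1, dtype=float)
    r2 = np.asarray(rater2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("rater vectors must be paired")
    keep = np.isfinite(r1) & np.isfinite(r2)
    return r1[keep], r2[keep]


def icc_two_way(rater1, rater2) -> tuple[float, float, float]:
    """ICC(2,1) and ICC(2,k) for two raters, with the between-subject F p-value.

    Two-way random effects, absolute agreement, computed from the ANOVA
    mean squares of the subjects × raters table.  Returns
    (icc_single, icc_mean, p).
    """
    r1, r2 = _paired(rater1, rater2)
    n = r1.size
    if n < 3:
        raise ValueError("insufficient pairs: need n >= 3")
    data = np.column_stack([r1, r2])
    k = 2
    gm = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - gm) ** 2)
    ss_cols = n * np.sum((col_means - gm) ** 2)
    ss_tot = np.sum((data - gm) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0 or np.allclose(row_means.var(), 0):
        warnings.warn("zero between-subject variance: ICC reported as 0", stacklevel=2)
        return 0.0, 0.0, 1.0
    denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    denom_mean = msr + (msc - mse) / n
    icc_single = (msr - mse) / denom_single if denom_single != 0 else 0.0
    icc_mean = (msr - mse) / denom_mean if denom_mean != 0 else 0.0
    if mse == 0:
        p = 0.0
    else:
        f = msr / mse
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc_single), float(icc_mean), p


def bland_altman(rater1, rater2) -> ReliabilityResult:
    """Fixed and proportional bias between two raters.

    Differences d = r1 − r2 against means m = (r1 + r2)/2.  Fixed bias is
    mean(d) with a t 95% CI and one-sample t-test p; proportional bias is
    the Pearson correlation of d on m.  Limits of agreement
    (mean ± 1.96 sd) are included for plotting.
    """
    r1, r2 = _paired(rater1, rater2)
    n = r1.size
    if n < 3:
        raise ValueError("insufficient pairs: need n >= 3")
    d = r1 - r2
    m = (r1 + r2) / 2.0
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0:
        ci = (mean_d, mean_d)
        p_fixed = 1.0 if mean_d == 0 else 0.0
    else:
        tcrit = sps.t.ppf(0.975, n - 1)
        half = tcrit * sd_d / np.sqrt(n)
        ci = (mean_d - half, mean_d + half)
        p_fixed = float(sps.ttest_1samp(d, 0.0).pvalue)
    if np.var(m) == 0 or np.var(d) == 0:
        r_prop, p_prop = float("nan"), float("nan")
    else:
        r_prop, p_prop = sps.pearsonr(d, m)
    icc_s, icc_m, icc_p = icc_two_way(r1, r2)
    return ReliabilityResult(
        icc_single=icc_s, icc_single_p=icc_p, icc_mean=icc_m, icc_mean_p=icc_p,
        fixed_bias=mean_d, fixed_bias_ci=ci, fixed_bias_p=p_fixed,
        proportional_r=float(r_prop), proportional_p=float(p_prop),
        loa=(mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d), n=n,
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def standardized_regression(response, predictors: dict, name: str = "response") -> RegressionResult:
    """OLS on z-scored response and predictors; standardized betas and p.

    Rows with any missing value are listwise-deleted.  Exactly collinear
    designs are rejected.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    names = list(predictors)
    X = np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    n = y.size
    if n <= 5:
        raise ValueError("need n > 5 for regression")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < X.shape[1] + 1:
        raise ValueError("singular design: predictors exactly collinear")
    yz = (y - y.mean()) / y.std(ddof=1)
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    betas = {k: float(model.params[i + 1]) for i, k in enumerate(names)}
    pvals = {k: float(model.pvalues[i + 1]) for i, k in enumerate(names)}
    return RegressionResult(response=name, betas=betas, p_values=pvals, n=n)


def kruskal_wallis(groups: list) -> GroupTestResult:
    """Kruskal–Wallis H with tie correction and chi-squared p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    medians = [float(np.median(g)) for g in groups]
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return GroupTestResult(0.0, len(groups) - 1, 1.0, medians)
    h, p = sps.kruskal(*groups)
    return GroupTestResult(float(h), len(groups) - 1, float(p), medians)
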