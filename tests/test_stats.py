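"""Statistical battery against brute-force oracles and designed simulations."""

import numpy as np
import pytest

from chorostrat import (
    bland_altman,
    icc_two_way,
    kruskal_wallis,
    spearman,
    standardized_regression,
)

# hand datasets small enough to grind through the textbook formulas
HAND_R1 = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
HAND_R2 = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])


def _icc_oracle(r1, r2):
    """Explicit two-way ANOVA mean-square computation."""
    data = np.column_stack([r1, r2])
    n, k = data.shape
    gm = data.mean()
    msr = k * ((data.mean(1) - gm) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(0) - gm) ** 2).sum() / (k - 1)
    mse = (((data - gm) ** 2).sum() - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
    single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    mean = (msr - mse) / (msr + (msc - mse) / n)
    return single, mean


def test_icc_perfect_agreement():
    s, m, p = icc_two_way(HAND_R1, HAND_R1)
    assert s == pytest.approx(1.0)
    assert m == pytest.approx(1.0)


def test_icc_uncorrelated_permutation_near_zero(rng):
    x = rng.normal(0, 1, 4000)
    y = rng.permutation(x)
    s, m, p = icc_two_way(x, y)
    assert abs(s) < 0.05


def test_icc_matches_anova_oracle():
    s, m, p = icc_two_way(HAND_R1, HAND_R2)
    os_, om = _icc_oracle(HAND_R1, HAND_R2)
    assert s == pytest.approx(os_, abs=1e-9)
    assert m == pytest.approx(om, abs=1e-9)


def test_icc_matches_pingouin():
    import pandas as pd
    import pingouin as pg

    df = pd.DataFrame({
        "targets": list(range(6)) * 2,
        "raters": ["a"] * 6 + ["b"] * 6,
        "ratings": np.r_[HAND_R1, HAND_R2],
    })
    icc = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
    ref_s = float(icc.loc[icc.Type == "ICC(A,1)", "ICC"].iloc[0])
    ref_m = float(icc.loc[icc.Type == "ICC(A,k)", "ICC"].iloc[0])
    ref_p = float(icc.loc[icc.Type == "ICC(A,1)", "pval"].iloc[0])
    s, m, p = icc_two_way(HAND_R1, HAND_R2)
    assert s == pytest.approx(ref_s, abs=1e-6)
    assert m == pytest.approx(ref_m, abs=1e-6)
    assert p == pytest.approx(ref_p, abs=1e-6)


def test_icc_zero_variance_warns():
    with pytest.warns(UserWarning, match="zero between-subject variance"):
        s, m, p = icc_two_way(np.full(5, 3.0), np.full(5, 3.0))
    assert s == 0.0


def test_icc_insufficient_pairs():
    with pytest.raises(ValueError, match="insufficient pairs"):
        icc_two_way([1.0, 2.0], [1.0, 2.0])


def test_icc_variance_component_consistency(rng):
    """ICC(2,1) tracks σ²_subject/(σ²_subject+σ²_error) at large n."""
    n = 2000
    subj = rng.normal(0, 1.0, n)
    r1 = subj + rng.normal(0, 0.5, n)
    r2 = subj + rng.normal(0, 0.5, n)
    s, _, _ = icc_two_way(r1, r2)
    assert abs(s - 0.8) <= 0.03


def test_bland_altman_identity():
    res = bland_altman(HAND_R1, HAND_R1)
    assert res.fixed_bias == 0.0
    assert res.fixed_bias_ci == (0.0, 0.0)
    assert np.isnan(res.proportional_r)


def test_bland_altman_constant_shift_detected(rng):
    r1 = rng.normal(10, 1, 60)
    r2 = r1 - 0.5 + rng.normal(0, 0.05, 60)
    res = bland_altman(r1, r2)
    lo, hi = res.fixed_bias_ci
    assert lo > 0  # CI excludes zero
    # closed-form t CI check
    d = r1 - r2
    from scipy import stats as sps
    half = sps.t.ppf(0.975, 59) * d.std(ddof=1) / np.sqrt(60)
    assert lo == pytest.approx(d.mean() - half)
    assert hi == pytest.approx(d.mean() + half)


def test_bland_altman_proportional_detected(rng):
    r1 = rng.normal(10, 2, 100)
    r2 = 0.9 * r1
    res = bland_altman(r1, r2)
    assert res.proportional_r > 0
    assert res.proportional_p < 0.01
    d, m = r1 - r2, (r1 + r2) / 2
    ref = np.corrcoef(d, m)[0, 1]
    assert res.proportional_r == pytest.approx(ref)


def test_spearman_monotone():
    x = np.arange(10.0)
    assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
    assert spearman(x, -x)[0] == pytest.approx(-1.0)


def test_spearman_ties_match_midrank_oracle():
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
    y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 5.0, 5.0])
    rho, _ = spearman(x, y)
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    ref = np.corrcoef(rx, ry)[0, 1]
    assert rho == pytest.approx(ref, abs=1e-12)


def test_spearman_constant_undefined():
    with pytest.warns(UserWarning, match="constant input"):
        rho, p = spearman(np.full(5, 1.0), np.arange(5.0))
    assert np.isnan(rho)


def test_regression_null_betas_small(rng):
    n = 500
    preds = {k: rng.normal(0, 1, n) for k in ("age", "se", "al")}
    y = rng.normal(0, 1, n)
    res = standardized_regression(y, preds)
    assert all(abs(b) < 0.1 for b in res.betas.values())


def test_regression_designed_effects_recovered(rng):
    n = 500
    age = rng.normal(0, 1, n)
    al = rng.normal(0, 1, n)
    se = rng.normal(0, 1, n)
    y = -0.5 * age - 0.5 * al + rng.normal(0, 0.5, n)
    res = standardized_regression(y, {"age": age, "se": se, "al": al})
    expected = -0.5 / np.sqrt(0.75)  # betas rescale by sd(y) = sqrt(0.25+0.25+0.25)
    assert res.betas["age"] == pytest.approx(expected, abs=0.08)
    assert res.betas["al"] == pytest.approx(expected, abs=0.08)
    assert abs(res.betas["se"]) < 0.08


def test_regression_orthonormal_betas_equal_correlations(rng):
    n = 400
    a = rng.normal(0, 1, n)
    b = rng.normal(0, 1, n)
    a = (a - a.mean()) / a.std(ddof=1)
    b = b - np.dot(a, b) / np.dot(a, a) * a  # orthogonalize
    b = (b - b.mean()) / b.std(ddof=1)
    y = 0.4 * a - 0.3 * b + rng.normal(0, 0.5, n)
    res = standardized_regression(y, {"age": a, "al": b})
    yz = (y - y.mean()) / y.std(ddof=1)
    assert res.betas["age"] == pytest.approx(np.corrcoef(a, yz)[0, 1], abs=1e-2)
    assert res.betas["al"] == pytest.approx(np.corrcoef(b, yz)[0, 1], abs=1e-2)


def test_regression_singular_design():
    x = np.arange(10.0)
    with pytest.raises(ValueError, match="singular design"):
        standardized_regression(x, {"a": x, "b": 2 * x})


def test_kruskal_identical_groups():
    g = [np.full(5, 3.0)] * 3
    res = kruskal_wallis(g)
    assert res.h == 0.0
    assert res.p == 1.0
    assert res.df == 2


def test_kruskal_separated_groups(rng):
    groups = [rng.normal(mu, 1.0, 50) for mu in (79.0, 67.6, 63.3)]
    res = kruskal_wallis(groups)
    assert res.p < 0.01
    assert res.medians[0] > res.medians[1] > res.medians[2]


def test_kruskal_matches_formula_oracle():
    """Tie-corrected H against a direct rank-sum computation."""
    from scipy.stats import rankdata

    groups = [np.array([1.0, 2.0, 2.0]), np.array([2.0, 3.0, 5.0]), np.array([4.0, 4.0, 6.0])]
    res = kruskal_wallis(groups)
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    n = pooled.size
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx:idx + g.size]
        idx += g.size
        h += r.sum() ** 2 / g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    h /= 1 - np.sum(counts**3 - counts) / (n**3 - n)
    assert res.h == pytest.approx(h, abs=1e-9)


def test_kruskal_empty_group():
    with pytest.raises(ValueError, match="empty group"):
        kruskal_wallis([np.array([1.0]), np.array([])])


def test_rank_tests_monotone_invariance(rng):
    """Spearman and Kruskal–Wallis are invariant to strictly monotone transforms."""
    x = rng.normal(0, 1, 60)
    y = rng.normal(0, 1, 60)
    assert spearman(x, y)[0] == pytest.approx(spearman(np.exp(x), y)[0], abs=1e-12)
    groups = [rng.normal(m, 1, 20) for m in (0, 0.5, 1.0)]
    h1 = kruskal_wallis(groups).h
    h2 = kruskal_wallis([np.exp(g) for g in groups]).h
    assert h1 == pytest.approx(h2, abs=1e-9)
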