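"""Statistics battery: effect sizes, GLM contrasts, partial correlation,
multiplicity, VIF and the demographic-table tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from dtialps import (
    CohortConfig,
    COVARIATE_COLUMNS,
    all_group_contrasts,
    cohens_d,
    compute_vif,
    effect_size_category,
    fisher_exact,
    fit_glm,
    fwe_correct,
    generate_cohort,
    group_contrast,
    kruskal_wallis,
    partial_correlation,
)


# --------------------------------------------------------------- Cohen's d

def test_cohens_d_reproduces_published_effect_size():
    """The printed Pre-DM vs T2DM effect size (−0.63) recomputes exactly
    from the printed group sizes, means and SDs under the n-pooled
    denominator."""
    d = cohens_d(22, 1.43, 0.08, 18, 1.36, 0.14)
    assert d == pytest.approx(-0.63, abs=0.01)


def test_cohens_d_identities():
    assert cohens_d(10, 1.0, 0.5, 10, 1.0, 0.5) == 0.0
    # equal n, equal SDs, means one SD apart -> exactly 1
    assert cohens_d(7, 2.0, 0.3, 7, 2.3, 0.3) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cohens_d(5, 1.0, 0.0, 5, 2.0, 0.0)


@given(
    n1=st.integers(2, 50), n2=st.integers(2, 50),
    m1=st.floats(-5, 5), m2=st.floats(-5, 5),
    s1=st.floats(0.1, 3), s2=st.floats(0.1, 3),
    shift=st.floats(-10, 10), scale=st.floats(0.1, 10),
)
@settings(max_examples=100, derandomize=True)
def test_cohens_d_antisymmetry_and_invariances(n1, n2, m1, m2, s1, s2,
                                               shift, scale):
    d = cohens_d(n1, m1, s1, n2, m2, s2)
    assert cohens_d(n2, m2, s2, n1, m1, s1) == pytest.approx(-d, rel=1e-9)
    # common shift of both means leaves d unchanged
    assert cohens_d(n1, m1 + shift, s1, n2, m2 + shift, s2) \
        == pytest.approx(d, rel=1e-9, abs=1e-12)
    # common scaling of means and SDs preserves |d|
    assert abs(cohens_d(n1, scale * m1, scale * s1,
                        n2, scale * m2, scale * s2)) \
        == pytest.approx(abs(d), rel=1e-9, abs=1e-12)


@pytest.mark.parametrize("d,cat", [
    (-1.32, "large"), (-0.63, "medium"), (0.2, "negligible"),
    (0.200001, "small"), (0.5, "small"), (0.500001, "medium"),
    (0.8, "medium"), (0.800001, "large"), (0.0, "negligible"),
])
def test_effect_size_categories(d, cat):
    assert effect_size_category(d) == cat


# -------------------------------------------------------------------- GLM

def test_glm_exact_fit_and_intercept_only():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
    beta = np.array([1.0, -2.0, 0.5])
    fit = fit_glm(X @ beta, X)
    np.testing.assert_allclose(fit.resid, 0.0, atol=1e-10)
    np.testing.assert_allclose(fit.params, beta, rtol=1e-10)

    y = rng.standard_normal(25)
    fit = fit_glm(y, np.ones((25, 1)))
    assert fit.params[0] == pytest.approx(y.mean(), rel=1e-12)


def test_glm_matches_pseudoinverse_oracle():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(50), rng.standard_normal((50, 4))])
    y = rng.standard_normal(50)
    fit = fit_glm(y, X)
    np.testing.assert_allclose(fit.params, np.linalg.pinv(X) @ y,
                               atol=1e-8)


def test_glm_rank_deficiency_names_columns():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(20)
    X = pd.DataFrame({"const": 1.0, "a": x, "b": 2 * x})
    with pytest.raises(ValueError, match="a"):
        fit_glm(rng.standard_normal(20), X)


# ---------------------------------------------------- partial correlation

def test_partial_correlation_collapses_to_pearson():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(40)
    y = 0.5 * x + rng.standard_normal(40)
    pc = partial_correlation(y, x)
    r_ref, p_ref = scipy.stats.pearsonr(y, x)
    assert pc.r == pytest.approx(r_ref, rel=1e-10)
    assert pc.p == pytest.approx(p_ref, rel=1e-8)
    assert pc.df == 38


def test_partial_correlation_perfect_dependence():
    rng = np.random.default_rng(4)
    z = rng.standard_normal((30, 2))
    x = rng.standard_normal(30)
    y = 2.0 * x + z @ [1.0, -1.0]
    pc = partial_correlation(y, x, z)
    assert pc.r == pytest.approx(1.0, abs=1e-10)


def test_partial_correlation_equals_glm_t_transform():
    """r equals sign(t)·|t|/sqrt(t² + df) computed from the GLM coefficient
    of x in the regression of y on (x, covariates) — tested to 1e-8."""
    rng = np.random.default_rng(5)
    n, k = 40, 7
    Z = rng.standard_normal((n, k))
    x = rng.standard_normal(n)
    y = -0.4 * x + Z @ rng.standard_normal(k) + rng.standard_normal(n)
    pc = partial_correlation(y, x, Z)
    X = np.column_stack([np.ones(n), x, Z])
    fit = fit_glm(y, X)
    t = fit.tvalues[1]
    df = n - k - 2
    assert fit.df_resid == df
    assert pc.r == pytest.approx(np.sign(t) * abs(t) / np.sqrt(t * t + df),
                                 abs=1e-8)
    assert pc.p == pytest.approx(fit.pvalues[1], rel=1e-8)


def test_partial_correlation_zero_variance_errors():
    with pytest.raises(ValueError):
        partial_correlation(np.ones(20), np.arange(20.0))


# ----------------------------------------------------------- multiplicity

def test_bonferroni_examples_and_monotonicity():
    assert fwe_correct([0.5], 3)[0] == 1.0
    assert fwe_correct([0.0], 10)[0] == 0.0
    assert fwe_correct([0.01], 3)[0] == pytest.approx(0.03)
    p = np.sort(np.random.default_rng(0).uniform(size=20))
    c3 = fwe_correct(p, 20)
    assert np.all(np.diff(c3) >= 0)          # monotone in raw p
    assert np.all(fwe_correct(p, 25) >= c3)  # monotone in m
    assert np.all(c3 <= 1.0) and np.all(c3 >= p)


# ------------------------------------------------------------------- VIF

def test_vif_orthogonal_and_collinear():
    n = 64
    t = np.arange(n)
    X = np.column_stack([np.cos(2 * np.pi * t / n),
                         np.sin(2 * np.pi * t / n)])
    vif = compute_vif(X)
    np.testing.assert_allclose(vif.to_numpy(), 1.0, atol=1e-10)

    X2 = np.column_stack([X, X[:, 0]])
    vif2 = compute_vif(X2)
    assert np.isinf(vif2.iloc[0]) and np.isinf(vif2.iloc[2])


def test_default_cohort_covariates_pass_vif_screen(default_cohort):
    """The seven adjustment covariates of the default synthetic cohort show
    no problematic multicollinearity (all VIF < 5)."""
    cohort, _ = default_cohort
    vif = compute_vif(cohort.loc[:, list(COVARIATE_COLUMNS)])
    assert (vif < 5).all()


# --------------------------------------------------------- Kruskal–Wallis

def test_kruskal_wallis_identical_and_hand_ranked():
    H, p = kruskal_wallis([1, 2, 3], [3, 1, 2])
    assert H == pytest.approx(0.0, abs=1e-12)

    # hand-ranked oracle: ranks 1..6, rank sums 6 and 15
    # H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 27/7
    H, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
    assert H == pytest.approx(27 / 7, rel=1e-12)
    assert p == pytest.approx(scipy.stats.chi2.sf(27 / 7, 1), rel=1e-10)

    H, p = kruskal_wallis([5, 5], [5, 5, 5])
    assert (H, p) == (0.0, 1.0)


def test_kruskal_wallis_null_p_uniformity():
    """Under the null (three groups from one distribution) the p-value is
    approximately uniform: the rejection rate at 0.05 is close to 5%."""
    rng = np.random.default_rng(6)
    rejections = 0
    n_rep = 2000
    for _ in range(n_rep):
        x = rng.standard_normal(36)
        _, p = kruskal_wallis(x[:12], x[12:24], x[24:])
        rejections += p < 0.05
    rate = rejections / n_rep
    assert 0.03 < rate < 0.07


# ---------------------------------------------------------- Fisher's exact

def test_fisher_exact_hand_cases():
    # diagonal 2x2: only the two extreme tables are as unlikely
    assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)
    assert fisher_exact([[4, 4], [4, 4]]) == 1.0
    with pytest.raises(ValueError):
        fisher_exact([[0, 0], [1, 2]])


def test_fisher_exact_matches_scipy_on_2x2():
    rng = np.random.default_rng(7)
    for _ in range(50):
        T = rng.integers(0, 12, size=(2, 2))
        if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
            continue
        _, p_ref = scipy.stats.fisher_exact(T)
        assert fisher_exact(T) == pytest.approx(p_ref, rel=1e-9)


def test_fisher_exact_2x3_properties():
    # identical rows -> most probable table, p = 1
    assert fisher_exact([[3, 4, 5], [3, 4, 5]]) == 1.0
    # p is a valid probability and shrinks for a concentrated table
    p_skew = fisher_exact([[8, 0, 0], [0, 8, 8]])
    assert 0 < p_skew < 0.01


def test_fisher_exact_2x3_matches_exhaustive_enumeration():
    T = np.array([[2, 5, 1], [4, 1, 3]])
    p = fisher_exact(T)
    # independent brute force over the first row with fixed margins
    from math import comb
    col = T.sum(axis=0)
    r1 = T[0].sum()
    obs = np.prod([comb(c, a) for c, a in zip(col, T[0])])
    acc = 0
    total = 0
    for a in range(col[0] + 1):
        for b in range(col[1] + 1):
            c = r1 - a - b
            if 0 <= c <= col[2]:
                w = comb(col[0], a) * comb(col[1], b) * comb(col[2], c)
                total += w
                if w <= obs:
                    acc += w
    assert p == pytest.approx(acc / total, rel=1e-12)
    assert total == comb(T.sum(), r1)


# ------------------------------------------------- group contrasts (GLM)

@pytest.fixture(scope="module")
def measured_cohort():
    """Default cohort with true ALPS standing in for the measured index."""
    cohort, truth = generate_cohort(CohortConfig(master_seed=11))
    cohort = cohort.copy()
    cohort["alps_bilateral"] = truth["alps_true"].to_numpy()
    return cohort


def test_group_contrast_structure(measured_cohort):
    alps = measured_cohort["alps_bilateral"].to_numpy()
    comps = all_group_contrasts(alps, measured_cohort)
    assert [c.pair for c in comps] == [
        ("NGM", "Pre-DM"), ("NGM", "T2DM"), ("Pre-DM", "T2DM")]
    for c in comps:
        assert c.p_fwe >= c.p_raw
        assert c.p_fwe <= 1.0
        assert c.p_fwe == pytest.approx(min(1.0, 3 * c.p_raw), rel=1e-12)
        # d sign matches the direction of the raw mean difference
        g1 = alps[measured_cohort["group"] == c.pair[0]].mean()
        g2 = alps[measured_cohort["group"] == c.pair[1]].mean()
        assert np.sign(c.cohens_d) == np.sign(g2 - g1)


def test_group_contrast_requires_two_subjects():
    cohort, truth = generate_cohort(
        CohortConfig(master_seed=0).with_groups(**{"T2DM": 1}))
    cohort["alps_bilateral"] = truth["alps_true"].to_numpy()
    with pytest.raises(ValueError, match="fewer than 2"):
        group_contrast(cohort["alps_bilateral"].to_numpy(), cohort,
                       ("NGM", "T2DM"))


def test_type_one_error_calibration():
    """With no group effect and no ALPS–HOMA coupling, the raw p of the
    NGM vs T2DM contrast rejects at alpha = 0.05 in 5% ± 1.5% of 2000
    null cohorts."""
    import dataclasses
    base = CohortConfig().groups
    null_groups = tuple(
        dataclasses.replace(g, alps_mean=1.5, alps_sd=0.15) for g in base)
    rejections = 0
    n_rep = 2000
    for i in range(n_rep):
        cfg = CohortConfig(groups=null_groups, alps_homair_partial_r=0.0,
                           master_seed=100_000 + i)
        cohort, truth = generate_cohort(cfg)
        comp = group_contrast(truth["alps_true"].to_numpy(), cohort,
                              ("NGM", "T2DM"))
        rejections += comp.p_raw < 0.05
    rate = rejections / n_rep
    assert 0.035 <= rate <= 0.065
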