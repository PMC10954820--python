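"""Covariate-adjusted group statistics for the ALPS analysis.

Implements the statistical battery of the study design: a general linear
model (GLM) comparing the bilateral ALPS index across glycemic groups
with seven clinical covariates, Bonferroni family-wise-error correction
over the three pairwise contrasts, Cohen's d from raw group summaries
(n-pooled denominator, as printed), GLM-based partial correlation with
``df = n - k - 2``, variance-inflation-factor screening, and the
demographic-table tests (Kruskal–Wallis for continuous markers, Fisher's
exact test for categorical ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "COVARIATE_COLUMNS",
    "GLMFit",
    "GroupComparison",
    "PartialCorrelation",
    "fit_glm",
    "group_contrast",
    "all_group_contrasts",
    "cohens_d",
    "effect_size_category",
    "partial_correlation",
    "fwe_correct",
    "compute_vif",
    "kruskal_wallis",
    "fisher_exact",
]

#: the seven adjustment covariates, as cohort-table column names
COVARIATE_COLUMNS = (
    "sex_female", "age", "icv_mm3", "education_years",
    "hypertension", "hyperlipidemia", "fazekas_total",
)


@dataclass
class GLMFit:
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    resid: np.ndarray
    df_resid: int
    results: object  # underlying statsmodels results


@dataclass
class GroupComparison:
    pair: tuple[str, str]
    adjusted_difference: float
    t: float
    p_raw: float
    p_fwe: float
    cohens_d: float
    effect_category: str


@dataclass
class PartialCorrelation:
    r: float
    p: float
    df: int


def _check_full_rank(X: np.ndarray, names=None):
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if names is None:
            names = [f"col{j}" for j in range(X.shape[1])]
        # smallest right singular vector points at the collinear columns
        _, _, vt = np.linalg.svd(X)
        involved = [names[j] for j in np.where(
            np.abs(vt[-1]) > 1e-8)[0]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {involved}"
        )
    return X


def fit_glm(y, X, names=None) -> GLMFit:
    """Ordinary least squares of ``y`` on the columns of ``X``.

    ``X`` must be full column rank (an informative error names the
    collinear columns otherwise).  Standard errors use the residual
    variance with ``df = n - p``.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
    X = _check_full_rank(X, names)
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and X row counts differ")
    res = sm.OLS(y, X).fit()
    return GLMFit(params=np.asarray(res.params), bse=np.asarray(res.bse),
                  tvalues=np.asarray(res.tvalues),
                  pvalues=np.asarray(res.pvalues),
                  resid=np.asarray(res.resid),
                  df_resid=int(res.df_resid), results=res)


def _group_design(cohort: pd.DataFrame, covariates=COVARIATE_COLUMNS):
    groups = cohort["group"].to_numpy()
    levels = [g for g in ("NGM", "Pre-DM", "T2DM") if g in set(groups)]
    if len(levels) < 2:
        raise ValueError("need at least two groups for a contrast")
    cols = {"const": np.ones(len(cohort))}
    for g in levels[1:]:  # NGM (or first present level) is the reference
        cols[f"group[{g}]"] = (groups == g).astype(float)
    for c in covariates:
        cols[c] = cohort[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    return X, levels


def group_contrast(alps, cohort: pd.DataFrame, pair: tuple[str, str],
                   covariates=COVARIATE_COLUMNS,
                   n_comparisons: int = 3) -> GroupComparison:
    """Covariate-adjusted comparison of the ALPS index for one group pair.

    Fits one GLM over all subjects — ALPS on group dummies (reference =
    NGM) plus the seven covariates — and t-tests the contrast between the
    requested pair.  The family-wise-corrected p applies Bonferroni over
    ``n_comparisons`` pairwise contrasts.  Cohen's d comes from the raw
    (unadjusted) group summaries, with the convention d = (mean(pair[1]) -
    mean(pair[0])) / S_c.
    """
    alps = np.asarray(alps, dtype=float)
    groups = cohort["group"].to_numpy()
    for g in pair:
        if int((groups == g).sum()) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    X, levels = _group_design(cohort, covariates)
    fit = fit_glm(alps, X)

    L = np.zeros(X.shape[1])
    for g, sign in ((pair[1], 1.0), (pair[0], -1.0)):
        j = X.columns.get_loc(f"group[{g}]") if g != levels[0] else None
        if j is not None:
            L[j] = sign
    tt = fit.results.t_test(L)
    t = float(np.squeeze(tt.tvalue))
    p_raw = float(np.squeeze(tt.pvalue))
    diff = float(np.squeeze(tt.effect))

    a, b = (alps[groups == g] for g in pair)
    d = cohens_d(len(a), a.mean(), a.std(ddof=1),
                 len(b), b.mean(), b.std(ddof=1))
    return GroupComparison(
        pair=pair, adjusted_difference=diff, t=t, p_raw=p_raw,
        p_fwe=fwe_correct([p_raw], n_comparisons)[0],
        cohens_d=d, effect_category=effect_size_category(d),
    )


def all_group_contrasts(alps, cohort: pd.DataFrame,
                        covariates=COVARIATE_COLUMNS) -> list[GroupComparison]:
    """The three pairwise contrasts with Bonferroni correction over all three."""
    levels = [g for g in ("NGM", "Pre-DM", "T2DM")
              if g in set(cohort["group"])]
    pairs = list(combinations(levels, 2))
    return [group_contrast(alps, cohort, pair, covariates,
                           n_comparisons=len(pairs)) for pair in pairs]


def cohens_d(n1: int, mean1: float, sd1: float,
             n2: int, mean2: float, sd2: float) -> float:
    """Cohen's d with the n-pooled denominator, exactly as printed:

    ``S_c = sqrt((n1 s1^2 + n2 s2^2) / (n1 + n2))``;
    ``d = (mean2 - mean1) / S_c``.

    Note the pooling divides by ``n1 + n2`` with no −2 correction; this
    reproduces the published effect sizes (e.g. −0.63 for the smallest
    printed contrast) where the conventional pooled-SD formula does not.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    s_c = np.sqrt((n1 * sd1**2 + n2 * sd2**2) / (n1 + n2))
    if s_c == 0:
        raise ValueError("pooled SD is zero; Cohen's d undefined")
    return float((mean2 - mean1) / s_c)


def effect_size_category(d: float) -> str:
    """Effect-size bands: |d| <= 0.2 negligible, (0.2, 0.5] small,
    (0.5, 0.8] medium, > 0.8 large."""
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    a = abs(d)
    if a <= 0.2:
        return "negligible"
    if a <= 0.5:
        return "small"
    if a <= 0.8:
        return "medium"
    return "large"


def partial_correlation(y, x, covars=None) -> PartialCorrelation:
    """Partial correlation of ``y`` and ``x`` given ``covars``, via the GLM.

    Both variables are residualized on the covariates (with intercept);
    r is the Pearson correlation of the residuals.  The p-value uses
    ``t = r sqrt(df / (1 - r^2))`` with ``df = n - k - 2`` (k covariates),
    two-sided — algebraically identical to the t statistic of x's
    coefficient in the GLM of y on (x, covariates).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.shape[0]
    if covars is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        Z = np.column_stack([np.ones(n), np.asarray(covars, dtype=float)])
        k = Z.shape[1] - 1
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    _check_full_rank(Z)
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    sy, sx = np.linalg.norm(ry), np.linalg.norm(rx)
    if sy == 0 or sx == 0:
        raise ValueError("zero-variance residuals; partial r undefined")
    r = float(np.clip((ry @ rx) / (sy * sx), -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return PartialCorrelation(r=r, p=p, df=df)


def fwe_correct(p_values, m: int) -> np.ndarray:
    """Bonferroni family-wise-error correction: ``min(1, m * p)`` per test."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError("m must cover at least the supplied tests")
    return np.minimum(1.0, m * p)


def compute_vif(X) -> pd.Series:
    """Variance inflation factor per column of the covariate matrix.

    ``VIF_j = 1 / (1 - R²_j)`` from regressing column j on the remaining
    columns (with an intercept).  Perfect collinearity yields ``inf``.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        A = X.to_numpy(dtype=float)
    else:
        A = np.asarray(X, dtype=float)
        names = [f"col{j}" for j in range(A.shape[1])]
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 columns")
    out = {}
    for j, name in enumerate(names):
        yj = A[:, j]
        Z = np.column_stack([np.ones(A.shape[0]),
                             np.delete(A, j, axis=1)])
        resid = yj - Z @ np.linalg.lstsq(Z, yj, rcond=None)[0]
        tss = np.sum((yj - yj.mean()) ** 2)
        rss = np.sum(resid**2)
        if tss == 0:
            raise ValueError(f"column {name!r} is constant")
        r2 = 1.0 - rss / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def kruskal_wallis(*samples) -> tuple[float, float]:
    """Kruskal–Wallis rank test (tie-corrected H, chi-square p).

    With two groups this reduces to a rank-sum-style comparison, the mode
    used for pairwise demographic-table entries.  If every value is
    identical the statistic is 0 with p = 1.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    flat = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    if flat.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    H, p = scipy.stats.kruskal(*samples)
    return float(H), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test for a 2x2 or 2x3 table.

    Enumerates every table with the observed margins, computing each
    probability under the (multivariate) hypergeometric null with exact
    integer arithmetic, and sums the probabilities of tables no more
    likely than the observed one.
    """
    T = np.asarray(table, dtype=int)
    if not np.array_equal(T, np.asarray(table)):
        raise ValueError("table entries must be integers")
    if T.ndim != 2 or T.shape[0] != 2 or T.shape[1] not in (2, 3):
        raise ValueError("table must be 2x2 or 2x3")
    if np.any(T < 0):
        raise ValueError("table entries must be non-negative")
    row = T.sum(axis=1)
    col = T.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("table has an empty margin")
    N = int(T.sum())
    r1 = int(row[0])

    # P(first row = a) ∝ prod_j C(col_j, a_j); denominator C(N, r1)
    def weight(a):
        w = 1
        for aj, cj in zip(a, col):
            w *= comb(int(cj), int(aj))
        return w

    obs_w = weight(T[0])

    def first_rows(remaining_cols, remaining_total):
        if len(remaining_cols) == 1:
            if 0 <= remaining_total <= remaining_cols[0]:
                yield (remaining_total,)
            return
        for a in range(min(remaining_cols[0], remaining_total) + 1):
            for rest in first_rows(remaining_cols[1:], remaining_total - a):
                yield (a,) + rest

    total = comb(N, r1)
    acc = 0
    for a in first_rows(list(map(int, col)), r1):
        w = weight(a)
        if w <= obs_w:
            acc += w
    return float(acc / total)
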