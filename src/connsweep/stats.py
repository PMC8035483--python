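"""Cohort-level statistics.

Demographic comparisons from raw data or printed summaries (chi-square,
two-sample t in pooled and Welch variants, one-way ANOVA), covariate-adjusted
three-group comparison of network AUCs (ANCOVA with Bonferroni-corrected
pairwise post hoc tests), partial correlation between network metrics and
clinical scores, and Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    posthoc: dict[tuple[str, str], float] | None = None
    effect_direction: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise StatsError("p must lie in [0, 1]")


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    q: float | None = None

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise StatsError("|r| must not exceed 1")


def classify_cognitive_status(moca: int) -> str:
    """Cognitive impairment iff MoCA total score < 26."""
    if not 0 <= moca <= 30:
        raise StatsError("MoCA score must lie in [0, 30]")
    return "CI" if moca < 26 else "NCI"


def chi_square_test(table: np.ndarray) -> StatResult:
    """Pearson chi-square on an R x C count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise StatsError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("table has an all-zero margin")
    chi2, p, dof, _ = st.chi2_contingency(table, correction=False)
    return StatResult("chi_square", float(chi2), (float(dof),), float(p))


def two_sample_t_from_summary(n1: int, mean1: float, sd1: float,
                              n2: int, mean2: float, sd2: float,
                              variant: str = "pooled") -> StatResult:
    """Two-sided independent t test from group summaries.

    ``variant='pooled'`` assumes equal variances (df = n1 + n2 - 2);
    ``variant='welch'`` uses the Satterthwaite approximation.
    """
    if variant not in ("pooled", "welch"):
        raise StatsError("variant must be 'pooled' or 'welch'")
    if min(n1, n2) < 2 or min(sd1, sd2) <= 0:
        raise StatsError("need n >= 2 and positive sds")
    t, p = st.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return StatResult(f"t_{variant}", float(t), (float(df),), float(p))


def one_way_anova_from_summary(groups: list[tuple[int, float, float]]) -> StatResult:
    """One-way ANOVA F test reconstructed from (n, mean, sd) per group."""
    if len(groups) < 2 or any(n < 2 for n, _, _ in groups):
        raise StatsError("need >= 2 groups with n >= 2 each")
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups])
    sds = np.array([g[2] for g in groups])
    total_n = ns.sum()
    grand = (ns * means).sum() / total_n
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df1 = len(groups) - 1
    df2 = total_n - len(groups)
    f = (ss_between / df1) / (ss_within / df2)
    return StatResult("anova", float(f), (float(df1), float(df2)), float(st.f.sf(f, df1, df2)))


def _design(group: np.ndarray, covariates: np.ndarray | None,
            levels: list[str]) -> tuple[np.ndarray, int]:
    """Full design [1 | covariates | group dummies]; returns it and the dummy count."""
    n = len(group)
    cols = [np.ones(n)]
    if covariates is not None and covariates.size:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    dummies = [(group == lev).astype(float) for lev in levels[1:]]
    x = np.column_stack(cols + dummies)
    return x, len(levels) - 1


def ancova_group_test(y: np.ndarray, group: np.ndarray,
                      covariates: np.ndarray | None = None,
                      bonferroni: bool = True) -> StatResult:
    """Group F test in the linear model y ~ intercept + covariates + group.

    The F statistic is the extra-sum-of-squares test of the group dummies.
    Post hoc: pairwise t tests on covariate-adjusted group means with
    Bonferroni correction (p x 3, capped at 1).  ``effect_direction`` orders
    the groups by adjusted mean, highest first.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = sorted(set(group.tolist()))
    if len(levels) < 2:
        raise StatsError("need at least two groups")
    x_full, n_dummies = _design(group, covariates, levels)
    x_red = x_full[:, : x_full.shape[1] - n_dummies]
    n, p_full = x_full.shape
    if np.linalg.matrix_rank(x_full) < p_full:
        raise StatsError("ANCOVA design matrix is rank deficient (collinear covariates/group)")
    beta, _, _, _ = np.linalg.lstsq(x_full, y, rcond=None)
    resid = y - x_full @ beta
    sse_full = float(resid @ resid)
    beta_r, _, _, _ = np.linalg.lstsq(x_red, y, rcond=None)
    resid_r = y - x_red @ beta_r
    sse_red = float(resid_r @ resid_r)
    df1 = n_dummies
    df2 = n - p_full
    f = ((sse_red - sse_full) / df1) / (sse_full / df2)
    p = float(st.f.sf(f, df1, df2))

    # pairwise contrasts on the dummy coefficients (reference level has 0)
    sigma2 = sse_full / df2
    xtx_inv = np.linalg.inv(x_full.T @ x_full)
    coef = {levels[0]: 0.0}
    idx = {levels[0]: None}
    for j, lev in enumerate(levels[1:]):
        coef[lev] = float(beta[p_full - n_dummies + j])
        idx[lev] = p_full - n_dummies + j
    posthoc = {}
    m = len(levels) * (len(levels) - 1) // 2
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            la, lb = levels[a], levels[b]
            contrast = np.zeros(p_full)
            if idx[la] is not None:
                contrast[idx[la]] = 1.0
            if idx[lb] is not None:
                contrast[idx[lb]] -= 1.0
            se = float(np.sqrt(sigma2 * contrast @ xtx_inv @ contrast))
            t = (coef[la] - coef[lb]) / se
            praw = 2 * st.t.sf(abs(t), df2)
            posthoc[(la, lb)] = float(min(1.0, praw * m)) if bonferroni else float(praw)
    order = sorted(levels, key=lambda g: coef[g], reverse=True)
    return StatResult("ancova", float(f), (float(df1), float(df2)), p,
                      posthoc=posthoc, effect_direction=" > ".join(order))


def partial_correlation_test(x: np.ndarray, y: np.ndarray,
                             covariates: np.ndarray | None = None,
                             pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson correlation of x and y after removing covariates from both.

    p value from the t transform with df = n - k - 2 (k covariate columns).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n < k + 3:
        raise StatsError("too few observations for the covariate count")
    design = np.column_stack([np.ones(n), cov])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if rx.std() <= 1e-10 * (x.std() + 1e-30) or ry.std() <= 1e-10 * (y.std() + 1e-30):
        raise StatsError("residuals are constant; correlation undefined")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * st.t.sf(abs(t), df))
    return CorrelationResult(pair, r, p)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise StatsError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
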