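"""Statistical comparisons: one-way ANOVA + LSD post-hoc, correlation/regression,
Bland–Altman agreement, and mean-error summaries.

These are the comparisons the study design calls for: ANOVA with Fisher's
least-significant-difference pairwise t-tests across target-to-background
groups and across threshold fractions; Pearson r and the ordinary
least-squares slope b (y on x, with intercept) between method pairs; and
Bland–Altman limits of agreement (mean difference ± 1.96 SD).  Everything is
callable on plain arrays, independent of the imaging stack.  Two-sided tests,
alpha = 0.05 throughout; no multiple-testing correction beyond LSD's
pooled-variance convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidParameterError

__all__ = [
    "AnovaResult",
    "AgreementResult",
    "one_way_anova",
    "lsd_posthoc",
    "pearson_and_slope",
    "bland_altman",
    "summarize_errors",
]


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    group_means: np.ndarray
    mse_within: float  # pooled within-group mean square (LSD error variance)


def _validate_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise InvalidParameterError("need at least two groups")
    if any(g.size < 2 for g in gs):
        raise InvalidParameterError("every group needs at least two observations")
    return gs


def one_way_anova(groups) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA (between/within decomposition)."""
    gs = _validate_groups(groups)
    all_x = np.concatenate(gs)
    grand = all_x.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = all_x.size - len(gs)
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
    else:
        f = (ss_between / df_b) / ms_w
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(F=float(f), p=p, df_between=df_b, df_within=df_w,
                       group_means=np.array([g.mean() for g in gs]), mse_within=float(ms_w))


def lsd_posthoc(groups) -> np.ndarray:
    """Fisher LSD pairwise p-value matrix (pooled MSE, ANOVA within df).

    Returns a symmetric k x k matrix with ones on the diagonal;
    entry (i, j) is the two-sided p for H0: mean_i = mean_j using
    t = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j)).
    """
    gs = _validate_groups(groups)
    res = one_way_anova(gs)
    k = len(gs)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(res.mse_within * (1.0 / gs[i].size + 1.0 / gs[j].size))
            if se == 0.0:
                pij = 1.0 if gs[i].mean() == gs[j].mean() else 0.0
            else:
                t = (gs[i].mean() - gs[j].mean()) / se
                pij = 2.0 * float(sps.t.sf(abs(t), res.df_within))
            p[i, j] = p[j, i] = pij
    return p


def pearson_and_slope(x, y) -> tuple[float, float]:
    """Sample Pearson r and the OLS slope b of y on x (intercept included)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("x and y must have equal length >= 3")
    if np.ptp(x) == 0:
        raise InvalidParameterError("x has zero variance")
    r = float(sps.pearsonr(x, y).statistic)
    b = float(sps.linregress(x, y).slope)
    return r, b


@dataclass
class AgreementResult:
    """Bland–Altman agreement between two paired measurement series (a - b)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within_loa: float
    r: float
    b: float
    diffs: np.ndarray
    means: np.ndarray


def bland_altman(a, b) -> AgreementResult:
    """Limits of agreement mean ± 1.96 SD for paired differences a - b.

    Also reports Pearson r and regression slope of a on b for convenience
    (b is treated as the reference method).
    """
    a = np.asarray(a, dtype=float).ravel()
    b_arr = np.asarray(b, dtype=float).ravel()
    if a.size != b_arr.size:
        raise InvalidParameterError("paired series must have equal length")
    if a.size < 3:
        raise InvalidParameterError("need at least three pairs")
    diffs = a - b_arr
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    lo, hi = mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff
    within = float(np.mean((diffs >= lo) & (diffs <= hi)) * 100.0)
    if np.ptp(b_arr) > 0:
        r, slope = pearson_and_slope(b_arr, a)
    else:
        r, slope = np.nan, np.nan
    return AgreementResult(mean_diff=mean_diff, sd_diff=sd_diff, loa_low=lo, loa_high=hi,
                           pct_within_loa=within, r=r, b=slope,
                           diffs=diffs, means=(a + b_arr) / 2.0)


def summarize_errors(values) -> float:
    """Arithmetic mean of percent errors, reported to two decimals."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise InvalidParameterError("no error values supplied")
    return float(round(v.mean(), 2))
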