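"""Group-comparison and correlation statistics for glycan traits.

The workflow mirrors routine clinical-glycomics practice: each trait is
tested for normality (one-sample Kolmogorov-Smirnov against a fitted
Gaussian); normally distributed traits go to one-way ANOVA with Bonferroni-
corrected pairwise contrasts, the rest to Kruskal-Wallis with Dunn's
post-hoc test.  Diagnostic performance of a single score is summarized by
the ROC AUC in its rank (Mann-Whitney) formulation, and trait-biomarker
association by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

__all__ = [
    "PairwiseContrast",
    "GroupComparisonResult",
    "CorrelationResult",
    "ks_normality",
    "anova_bonferroni",
    "kruskal_dunn",
    "pearson",
    "roc_auc",
]


@dataclass(frozen=True)
class PairwiseContrast:
    group_a: str
    group_b: str
    mean_difference: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparisonResult:
    variable: str
    group_names: Tuple[str, ...]
    group_means: Tuple[float, ...]
    group_sds: Tuple[float, ...]
    test_name: str
    statistic: float
    p_value: float
    contrasts: Tuple[PairwiseContrast, ...]


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p_value: float
    n: int


def ks_normality(x: Sequence[float], lilliefors: bool = False) -> Tuple[float, float]:
    """One-sample K-S test of x against a normal with estimated mean/SD.

    Returns (statistic, p).  Constant input gets p = 0.0 (treated as
    non-Gaussian, since a degenerate distribution has no density).  The
    plain K-S p-value with estimated parameters is anticonservative; set
    ``lilliefors=True`` for the corrected version.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError(f"K-S normality test needs n >= 5, got {x.size}")
    if np.ptp(x) == 0:
        return float("nan"), 0.0
    if lilliefors:
        stat, p = _lilliefors(x, dist="norm")
        return float(stat), float(p)
    stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(stat), float(p)


def _check_groups(groups: Sequence[Sequence[float]], names: Sequence[str] | None, min_n: int):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.size < min_n:
            raise ValueError(f"group {i} has n={g.size} < {min_n}")
    if names is None:
        names = [f"group{i + 1}" for i in range(len(arrays))]
    return arrays, tuple(str(n) for n in names)


def anova_bonferroni(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    variable: str = "",
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """One-way ANOVA with Bonferroni-corrected pairwise contrasts.

    Pairwise mean differences use the pooled within-group variance (ANOVA
    mean-square error, N - k df); adjusted p = min(1, m * p_raw) with m the
    number of pairwise comparisons, and the 95% CI of each difference is
    widened to the Bonferroni-adjusted confidence level 1 - alpha/m.
    """
    arrays, names = _check_groups(groups, names, min_n=2)
    f_stat, p = sps.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    df_err = n_total - k
    mse = sum((a.size - 1) * a.var(ddof=1) for a in arrays) / df_err
    m = k * (k - 1) // 2
    contrasts: List[PairwiseContrast] = []
    for (i, a), (j, b) in combinations(enumerate(arrays), 2):
        diff = a.mean() - b.mean()
        se = np.sqrt(mse * (1 / a.size + 1 / b.size))
        if se == 0:
            t_stat, p_raw, half = 0.0, 1.0, 0.0
        else:
            t_stat = diff / se
            p_raw = 2 * sps.t.sf(abs(t_stat), df_err)
            half = sps.t.ppf(1 - alpha / (2 * m), df_err) * se
        contrasts.append(
            PairwiseContrast(
                names[i], names[j], float(diff),
                float(diff - half), float(diff + half),
                float(p_raw), float(min(1.0, m * p_raw)),
            )
        )
    return GroupComparisonResult(
        variable=variable,
        group_names=names,
        group_means=tuple(float(a.mean()) for a in arrays),
        group_sds=tuple(float(a.std(ddof=1)) for a in arrays),
        test_name="anova",
        statistic=float(f_stat),
        p_value=float(p),
        contrasts=tuple(contrasts),
    )


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    variable: str = "",
) -> GroupComparisonResult:
    """Kruskal-Wallis test with Dunn's post-hoc z tests (Bonferroni adjusted).

    Dunn's z uses pooled mean ranks and the tie-corrected variance
    (N(N+1)/12 - T)(1/n_i + 1/n_j) with T = sum(t^3 - t)/(12(N-1)).  The CI
    fields of the contrasts report the rank-mean difference +/- the critical
    half-width at the Bonferroni-adjusted level (Dunn's test has no CI on the
    original scale).
    """
    arrays, names = _check_groups(groups, names, min_n=1)
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    ranks = sps.rankdata(pooled)
    split = np.cumsum([a.size for a in arrays])[:-1]
    group_ranks = np.split(ranks, split)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(arrays) * (len(arrays) - 1) // 2
    contrasts: List[PairwiseContrast] = []
    for (i, ra), (j, rb) in combinations(enumerate(group_ranks), 2):
        diff = float(ra.mean() - rb.mean())
        se = float(np.sqrt(base_var * (1 / ra.size + 1 / rb.size)))
        if se == 0:
            z, p_raw, half = 0.0, 1.0, 0.0
        else:
            z = diff / se
            p_raw = 2 * sps.norm.sf(abs(z))
            half = sps.norm.ppf(1 - 0.05 / (2 * m)) * se
        contrasts.append(
            PairwiseContrast(
                names[i], names[j], diff, diff - half, diff + half,
                float(p_raw), float(min(1.0, m * p_raw)),
            )
        )
    return GroupComparisonResult(
        variable=variable,
        group_names=names,
        group_means=tuple(float(a.mean()) for a in arrays),
        group_sds=tuple(float(a.std(ddof=1)) if a.size > 1 else 0.0 for a in arrays),
        test_name="kruskal-wallis",
        statistic=float(h),
        p_value=float(p),
        contrasts=tuple(contrasts),
    )


def pearson(x: Sequence[float], y: Sequence[float], var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Pearson correlation with the t-distribution p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError(f"Pearson correlation needs n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(var_x, var_y, float(r), float(p), int(x.size))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC by the rank (Mann-Whitney) formulation; ties count 1/2.

    ``labels`` are binary (1 = positive).  Equals the probability that a
    random positive scores above a random negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = sps.rankdata(scores)
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
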