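"""Nonparametric group comparisons implemented from their formulas.

Kruskal-Wallis one-way ANOVA on ranks with the tie correction, and Dunn's
post hoc z test with Bonferroni adjustment over all k(k-1)/2 pairs.
Mid-ranks are used for ties and the chi-square approximation for the
Kruskal-Wallis p value (the intended group sizes are large).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import chi2, norm, rankdata

__all__ = ["GroupedValues", "PairwiseResult", "TestResult", "kruskal_wallis", "dunn_bonferroni"]


@dataclass(frozen=True)
class GroupedValues:
    """Labelled groups of values; >= 2 non-empty groups, total n >= 3."""

    groups: tuple

    def __post_init__(self) -> None:
        groups = tuple((label, tuple(float(v) for v in vals)) for label, vals in self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) < 2:
            raise ValueError("need at least two groups")
        if any(len(vals) == 0 for _, vals in groups):
            raise ValueError("every group must be non-empty")
        if sum(len(vals) for _, vals in groups) < 3:
            raise ValueError("need total n >= 3")

    @property
    def labels(self):
        return tuple(label for label, _ in self.groups)


@dataclass(frozen=True)
class PairwiseResult:
    label_a: str
    label_b: str
    z: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    pairwise: tuple = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")


def _pooled_ranks(data: GroupedValues):
    sizes = [len(vals) for _, vals in data.groups]
    pooled = np.concatenate([np.asarray(vals) for _, vals in data.groups])
    ranks = rankdata(pooled)  # mid-ranks for ties
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    # tie sizes over the pooled sample
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return split, sizes, tie_term


def kruskal_wallis(data: GroupedValues) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square with k-1 df.

    H = [12/(N(N+1))] * sum R_i^2/n_i - 3(N+1), divided by the correction
    1 - sum(t^3 - t)/(N^3 - N).  All values tied gives H = 0, p = 1.
    """
    split, sizes, tie_term = _pooled_ranks(data)
    n_total = sum(sizes)
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        r.sum() ** 2 / n for r, n in zip(split, sizes)
    ) - 3.0 * (n_total + 1)
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:  # every value identical
        return TestResult(statistic=0.0, df=len(sizes) - 1, p_value=1.0)
    h /= correction
    h = max(h, 0.0)  # guard tiny negative round-off
    df = len(sizes) - 1
    return TestResult(statistic=float(h), df=df, p_value=float(chi2.sf(h, df)))


def dunn_bonferroni(data: GroupedValues) -> TestResult:
    """Dunn's post hoc test on mean ranks, Bonferroni-adjusted.

    For each pair (i, j):
    z = (Rbar_i - Rbar_j) / sqrt{[N(N+1)/12 - sum(t^3 - t)/(12(N-1))](1/n_i + 1/n_j)}
    with two-sided normal p, multiplied by the full m = k(k-1)/2.
    The overall statistic/df/p are the Kruskal-Wallis ones on the same data.
    """
    split, sizes, tie_term = _pooled_ranks(data)
    n_total = sum(sizes)
    k = len(sizes)
    m = k * (k - 1) // 2
    variance_core = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks = [float(r.mean()) for r in split]
    pairwise = []
    for i, j in combinations(range(k), 2):
        denom = variance_core * (1.0 / sizes[i] + 1.0 / sizes[j])
        if denom <= 0:  # all values tied across the pooled sample
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom)
            p_raw = float(2.0 * norm.sf(abs(z)))
        pairwise.append(
            PairwiseResult(
                label_a=data.labels[i],
                label_b=data.labels[j],
                z=float(z),
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * m),
            )
        )
    omnibus = kruskal_wallis(data)
    return TestResult(
        statistic=omnibus.statistic,
        df=omnibus.df,
        p_value=omnibus.p_value,
        pairwise=tuple(pairwise),
    )
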