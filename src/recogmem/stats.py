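"""Thin statistical contracts used across the analysis figures.

Nonparametric tests for small-cohort comparisons (Wilcoxon signed-rank for
paired data, rank-sum for unpaired), one-way ANOVA with Tukey-Kramer (or a
rank-based post hoc), and Pearson correlation. Standard scipy routines stand
behind every contract; this module fixes the conventions (two-sided
alternatives, exact signed-rank p for small n, midrank tie handling) and the
result container.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as spstats

__all__ = [
    "TestResult",
    "PairwiseResult",
    "paired_compare",
    "rank_sum",
    "group_compare",
    "correlate",
    "grubbs_outlier",
    "significance_band",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n: int
    test: str
    alternative: str = "two-sided"
    group_ns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_adjusted: float


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p under the sign-flip null with midranks.

    The null distribution of W+ (sum of midranks of positive differences) is
    built by dynamic programming over independent sign flips; midranks are
    doubled so the support stays integral. Matches the classical exact test
    when |d| has no ties and extends it exactly when it does.
    """
    ranks = spstats.rankdata(np.abs(d))
    w2 = np.rint(2 * ranks).astype(int)  # doubled midranks are integers
    total = int(w2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for w in w2:
        shifted = np.zeros_like(dist)
        shifted[w:] = dist[: total + 1 - w]
        dist = 0.5 * (dist + shifted)
    w_plus = float(ranks[d > 0].sum())
    w_obs = int(round(2 * w_plus))
    p_low = dist[: w_obs + 1].sum()
    p_high = dist[w_obs:].sum()
    return w_plus, float(min(1.0, 2.0 * min(p_low, p_high)))


def paired_compare(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are discarded (Wilcoxon convention); at least 5 nonzero
    pairs are required. The p-value is exact for n <= 25 (sign-flip
    enumeration with midranks for ties) and a tie-corrected normal
    approximation beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    if d.size < 5:
        raise ValueError("need at least 5 nonzero paired differences")
    if d.size <= 25:
        stat, p = _exact_signed_rank_p(d)
        # report min(W+, W-) like the classical statistic
        stat = min(stat, d.size * (d.size + 1) / 2 - stat)
        return TestResult(float(stat), p, int(d.size), "wilcoxon-signed-rank")
    res = spstats.wilcoxon(d, alternative="two-sided", method="approx")
    return TestResult(float(res.statistic), float(res.pvalue), int(d.size), "wilcoxon-signed-rank")


def rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for unpaired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = spstats.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(
        float(res.statistic), float(res.pvalue), int(x.size + y.size), "rank-sum",
        group_ns=(int(x.size), int(y.size)),
    )


def group_compare(
    groups: dict[str, Sequence[float]],
    posthoc: Literal["tukey", "ranksum"] = "tukey",
) -> tuple[TestResult, list[PairwiseResult]]:
    """One-way ANOVA omnibus with pairwise post-hoc comparisons.

    ``posthoc='tukey'`` runs Tukey-Kramer (honestly significant difference
    with unequal group sizes); ``'ranksum'`` runs pairwise rank-sum tests
    with Holm correction, the rank-based post hoc used when group
    distributions are skewed. Requires >= 2 groups of >= 2 values each.
    """
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    if len(data) < 2 or any(len(g) < 2 for g in data):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(data)
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate data: all values identical")
    # identical group means with positive within-group variance -> F = 0, p = 1
    f_res = spstats.f_oneway(*data)
    omnibus = TestResult(
        float(f_res.statistic), float(f_res.pvalue), int(pooled.size), "one-way-anova",
        group_ns=tuple(len(g) for g in data),
    )
    pairwise: list[PairwiseResult] = []
    if posthoc == "tukey":
        res = spstats.tukey_hsd(*data)
        for i, j in itertools.combinations(range(len(data)), 2):
            pairwise.append(
                PairwiseResult((names[i], names[j]), float(res.statistic[i, j]), float(res.pvalue[i, j]))
            )
    else:
        raw = []
        for i, j in itertools.combinations(range(len(data)), 2):
            r = spstats.mannwhitneyu(data[i], data[j], alternative="two-sided")
            raw.append(((names[i], names[j]), float(r.statistic), float(r.pvalue)))
        # Holm step-down adjustment
        order = np.argsort([p for *_, p in raw])
        m = len(raw)
        adj = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * raw[idx][2]))
            adj[idx] = running
        for (pair, stat, _), p_adj in zip(raw, adj):
            pairwise.append(PairwiseResult(pair, stat, p_adj))
    return omnibus, pairwise


def correlate(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with a two-sided p-value (n >= 3 finite pairs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = spstats.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), int(x.size), "pearson")


def grubbs_outlier(x: Sequence[float], alpha: float = 0.05) -> Optional[int]:
    """Two-sided single-outlier Grubbs test; optional data pre-filter.

    Returns the index of the detected outlier, or ``None``. Off by default in
    every pipeline stage; callers that apply it should log the removal.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return None
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - mu)
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    t2 = spstats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t2 / (n - 2 + t2))
    return idx if g > g_crit else None


def significance_band(p: float) -> str:
    """Render a p-value as the conventional significance band."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
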