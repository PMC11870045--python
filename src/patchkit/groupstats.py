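"""Normality-gated group statistics and percent-change summaries.

The comparison logic mirrors common practice in cellular
electrophysiology: data are first screened with the Shapiro-Wilk test
(gate alpha = 0.05); paired comparisons then use Student's paired t test
when the paired differences look Gaussian and Wilcoxon's signed-rank
test otherwise (exact null distribution for n <= 25, normal
approximation with continuity correction above); multi-group comparisons
use one-way ANOVA with Holm-Sidak pairwise post hocs when every group
passes the gate and Kruskal-Wallis with Dunn's rank post hocs otherwise.
Every result records which branch fired.

Percent change between condition means is 100*(post - pre)/pre, reported
both at full precision and rounded to the nearest integer (the
convention used when quoting drug effects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "GroupComparison",
    "paired_compare",
    "group_compare",
    "percent_change",
    "dunn_posthoc",
]

GATE_ALPHA = 0.05
WILCOXON_EXACT_MAX_N = 25


@dataclass
class ComparisonResult:
    """A two-condition comparison with the branch that produced it."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    percent_change: float
    percent_change_rounded: int | float
    shapiro_p: float = math.nan
    flags: list = field(default_factory=list)


def percent_change(mean_pre: float, mean_post: float):
    """100*(post - pre)/pre, full precision and nearest-integer rounded."""
    if mean_pre == 0:
        raise ValueError("percent change undefined for a zero pre-mean")
    full = 100.0 * (mean_post - mean_pre) / mean_pre
    return full, int(round(full))


def paired_compare(pre, post, alpha_gate: float = GATE_ALPHA
                   ) -> ComparisonResult:
    """Shapiro-Wilk-gated paired comparison.

    The gate is applied to the paired differences: p >= ``alpha_gate``
    selects the paired t test, otherwise the Wilcoxon signed-rank test.
    Degenerate all-zero differences report p = 1 with a flag.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    n = len(pre)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    diff = post - pre
    flags: list[str] = []
    try:
        pc_full, pc_round = percent_change(pre.mean(), post.mean())
    except ValueError:
        pc_full, pc_round = math.nan, math.nan
        flags.append("zero pre-mean: percent change undefined")

    if np.all(diff == 0):
        return ComparisonResult(
            test_name="degenerate (all differences zero)",
            statistic=math.nan, p_value=1.0, n=n,
            mean_pre=float(pre.mean()), sd_pre=float(pre.std(ddof=1)),
            mean_post=float(post.mean()), sd_post=float(post.std(ddof=1)),
            percent_change=pc_full, percent_change_rounded=pc_round,
            flags=flags + ["degenerate difference vector"],
        )
    if np.ptp(diff) == 0:
        # constant nonzero shift: Shapiro undefined, normality moot
        shapiro_p = 1.0
        flags.append("constant differences; normal branch by convention")
    else:
        shapiro_p = float(stats.shapiro(diff).pvalue)
    if shapiro_p >= alpha_gate:
        res = stats.ttest_rel(post, pre)
        name = "paired t test"
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        # exact null for small n; ties/zeros force the approximation
        exact_ok = (
            n <= WILCOXON_EXACT_MAX_N
            and not np.any(diff == 0)
            and len(np.unique(np.abs(diff))) == len(diff)
        )
        method = "exact" if exact_ok else "approx"
        res = stats.wilcoxon(
            post, pre, method=method, correction=(method == "approx")
        )
        name = f"Wilcoxon signed-rank ({method})"
        statistic, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        test_name=name, statistic=statistic, p_value=p, n=n,
        mean_pre=float(pre.mean()), sd_pre=float(pre.std(ddof=1)),
        mean_post=float(post.mean()), sd_post=float(post.std(ddof=1)),
        percent_change=pc_full, percent_change_rounded=pc_round,
        shapiro_p=shapiro_p, flags=flags,
    )


def dunn_posthoc(groups: list[np.ndarray], names=None) -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests after Kruskal-Wallis.

    Uses pooled ranks with tie correction; two-sided p-values are
    Holm-adjusted (so adjusted >= raw for every pair).
    """
    if names is None:
        names = [f"group_{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    raw_ps = []
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((names[i], names[j], z, p))
        raw_ps.append(p)
    adj = multipletests(raw_ps, method="holm")[1] if raw_ps else []
    return pd.DataFrame(
        [(a, b, z, p, q) for (a, b, z, p), q in zip(rows, adj)],
        columns=["group_a", "group_b", "statistic", "p_raw", "p_adj"],
    )


def _holm_sidak_posthoc(groups, names) -> pd.DataFrame:
    """Pairwise Welch t tests with Holm-Sidak adjustment."""
    rows = []
    raw_ps = []
    for i, j in combinations(range(len(groups)), 2):
        res = stats.ttest_ind(groups[i], groups[j])
        rows.append((names[i], names[j], float(res.statistic),
                     float(res.pvalue)))
        raw_ps.append(float(res.pvalue))
    adj = multipletests(raw_ps, method="holm-sidak")[1] if raw_ps else []
    return pd.DataFrame(
        [(a, b, t, p, q) for (a, b, t, p), q in zip(rows, adj)],
        columns=["group_a", "group_b", "statistic", "p_raw", "p_adj"],
    )


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    group_names: list
    group_n: list
    posthoc: pd.DataFrame
    shapiro_p: list
    flags: list = field(default_factory=list)


def group_compare(groups, names=None, alpha_gate: float = GATE_ALPHA
                  ) -> GroupComparison:
    """Shapiro-Wilk-gated omnibus comparison of >= 2 groups.

    All groups normal -> one-way ANOVA with Holm-Sidak pairwise post
    hocs; otherwise Kruskal-Wallis with Dunn's post hocs.  Groups with
    n < 3 are excluded with a warning flag.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if names is None:
        names = [f"group_{i + 1}" for i in range(len(groups))]
    flags = []
    kept, kept_names = [], []
    for g, nm in zip(groups, names):
        if len(g) < 3:
            flags.append(f"excluded {nm}: n={len(g)} < 3")
        else:
            kept.append(g)
            kept_names.append(nm)
    if len(kept) < 2:
        raise ValueError("need at least 2 groups with n >= 3")
    shapiro_ps = []
    for g in kept:
        if np.ptp(g) == 0:
            shapiro_ps.append(0.0)  # constant group: treat as non-normal
        else:
            shapiro_ps.append(float(stats.shapiro(g).pvalue))
    all_normal = all(p >= alpha_gate for p in shapiro_ps)
    if all_normal:
        res = stats.f_oneway(*kept)
        name = "one-way ANOVA + Holm-Sidak"
        posthoc = _holm_sidak_posthoc(kept, kept_names)
    else:
        res = stats.kruskal(*kept)
        name = "Kruskal-Wallis + Dunn"
        posthoc = dunn_posthoc(kept, kept_names)
    return GroupComparison(
        test_name=name, statistic=float(res.statistic),
        p_value=float(res.pvalue), group_names=kept_names,
        group_n=[len(g) for g in kept], posthoc=posthoc,
        shapiro_p=shapiro_ps, flags=flags,
    )
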