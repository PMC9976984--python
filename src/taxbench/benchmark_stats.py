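"""Normality-routed comparison tests and cross-tool rank correlation.

Tool sensitivities are compared with a location test chosen by a normality
gate: Shapiro–Wilk below 30 observations, the Lilliefors variant of the
Kolmogorov–Smirnov test from 30 up.  Samples that both look normal get a
two-sample t-test (ANOVA beyond two groups); otherwise the Wilcoxon
rank-sum test.  Variance ranges are compared with Fligner–Killeen, and
per-species sensitivity profiles across tools with Spearman's rank
correlation.  Significance is declared below alpha = 0.05 throughout; no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ComparisonReport",
    "normality_route",
    "normality_pvalue",
    "compare_groups",
    "compare_variances",
    "anova",
    "spearman_matrix",
]

SMALL_SAMPLE_LIMIT = 30  # Shapiro-Wilk below this n, Lilliefors from it up


@dataclass(frozen=True)
class ComparisonReport:
    groups: Tuple[str, ...]
    test_name: str
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    note: str = ""


def _check_sample(x: Sequence[float], name: str = "sample") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError(f"{name} needs at least 3 one-dimensional observations")
    return arr


def normality_route(sample: Sequence[float]) -> str:
    """Name the normality test appropriate for this sample size."""
    arr = _check_sample(sample)
    return "shapiro-wilk" if arr.size < SMALL_SAMPLE_LIMIT else "lilliefors"


def normality_pvalue(sample: Sequence[float]) -> Tuple[str, float]:
    """Run the routed normality test; returns (test name, p-value)."""
    arr = _check_sample(sample)
    route = normality_route(arr)
    if np.ptp(arr) == 0:
        # constant sample: normality is undefined; treat as non-normal
        return route, 0.0
    if route == "shapiro-wilk":
        return route, float(stats.shapiro(arr).pvalue)
    _, pval = lilliefors(arr, dist="norm")
    return route, float(pval)


def compare_groups(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alpha: float = 0.05,
    names: Tuple[str, str] = ("a", "b"),
) -> ComparisonReport:
    """Two-group location comparison with normality routing.

    Both samples normal at ``alpha`` -> two-sample t-test; otherwise
    Wilcoxon rank-sum (normal approximation handles ties).  A pair of
    constant samples is flagged and not tested.
    """
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        equal = a[0] == b[0]
        return ComparisonReport(
            groups=names,
            test_name="none",
            statistic=float("nan"),
            p_value=float("nan"),
            alpha=alpha,
            significant=False,
            note="constant samples; not tested"
            + ("" if equal else " (locations differ but carry no variance)"),
        )
    _, pa = normality_pvalue(a)
    _, pb = normality_pvalue(b)
    if pa >= alpha and pb >= alpha:
        res = stats.ttest_ind(a, b)
        test = "t-test"
    else:
        res = stats.ranksums(a, b)
        test = "wilcoxon-rank-sum"
    pval = float(res.pvalue)
    return ComparisonReport(
        groups=names,
        test_name=test,
        statistic=float(res.statistic),
        p_value=pval,
        alpha=alpha,
        significant=pval < alpha,
    )


def anova(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ComparisonReport:
    """One-way ANOVA across >2 groups of (routed-normal) scores."""
    if len(groups) < 3:
        raise ValueError("anova expects more than two groups")
    arrays = [_check_sample(v, k) for k, v in groups.items()]
    res = stats.f_oneway(*arrays)
    pval = float(res.pvalue)
    return ComparisonReport(
        groups=tuple(groups),
        test_name="anova",
        statistic=float(res.statistic),
        p_value=pval,
        alpha=alpha,
        significant=pval < alpha,
    )


def compare_variances(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ComparisonReport:
    """Spread comparison across groups (Fligner–Killeen, rank-based)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [_check_sample(v, k) for k, v in groups.items()]
    res = stats.fligner(*arrays)
    pval = float(res.pvalue)
    return ComparisonReport(
        groups=tuple(groups),
        test_name="fligner-killeen",
        statistic=float(res.statistic),
        p_value=pval,
        alpha=alpha,
        significant=pval < alpha,
    )


def spearman_matrix(
    sensitivities_by_tool: Mapping[str, Mapping[str, float]] | pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho between tools' per-species sensitivity profiles.

    Input: tool -> (species -> sensitivity), or an equivalent DataFrame with
    species as rows and tools as columns.  Correlations use pairwise
    complete observations; every tool pair needs >= 3 shared species.
    Returns (rho matrix, p-value matrix), both symmetric with unit/zero
    diagonals.
    """
    df = (
        sensitivities_by_tool
        if isinstance(sensitivities_by_tool, pd.DataFrame)
        else pd.DataFrame(sensitivities_by_tool)
    )
    tools = list(df.columns)
    rho = pd.DataFrame(np.eye(len(tools)), index=tools, columns=tools)
    pmat = pd.DataFrame(np.zeros((len(tools), len(tools))), index=tools, columns=tools)
    for i, t1 in enumerate(tools):
        for t2 in tools[i + 1 :]:
            sub = df[[t1, t2]].dropna()
            if len(sub) < 3:
                raise ValueError(
                    f"tools {t1!r} and {t2!r} share fewer than 3 species"
                )
            res = stats.spearmanr(sub[t1], sub[t2])
            rho.loc[t1, t2] = rho.loc[t2, t1] = float(res.statistic)
            pmat.loc[t1, t2] = pmat.loc[t2, t1] = float(res.pvalue)
    return rho, pmat
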