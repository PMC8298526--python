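"""Group comparisons following the normality-gated decision tree.

Each data set is first checked with the D'Agostino–Pearson omnibus
normality test.  If every group passes (and every group has n >= 8, the
minimum for the test), two groups are compared with Student's t-test;
otherwise two groups fall to Mann–Whitney, and three or more groups to
Kruskal–Wallis with Dunn's multiple-comparison post-hoc.  Significance
stars: *p<0.05, **p<0.01, ***p<0.001, ****p<0.0001.  All tests two-sided.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_NORMALITY = 0.05
MIN_N_NORMALITY = 8


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    metric_name: str
    group_names: list[str]
    normality_p: dict
    test_used: str                 # t | MannWhitney | KruskalWallis+Dunn
    statistic: float
    p_value: float                 # omnibus (or the single pairwise) p
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> str:
        lines = [
            f"{self.metric_name}: {self.test_used}, "
            f"stat={self.statistic:.4g}, p={self.p_value:.4g}"
        ]
        for _, r in self.pairwise.iterrows():
            lines.append(
                f"  {r['group_a']} vs {r['group_b']}: p={r['p']:.4g} {r['stars']}"
            )
        return "\n".join(lines)


def _dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc after Kruskal–Wallis.

    Rank-sum z statistics with tie correction; two-sided p-values
    Bonferroni-adjusted over all pairs (the adjustment built into the
    procedure; no further correction is layered on).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    i = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = ranks[i : i + n].mean()
        sizes[g] = n
        i += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = min(2.0 * stats.norm.sf(abs(z)) * m, 1.0)
        rows.append(
            {"group_a": a, "group_b": b, "statistic": z, "p": p,
             "stars": significance_stars(p)}
        )
    return pd.DataFrame(rows)


def choose_and_run_test(
    groups: dict[str, np.ndarray],
    metric_name: str = "",
    alpha_normality: float = ALPHA_NORMALITY,
) -> GroupComparison:
    """Apply the decision tree to named value lists."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    groups = {k: np.asarray(v, float) for k, v in groups.items()}
    names = list(groups)

    normality_p: dict[str, float] = {}
    all_normal = True
    for g, v in groups.items():
        if len(v) < MIN_N_NORMALITY:
            warnings.warn(
                f"group {g!r} has n={len(v)} < {MIN_N_NORMALITY}: normality "
                "untestable, falling back to non-parametric",
                stacklevel=2,
            )
            normality_p[g] = float("nan")
            all_normal = False
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.normaltest(v).pvalue)
            normality_p[g] = p
            all_normal = all_normal and p > alpha_normality

    if len(groups) == 2:
        a, b = (groups[n] for n in names)
        if all_normal:
            res = stats.ttest_ind(a, b)
            test = "t"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "MannWhitney"
        stat, p = float(res.statistic), float(res.pvalue)
        pairwise = pd.DataFrame(
            [{"group_a": names[0], "group_b": names[1], "statistic": stat,
              "p": p, "stars": significance_stars(p)}]
        )
    else:
        res = stats.kruskal(*groups.values())
        stat, p = float(res.statistic), float(res.pvalue)
        test = "KruskalWallis+Dunn"
        pairwise = _dunn_test(groups)

    return GroupComparison(
        metric_name=metric_name,
        group_names=names,
        normality_p=normality_p,
        test_used=test,
        statistic=stat,
        p_value=p,
        pairwise=pairwise,
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie handling; NaN rs on constant input."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman rs undefined", stacklevel=2)
        return float("nan"), float("nan")
    rs, p = stats.spearmanr(x, y)
    return float(rs), float(p)


def mean_sem_table(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-group mean, SEM (= sd/√n) and n."""
    if not groups:
        raise ValueError("no groups")
    rows = []
    for g, v in groups.items():
        v = np.asarray(v, float)
        n = len(v)
        sem = float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append({"group": g, "mean": float(v.mean()), "sem": sem, "n": n})
    return pd.DataFrame(rows)


def compare_long_table(df: pd.DataFrame) -> list[GroupComparison]:
    """Run the decision tree per metric on a long-format (metric, group, value) table."""
    out = []
    for metric, grp in df.groupby("metric"):
        named = {
            str(g): sub["value"].to_numpy(float)
            for g, sub in grp.groupby("group")
        }
        if len(named) >= 2:
            out.append(choose_and_run_test(named, metric_name=str(metric)))
    return out
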