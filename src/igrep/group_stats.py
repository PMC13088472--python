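"""Nonparametric comparison layer.

Paired longitudinal comparisons use the Wilcoxon signed-rank test (exact
two-sided p for small tie-free samples, tie-corrected normal approximation
otherwise), cross-sectional two-group comparisons the Mann-Whitney U test,
multi-group comparisons the Kruskal-Wallis test with Dunn's Bonferroni-
corrected post hoc z-tests, and overlap grids Benjamini-Hochberg adjustment.
A declarative comparison plan drives grids of (metric, subset, comparison)
cells and reports figure-legend significance tiers (# p<0.1, * p<0.05,
** p<0.01, *** p<0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: switchover sample sizes between exact enumeration and normal approximation
WILCOXON_EXACT_MAX_N = 25
MANNWHITNEY_EXACT_MAX_N = 12


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    groups: tuple
    n: tuple
    adjusted_p: float | None = None
    pairwise: list = field(default_factory=list)


def significance_tier(p: float) -> str:
    """Figure-legend tiers: # p<0.1, * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "#"
    return "ns"


def wilcoxon_signed_rank(values_a, values_b, labels=("a", "b")) -> TestResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped; exact p when the remaining n is <= 25 and
    the absolute differences are tie-free, tie-corrected normal approximation
    otherwise.  All-zero differences give the degenerate p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, labels, (len(a), len(b)))
    ties = len(np.unique(np.abs(nz))) < nz.size
    method = "exact" if (nz.size <= WILCOXON_EXACT_MAX_N and not ties) else "approx"
    res = sps.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method=method,
        correction=(method == "approx"),
    )
    return TestResult(
        "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue),
        labels, (len(a), len(b)),
    )


def mann_whitney_u(values_a, values_b, labels=("a", "b")) -> TestResult:
    """Mann-Whitney U test for two independent groups, two-sided.

    Exact p by enumeration when n_a + n_b <= 12 and there are no ties,
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size + b.size <= MANNWHITNEY_EXACT_MAX_N and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        "mann_whitney_u", float(res.statistic), float(res.pvalue),
        labels, (a.size, b.size),
    )


@dataclass
class DunnResult:
    group_a: str
    group_b: str
    z: float
    p_value: float
    adjusted_p: float


def kruskal_wallis_dunn(groups: dict) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's Bonferroni post hoc z-tests.

    Requires at least three nonempty groups (use :func:`mann_whitney_u` for
    two).  Dunn z-statistics compare mean ranks with the tie-corrected pooled
    variance; adjusted p-values multiply by the number of pairwise comparisons
    (capped at 1).
    """
    names = sorted(groups)
    if len(names) < 3:
        raise ValueError("kruskal_wallis_dunn needs >= 3 groups; use mann_whitney_u")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(arr.size == 0 for arr in arrays):
        raise ValueError("all groups must be nonempty")
    if all(np.all(arr == arrays[0][0]) for arr in arrays):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = [], []
    pos = 0
    for arr in arrays:
        mean_ranks.append(ranks[pos : pos + arr.size].mean())
        sizes.append(arr.size)
        pos += arr.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_comparisons = len(names) * (len(names) - 1) // 2
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_ij = 2.0 * sps.norm.sf(abs(z))
            pairwise.append(
                DunnResult(names[i], names[j], float(z), float(p_ij),
                           float(min(1.0, p_ij * n_comparisons)))
            )
    return TestResult(
        "kruskal_wallis_dunn", float(h), float(p), tuple(names),
        tuple(sizes), pairwise=pairwise,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment; input order preserved in the output."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_comparison_plan(metrics_table: pd.DataFrame, plan: list[dict]) -> pd.DataFrame:
    """Run a declarative grid of comparisons over a tidy metrics table.

    Each plan item is a dict with keys:
      ``test``: wilcoxon_signed_rank | mann_whitney_u | kruskal_wallis_dunn;
      ``metric``: value of the ``metric`` column to select;
      ``group_col``: grouping column; ``groups``: labels to compare;
      optional ``pair_col``: pairing column for the paired test;
      optional ``strata``: column whose levels each get their own test;
      optional ``global_bh``: apply Benjamini-Hochberg across the resulting
      rows of this item (the overlap-analysis convention).
    Empty plans give empty results.
    """
    results = []
    for item in plan:
        needed = {item["metric_col"] if "metric_col" in item else "metric",
                  item["group_col"], *( [item["pair_col"]] if "pair_col" in item else [] ),
                  *( [item["strata"]] if "strata" in item else [] )}
        missing = needed - set(metrics_table.columns)
        if missing:
            raise KeyError(f"plan references absent columns: {sorted(missing)}")
        sub = metrics_table[metrics_table["metric"] == item["metric"]]
        strata = (
            [(lev, sub[sub[item["strata"]] == lev]) for lev in sorted(sub[item["strata"]].unique())]
            if "strata" in item
            else [("", sub)]
        )
        item_rows = []
        for stratum, cell in strata:
            gcol, glabels = item["group_col"], item["groups"]
            try:
                if item["test"] == "wilcoxon_signed_rank":
                    pcol = item["pair_col"]
                    wide = cell.pivot_table(
                        index=pcol, columns=gcol, values="value", aggfunc="first"
                    ).dropna(subset=list(glabels))
                    res = wilcoxon_signed_rank(
                        wide[glabels[0]], wide[glabels[1]], tuple(glabels)
                    )
                elif item["test"] == "mann_whitney_u":
                    res = mann_whitney_u(
                        cell.loc[cell[gcol] == glabels[0], "value"],
                        cell.loc[cell[gcol] == glabels[1], "value"],
                        tuple(glabels),
                    )
                elif item["test"] == "kruskal_wallis_dunn":
                    res = kruskal_wallis_dunn(
                        {g: cell.loc[cell[gcol] == g, "value"].to_numpy() for g in glabels}
                    )
                else:
                    raise ValueError(f"unknown test {item['test']!r}")
            except ValueError:
                continue
            item_rows.append(
                {
                    "metric": item["metric"], "stratum": stratum,
                    "test": res.method, "groups": "|".join(res.groups),
                    "statistic": res.statistic, "p_value": res.p_value,
                    "adjusted_p": np.nan,
                    "tier": significance_tier(res.p_value),
                }
            )
        if item.get("global_bh") and item_rows:
            adj = benjamini_hochberg([r["p_value"] for r in item_rows])
            for r, ap in zip(item_rows, adj):
                r["adjusted_p"] = float(ap)
                r["tier"] = significance_tier(float(ap))
        results.extend(item_rows)
    return pd.DataFrame(
        results,
        columns=["metric", "stratum", "test", "groups", "statistic",
                 "p_value", "adjusted_p", "tier"],
    )
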