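"""Four-group comparison workflow over ISI severity bands.

Participants are banded by ISI total (none / mild / moderate / severe)
and every derived variable is compared across the four groups with a
normality-gated policy:

* continuous, any group non-normal (Shapiro-Wilk, alpha 0.05) →
  Kruskal-Wallis omnibus plus all pairwise two-sided Wilcoxon rank-sum
  (Mann-Whitney) tests, flagged at the Bonferroni threshold
  ``family_alpha / C(k, 2)`` (0.05/6 ≈ .0083 for four groups);
  summaries reported as median (IQR);
* continuous, all groups normal → one-way ANOVA with Tukey HSD post
  hoc; summaries reported as mean (SD);
* categorical → chi-square on the contingency table; summaries as n (%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .questionnaires import classify_isi

GROUP_ORDER = ("no_insomnia", "mild", "moderate", "severe")


@dataclass(frozen=True)
class StatisticalPolicy:
    normality_alpha: float = 0.05
    family_alpha: float = 0.05
    #: smallest per-group n at which Shapiro-Wilk is attempted
    min_normality_n: int = 3
    #: "auto" = normality-gated; "kruskal_wallis" or "anova" bypass the gate
    force_test: str = "auto"


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p: float
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test_used: str  # kruskal_wallis | anova | chi_square
    omnibus_p: float
    omnibus_statistic: float
    pairwise: tuple[PairwiseResult, ...] = ()
    group_summary: Mapping[str, str] = field(default_factory=dict)
    corrected_threshold: float | None = None
    posthoc_narrative: str = ""
    notes: str = ""


def assign_groups(isi_totals: Sequence[int]) -> tuple[list[str], dict[str, int]]:
    """Band ISI totals into the four severity groups; returns labels and counts."""
    labels = [classify_isi(int(t)) for t in isi_totals]
    counts = {g: labels.count(g) for g in GROUP_ORDER}
    return labels, counts


def bonferroni_threshold(n_groups: int, family_alpha: float = 0.05) -> float:
    """Pairwise significance threshold: family alpha over C(n_groups, 2)."""
    if n_groups < 2:
        raise ValueError("need >= 2 groups for pairwise comparisons")
    return family_alpha / math.comb(n_groups, 2)


def rank_sum_pairwise(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when the combined sample is small
    (n <= 20) and tie-free, and the normal approximation with mid-rank
    tie correction and continuity correction otherwise. Returns the
    Mann-Whitney U statistic of the first sample and the p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("rank-sum test requires two nonempty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} ({np.std(x, ddof=1):.2f})" if len(x) > 1 else f"{np.mean(x):.2f} (—)"


def _narrative(pairwise: Sequence[PairwiseResult], medians: Mapping[str, float]) -> str:
    """Ordered post hoc summary, e.g. "no_insomnia<insomnia groups"."""
    sig = [p for p in pairwise if p.significant]
    if not sig:
        return "—"
    vs_first = [p for p in sig if GROUP_ORDER[0] in p.pair]
    others = [g for g in GROUP_ORDER[1:]]
    if len(vs_first) == 3 and all(
        medians[GROUP_ORDER[0]] < medians[g] for g in others
    ):
        return f"{GROUP_ORDER[0]}<insomnia groups"
    parts = []
    for p in sig:
        g1, g2 = p.pair
        lo, hi = (g1, g2) if medians.get(g1, 0) <= medians.get(g2, 0) else (g2, g1)
        parts.append(f"{lo}<{hi}")
    return "; ".join(parts)


def test_variable(
    name: str,
    values: Sequence,
    groups: Sequence[str],
    kind: str = "continuous",
    policy: StatisticalPolicy = StatisticalPolicy(),
) -> ComparisonResult:
    """Run the normality-gated omnibus + post hoc policy on one variable."""
    groups = list(groups)
    if kind == "categorical":
        return _test_categorical(name, list(values), groups)
    x = np.asarray(values, dtype=float)
    by_group = {g: x[np.array([gg == g for gg in groups])] for g in GROUP_ORDER}
    by_group = {g: v[np.isfinite(v)] for g, v in by_group.items() if np.isfinite(v).sum() > 0}
    if len(by_group) < 2:
        return ComparisonResult(name, "kruskal_wallis", float("nan"), float("nan"),
                                notes="fewer than 2 nonempty groups; omnibus skipped")
    samples = list(by_group.values())
    if policy.force_test == "anova":
        return _test_anova(name, by_group)
    if policy.force_test == "kruskal_wallis":
        return _test_kruskal(name, by_group, policy)
    if _all_groups_normal(samples, policy):
        return _test_anova(name, by_group)
    return _test_kruskal(name, by_group, policy)


def _all_groups_normal(samples: Sequence[np.ndarray], policy: StatisticalPolicy) -> bool:
    for s in samples:
        if len(s) < policy.min_normality_n:
            return False
        if np.ptp(s) == 0:  # degenerate: Shapiro undefined, treat as non-normal
            return False
        if stats.shapiro(s).pvalue < policy.normality_alpha:
            return False
    return True


def _test_kruskal(name: str, by_group: Mapping[str, np.ndarray],
                  policy: StatisticalPolicy) -> ComparisonResult:
    samples = list(by_group.values())
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:  # identical values everywhere: no evidence of difference
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*samples)
    threshold = bonferroni_threshold(len(by_group), policy.family_alpha)
    pairwise = []
    for g1, g2 in combinations(by_group, 2):
        if np.ptp(np.concatenate([by_group[g1], by_group[g2]])) == 0:
            u, pv = len(by_group[g1]) * len(by_group[g2]) / 2.0, 1.0
        else:
            u, pv = rank_sum_pairwise(by_group[g1], by_group[g2])
        pairwise.append(PairwiseResult((g1, g2), u, pv, pv < threshold))
    medians = {g: float(np.median(v)) for g, v in by_group.items()}
    return ComparisonResult(
        variable=name, test_used="kruskal_wallis", omnibus_p=float(p),
        omnibus_statistic=float(stat), pairwise=tuple(pairwise),
        group_summary={g: _median_iqr(v) for g, v in by_group.items()},
        corrected_threshold=threshold,
        posthoc_narrative=_narrative(pairwise, medians) if p < policy.family_alpha else "—",
    )


def _test_anova(name: str, by_group: Mapping[str, np.ndarray]) -> ComparisonResult:
    samples = list(by_group.values())
    stat, p = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    names = list(by_group)
    pairwise = []
    for i, j in combinations(range(len(names)), 2):
        pv = float(tukey.pvalue[i, j])
        pairwise.append(PairwiseResult((names[i], names[j]),
                                       float(tukey.statistic[i, j]), pv, pv < 0.05))
    means = {g: float(np.mean(v)) for g, v in by_group.items()}
    return ComparisonResult(
        variable=name, test_used="anova", omnibus_p=float(p), omnibus_statistic=float(stat),
        pairwise=tuple(pairwise),
        group_summary={g: _mean_sd(v) for g, v in by_group.items()},
        posthoc_narrative=_narrative(pairwise, means) if p < 0.05 else "—",
    )


def _test_categorical(name: str, values: list, groups: list[str]) -> ComparisonResult:
    levels = sorted({v for v in values if v is not None and v == v})
    present_groups = [g for g in GROUP_ORDER if g in groups]
    table = np.array([
        [sum(1 for v, gg in zip(values, groups) if gg == g and v == lev) for lev in levels]
        for g in present_groups
    ])
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    notes = ""
    if table.shape[0] < 2 or table.shape[1] < 2:
        return ComparisonResult(name, "chi_square", float("nan"), float("nan"),
                                notes="degenerate contingency table")
    chi2, p, _, expected = stats.chi2_contingency(table)
    if (expected < 5).any():
        notes = "expected cell count < 5 in some cells"
    summary = {}
    for g in present_groups:
        n_g = sum(1 for gg in groups if gg == g)
        cells = []
        for lev in levels:
            c = sum(1 for v, gg in zip(values, groups) if gg == g and v == lev)
            cells.append(f"{lev}: {c} ({100*c/n_g:.1f}%)" if n_g else f"{lev}: 0")
        summary[g] = "; ".join(cells)
    return ComparisonResult(
        variable=name, test_used="chi_square", omnibus_p=float(p),
        omnibus_statistic=float(chi2), group_summary=summary, notes=notes,
    )


def build_report(results: Sequence[ComparisonResult]) -> list[dict]:
    """Flatten comparison results to table-style rows (one per variable)."""
    rows = []
    for r in results:
        row = {
            "variable": r.variable,
            "test": r.test_used,
            "omnibus_p": r.omnibus_p,
            "omnibus_statistic": r.omnibus_statistic,
            "posthoc": r.posthoc_narrative,
        }
        for g in GROUP_ORDER:
            row[g] = r.group_summary.get(g, "")
        row["pairwise"] = [
            {"pair": list(p.pair), "statistic": p.statistic, "p": p.p,
             "significant": p.significant}
            for p in r.pairwise
        ]
        if r.notes:
            row["notes"] = r.notes
        rows.append(row)
    return rows
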