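"""Group-comparison statistics for baseline tables and phenogroup contrasts.

Two-arm baseline comparisons: continuous features get an unpaired t-test
when both arms pass a Shapiro-Wilk normality check at alpha = 0.05,
otherwise Mann-Whitney U; categorical features get Fisher's exact test
when any expected cell count is below 5, otherwise the chi-square test.
Pairwise phenogroup contrasts use the two-sample Kolmogorov-Smirnov test
for continuous features and the same chi-square/Fisher rule for
categorical ones. Raw p-values are reported; an optional Holm correction
is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_two_arms", "pairwise_phenogroup_tests", "baseline_table"]


@dataclass
class GroupComparison:
    feature: str
    groups: tuple
    test: str  # t | mann_whitney | ks | chi2 | fisher | skipped
    statistic: float
    p: float
    reason: str = ""


def _contingency(a: np.ndarray, b: np.ndarray):
    levels = sorted(set(a) | set(b))
    table = np.array(
        [[np.sum(a == lv) for lv in levels], [np.sum(b == lv) for lv in levels]],
        dtype=float,
    )
    return table, levels


def _categorical_test(feature, groups, a, b) -> GroupComparison:
    table, levels = _contingency(a, b)
    if len(levels) < 2:
        return GroupComparison(
            feature, groups, "skipped", float("nan"), float("nan"),
            reason="feature constant in both arms",
        )
    expected = sps.contingency.expected_freq(table)
    if (expected < 5).any():
        if table.shape == (2, 2):
            stat, p = sps.fisher_exact(table)
            return GroupComparison(feature, groups, "fisher", float(stat), float(p))
        # Fisher beyond 2x2 is not available; fall back to chi-square
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return GroupComparison(
            feature, groups, "chi2", float(chi2), float(p),
            reason="expected count < 5 but table larger than 2x2",
        )
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return GroupComparison(feature, groups, "chi2", float(chi2), float(p))


def compare_two_arms(feature: str, values_a, values_b, kind: str,
                     groups: tuple = ("A", "B")) -> GroupComparison:
    """Baseline-table comparison of one feature across two arms."""
    a = np.asarray(pd.Series(values_a).dropna())
    b = np.asarray(pd.Series(values_b).dropna())
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both arms must be non-empty")
    if kind == "continuous":
        normal = all(
            len(x) >= 3 and sps.shapiro(x).pvalue > 0.05 for x in (a.astype(float), b.astype(float))
        )
        if normal:
            stat, p = sps.ttest_ind(a, b, equal_var=True)
            return GroupComparison(feature, groups, "t", float(stat), float(p))
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(feature, groups, "mann_whitney", float(stat), float(p))
    if kind == "binary" or kind == "categorical":
        return _categorical_test(feature, groups, a, b)
    raise ValueError(f"unknown feature kind {kind!r}")


def pairwise_phenogroup_tests(values_by_group: dict, feature: str, kind: str,
                              holm: bool = False) -> list:
    """All unordered pairwise contrasts of one feature across phenogroups.

    ``values_by_group`` maps group label -> feature values (NaN allowed).
    Continuous features use the two-sample KS test. Raw p-values by
    default; ``holm=True`` applies a Holm step-down correction.
    """
    labels = sorted(values_by_group)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    results = []
    for ga, gb in combinations(labels, 2):
        a = np.asarray(pd.Series(values_by_group[ga]).dropna())
        b = np.asarray(pd.Series(values_by_group[gb]).dropna())
        if kind == "continuous":
            if len(a) < 2 or len(b) < 2:
                results.append(GroupComparison(
                    feature, (ga, gb), "skipped", float("nan"), float("nan"),
                    reason="fewer than 2 observations for KS",
                ))
                continue
            stat, p = sps.ks_2samp(a, b)
            results.append(GroupComparison(feature, (ga, gb), "ks", float(stat), float(p)))
        else:
            results.append(_categorical_test(feature, (ga, gb), a, b))
    if holm:
        tested = [r for r in results if r.test != "skipped"]
        order = np.argsort([r.p for r in tested])
        m = len(tested)
        running = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * tested[idx].p)
            running = max(running, adj)
            tested[idx].p = running
    return results


def baseline_table(features: pd.DataFrame, feature_kinds: dict, arms: pd.Series) -> pd.DataFrame:
    """'Table 1'-style CSV-ready frame: per-arm summary and test per feature.

    ``arms`` is a patient-aligned Series with exactly two levels.
    Continuous features summarize as mean (SD); binary ones as n (%).
    """
    levels = sorted(arms.dropna().unique())
    if len(levels) != 2:
        raise ValueError("baseline_table needs exactly two arms")
    rows = []
    for feat in features.columns:
        kind = feature_kinds.get(feat, "continuous")
        col = features[feat]
        per_arm = {}
        for lv in levels:
            vals = col[arms == lv].dropna()
            if kind == "continuous":
                per_arm[lv] = f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})"
            else:
                per_arm[lv] = f"{int(vals.sum())} ({100 * vals.mean():.0f})"
        try:
            cmp_res = compare_two_arms(
                feat, col[arms == levels[0]], col[arms == levels[1]], kind,
                groups=(levels[0], levels[1]),
            )
            test, p = cmp_res.test, cmp_res.p
        except ValueError:
            test, p = "skipped", float("nan")
        rows.append({
            "feature": feat,
            str(levels[0]): per_arm[levels[0]],
            str(levels[1]): per_arm[levels[1]],
            "test": test,
            "p": p,
        })
    return pd.DataFrame(rows)
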