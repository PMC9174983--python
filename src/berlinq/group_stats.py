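"""Descriptive and inferential comparisons between BQ risk groups.

Reproduces the style of grouped questionnaire summaries: per-item level
counts and percentages by risk group, chi-square / Fisher exact tests for
contingency tables, and rank tests (Mann–Whitney U, Kruskal–Wallis) for
ordinal items.  All operations work both from individual-level cohorts
and directly from grouped counts, so published summary tables can be
re-analysed without raw data.

Test routing (deterministic): L×2 tables get the Pearson chi-square test
without continuity correction; 2×2 tables fall back to Fisher's exact
test when any expected cell count is below 5.  Rank tests are available
alongside for ordinal scales.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .items import (
    EncodedDataset,
    EncodingPolicy,
    HIGH,
    ITEMS,
    ItemDef,
    as_records,
    classify_risk,
)
from .printed_tables import ClassConditionalTable

#: grouped counts container shared with the generator calibration tables
ContingencyTable = ClassConditionalTable


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    dof: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def significance_stars(p_value: float) -> str:
    """Conventional significance markers at 0.05 / 0.01 / 0.001."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def crosstab(cohort, item_id: str,
             items: Mapping[str, ItemDef] = ITEMS) -> ContingencyTable:
    """Level-by-risk-group counts for one item of an individual-level cohort.

    Labels are recomputed by the BQ scorer.  Missing answers are tracked
    separately from the level counts.
    """
    item = items.get(item_id)
    if item is None:
        raise KeyError(f"unknown item {item_id!r}")
    if item.continuous:
        raise ValueError(f"{item_id} is continuous; crosstab needs levels")
    records = as_records(cohort)
    if not records:
        raise ValueError("empty cohort")
    counts = {lv: [0, 0] for lv in item.levels}
    missing = [0, 0]
    for rec in records:
        k = int(classify_risk(rec) == HIGH)
        ans = rec.answer(item_id)
        if ans is None:
            missing[k] += 1
        else:
            counts[ans][k] += 1
    return ContingencyTable(
        item_id=item_id,
        levels=item.levels,
        counts_low=tuple(counts[lv][0] for lv in item.levels),
        counts_high=tuple(counts[lv][1] for lv in item.levels),
        missing_low=missing[0],
        missing_high=missing[1],
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def group_percentages(table: ContingencyTable) -> pd.DataFrame:
    """Per-class percentages of each level (missing shown as its own row).

    Percentages use the full class totals (answered + missing) as the
    base, matching how grouped survey tables are usually printed; raw and
    half-up integer-rounded values are both returned.
    """
    n_low, n_high = table.totals()
    if n_low == 0 or n_high == 0:
        raise ValueError(f"{table.item_id}: empty class")
    rows = []
    for lv, cl, ch in zip(table.levels + ("missing",),
                          table.counts_low + (table.missing_low,),
                          table.counts_high + (table.missing_high,)):
        pl, ph = 100.0 * cl / n_low, 100.0 * ch / n_high
        rows.append({"level": lv, "low_n": cl, "low_pct_raw": pl,
                     "low_pct": _round_half_up(pl), "high_n": ch,
                     "high_pct_raw": ph, "high_pct": _round_half_up(ph)})
    return pd.DataFrame(rows)


def _level_matrix(table: ContingencyTable) -> np.ndarray:
    """levels × {low, high} matrix with all-zero rows dropped."""
    mat = np.array([table.counts_low, table.counts_high], dtype=float).T
    return mat[mat.sum(axis=1) > 0]


def chi_square_test(table: ContingencyTable) -> TestResult:
    """Pearson chi-square without continuity correction on the level counts."""
    mat = _level_matrix(table)
    if mat.shape[0] < 2 or np.any(mat.sum(axis=0) == 0):
        raise ValueError(f"{table.item_id}: degenerate table for chi-square")
    stat, p, dof, _ = stats.chi2_contingency(mat, correction=False)
    return TestResult("chi_square", float(stat), float(p), int(dof))


def fisher_exact_2x2(table: ContingencyTable | np.ndarray) -> TestResult:
    """Two-sided Fisher exact test; requires a 2×2 table."""
    if isinstance(table, ContingencyTable):
        mat = _level_matrix(table)
    else:
        mat = np.asarray(table, dtype=float)
    if mat.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    odds, p = stats.fisher_exact(mat, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p))


def expected_counts(table: ContingencyTable) -> np.ndarray:
    mat = _level_matrix(table)
    return stats.contingency.expected_freq(mat)


def choose_test(table: ContingencyTable) -> TestResult:
    """Deterministic routing: chi-square, or Fisher exact for sparse 2×2."""
    mat = _level_matrix(table)
    if mat.shape == (2, 2) and expected_counts(table).min() < 5:
        return fisher_exact_2x2(table)
    return chi_square_test(table)


def _expand(table: ContingencyTable, policy: EncodingPolicy) -> tuple[np.ndarray, np.ndarray]:
    """Grouped counts to per-class numeric value arrays (missing dropped)."""
    codes = _codes_for_levels(table.levels, policy)
    vals = {"low": [], "high": []}
    for lv, cl, ch in zip(table.levels, table.counts_low, table.counts_high):
        c = codes[lv]
        if math.isnan(c):
            continue
        vals["low"].extend([c] * cl)
        vals["high"].extend([c] * ch)
    return np.array(vals["low"]), np.array(vals["high"])


def _codes_for_levels(levels: Sequence[str], policy: EncodingPolicy) -> dict[str, float]:
    stub = ItemDef("tmp", "", tuple(levels))
    return policy.codes(stub)


def rank_test(data, item_id: str | None = None,
              policy: EncodingPolicy | None = None,
              groups: Sequence[np.ndarray] | None = None) -> TestResult:
    """Mann–Whitney U (tie-corrected, two-sided) between risk groups.

    ``data`` may be an :class:`EncodedDataset`, a grouped
    :class:`ContingencyTable`, or ``None`` with explicit ``groups``.  The
    U statistic is oriented as the count of (high > low) pairs plus half
    the ties.  With more than two explicit groups a Kruskal–Wallis test
    is run instead.
    """
    policy = policy or EncodingPolicy()
    if groups is not None:
        samples = [np.asarray(g, dtype=float) for g in groups]
    elif isinstance(data, EncodedDataset):
        col = data.column(item_id)
        ok = ~np.isnan(col)
        samples = [col[ok & (data.y == 0)], col[ok & (data.y == 1)]]
    elif isinstance(data, ContingencyTable):
        samples = list(_expand(data, policy))
    else:
        raise TypeError("rank_test needs an EncodedDataset, a ContingencyTable "
                        "or explicit groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("a group is empty after missing removal")
    if len(samples) > 2:
        stat, p = stats.kruskal(*samples)
        return TestResult("kruskal_wallis", float(stat), float(p), len(samples) - 1)
    low, high = samples
    res = stats.mannwhitneyu(high, low, alternative="two-sided")
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue))


def build_summary_table(source, items: Sequence[str],
                        policy: EncodingPolicy | None = None) -> pd.DataFrame:
    """Formatted per-item summary: counts, percentages, test, p, stars.

    ``source`` is either an individual-level cohort or a mapping /
    sequence of grouped :class:`ContingencyTable` objects.
    """
    rows = []
    for item_id in items:
        if isinstance(source, (list, tuple)):
            table = next(t for t in source if t.item_id == item_id)
        elif isinstance(source, Mapping):
            table = source[item_id]
        else:
            table = crosstab(source, item_id)
        result = choose_test(table)
        pct = group_percentages(table)
        for _, r in pct.iterrows():
            rows.append({
                "item_id": item_id,
                "level": r["level"],
                "low_n": int(r["low_n"]),
                "low_pct": int(r["low_pct"]),
                "high_n": int(r["high_n"]),
                "high_pct": int(r["high_pct"]),
                "test": result.test_name,
                "p_value": result.p_value,
                "stars": significance_stars(result.p_value),
            })
    return pd.DataFrame(rows)
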