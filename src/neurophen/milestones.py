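"""Developmental-milestone maturity scoring and group summaries.

Neonatal mice are scored daily (P1-P21) on a battery of somatic and reflex
tests; each test has a maturity criterion (a target score, binary or graded
0-3) and, for some tests, a requirement of 3 consecutive qualifying days.
The registered *maturity day* is the final day of the first qualifying run.
Group comparisons use the median maturity day per test and the Mann-Whitney
U statistic (the rank-sum statistic itself; p-values are left to standard
statistical software).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MaturityRule, MilestoneTable, WEANING_DAY


def mature_day(
    scores: dict[int, int] | pd.Series,
    rule: MaturityRule,
    run_convention: str = "final",
) -> int | None:
    """Maturity day for one animal on one test, or None if never reached.

    ``scores`` maps postnatal day -> score over a contiguous observation
    window; a gap inside the window is an error (scores cannot be assumed).
    A day qualifies when its score >= the rule's criterion; maturity is
    registered on the final day of the first run of
    ``consecutive_days_required`` qualifying days (``run_convention="first"``
    registers the run's first day instead).
    """
    if run_convention not in ("final", "first"):
        raise ValueError("run_convention must be 'final' or 'first'")
    if isinstance(scores, pd.Series):
        scores = {int(d): int(s) for d, s in scores.items()}
    if not scores:
        raise ValueError("no scores given")
    days = sorted(scores)
    gaps = [d for a, b in zip(days, days[1:]) for d in range(a + 1, b)]
    if gaps:
        raise ValueError(f"missing day {gaps[0]} inside the observation window")

    need = rule.consecutive_days_required
    run = 0
    for d in days:
        if scores[d] >= rule.criterion:
            run += 1
            if run >= need:
                return d if run_convention == "final" else d - need + 1
        else:
            run = 0
    return None


def group_summary(
    table: MilestoneTable,
    run_convention: str = "final",
) -> pd.DataFrame:
    """Per test x group: median maturity day, n reaching, n not reaching.

    Animals that never reach maturity by P21 are excluded from the median
    and reported in ``n_not_reached``.  Medians use the even-n convention
    (mean of the middle pair).  Raises on an empty group.
    """
    rows = []
    df = table.records
    for (test, group), sub in df.groupby(["test_name", "group"], sort=True):
        rule = table.rule_set[str(test)]
        days = []
        n_not = 0
        for animal, a_sub in sub.groupby("animal_id"):
            scores = dict(
                zip(a_sub["postnatal_day"].astype(int), a_sub["score"].astype(int))
            )
            d = mature_day(scores, rule, run_convention)
            if d is None:
                n_not += 1
            else:
                days.append(d)
        if not days and n_not == 0:
            raise ValueError(f"empty group {group!r} for test {test!r}")
        rows.append(
            {
                "test_name": test,
                "group": group,
                "median_day": float(np.median(days)) if days else np.nan,
                "n": len(days),
                "n_not_reached": n_not,
            }
        )
    return pd.DataFrame(rows)


def rank_sum_u(
    group_a,
    group_b,
    convention: str = "min",
) -> float:
    """Mann-Whitney U statistic by direct pair counting.

    U_a counts pairs (a, b) with a < b plus half the tied pairs.  With
    ``convention="min"`` (default) the conventionally reported
    min(U_a, n_a*n_b - U_a) is returned; ``convention="raw"`` returns U_a,
    so that U_a(x, y) + U_a(y, x) = n_x * n_y exactly.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = a[:, None] - b[None, :]
    u = float(np.sum(diff < 0) + 0.5 * np.sum(diff == 0))
    if convention == "raw":
        return u
    if convention == "min":
        return min(u, a.size * b.size - u)
    raise ValueError("convention must be 'min' or 'raw'")


def compare_groups(
    table: MilestoneTable,
    group_a: str,
    group_b: str,
    run_convention: str = "final",
) -> pd.DataFrame:
    """Per-test group comparison: medians of each group and the U statistic.

    Animals not reaching maturity are excluded from both the medians and the
    rank statistic (they carry no maturity day to rank).
    """
    rows = []
    df = table.records
    for test, sub in df.groupby("test_name", sort=True):
        rule = table.rule_set[str(test)]
        days = {group_a: [], group_b: []}
        for (animal, group), a_sub in sub.groupby(["animal_id", "group"]):
            if group not in days:
                continue
            scores = dict(
                zip(a_sub["postnatal_day"].astype(int), a_sub["score"].astype(int))
            )
            d = mature_day(scores, rule, run_convention)
            if d is not None:
                days[str(group)].append(d)
        if not days[group_a] or not days[group_b]:
            continue
        rows.append(
            {
                "test_name": test,
                f"median_{group_a}": float(np.median(days[group_a])),
                f"median_{group_b}": float(np.median(days[group_b])),
                "n_a": len(days[group_a]),
                "n_b": len(days[group_b]),
                "U": rank_sum_u(days[group_a], days[group_b]),
            }
        )
    return pd.DataFrame(rows)
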