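"""Group-comparison statistics and condition-level reporting.

Two groups are compared with Student's t test (Welch by default), three
or more with one-way ANOVA; p-values map to the conventional asterisks
(* p < 0.05, ** p < 0.01, *** p < 0.001, else ns). No multiple-testing
correction is applied by default; a Benjamini–Hochberg option exists.
Each row of the group table is treated as one independent unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import validate_group_table

__all__ = ["ComparisonResult", "p_to_stars", "compare_groups", "condition_report"]


@dataclass
class ComparisonResult:
    metric_name: str
    groups: tuple[str, ...]
    test_name: str  # "t_test" or "one_way_anova"
    statistic: float
    p_value: float
    stars: str


def p_to_stars(p: float) -> str:
    """Asterisk convention: * p<0.05, ** p<0.01, *** p<0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    table: pd.DataFrame,
    metric_name: str,
    equal_var: bool = False,
) -> ComparisonResult:
    """Compare conditions on one metric.

    Two groups -> Student's t test (Welch unless ``equal_var``); three or
    more -> one-way ANOVA. Every group needs >= 2 values.
    """
    validate_group_table(table)
    sub = table[table["metric_name"] == metric_name]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric_name!r}")
    groups = sorted(sub["condition"].unique())
    samples = [sub.loc[sub["condition"] == g, "value"].to_numpy(dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has < 2 values")
    if len(samples) == 2:
        stat, p = sps.ttest_ind(samples[0], samples[1], equal_var=equal_var)
        test = "t_test"
    else:
        stat, p = sps.f_oneway(*samples)
        test = "one_way_anova"
    if np.isnan(p):  # identical constant groups
        stat, p = 0.0, 1.0
    return ComparisonResult(
        metric_name=metric_name,
        groups=tuple(groups),
        test_name=test,
        statistic=float(stat),
        p_value=float(p),
        stars=p_to_stars(float(p)),
    )


def condition_report(
    table: pd.DataFrame,
    equal_var: bool = False,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(metric, condition) summary plus group comparisons.

    Returns ``(summary, comparisons)``: the summary has one row per
    metric/condition with mean, SD and n; comparisons has one row per
    metric with >= 2 eligible groups. Output row order is deterministic
    and independent of input row order.
    """
    validate_group_table(table)
    summary_rows = []
    for (metric, cond), grp in sorted(
        table.groupby(["metric_name", "condition"], sort=True), key=lambda kv: kv[0]
    ):
        vals = grp["value"].to_numpy(dtype=float)
        summary_rows.append(
            {
                "metric_name": metric,
                "condition": cond,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    summary = pd.DataFrame(summary_rows)

    comp_rows = []
    for metric in sorted(table["metric_name"].unique()):
        sub = table[table["metric_name"] == metric]
        counts = sub.groupby("condition").size()
        if (counts >= 2).sum() >= 2:
            eligible = counts[counts >= 2].index
            res = compare_groups(sub[sub["condition"].isin(eligible)], metric, equal_var=equal_var)
            comp_rows.append(
                {
                    "metric_name": res.metric_name,
                    "groups": "|".join(res.groups),
                    "test_name": res.test_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "stars": res.stars,
                }
            )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["metric_name", "groups", "test_name", "statistic", "p_value", "stars"],
    )
    if bh_correct and len(comparisons):
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(comparisons["p_value"], method="fdr_bh")
        comparisons["p_value_bh"] = p_adj
        comparisons["stars_bh"] = [p_to_stars(p) for p in p_adj]
    return summary, comparisons
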