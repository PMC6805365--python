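"""Rendering of the cohort-statistics tables as data frames and plain text.

The four tables follow the reporting conventions of clinical screening
studies: continuous variables as "mean (SD)", categorical ones as count
and percent, p-values to three decimals with small values shown as
"< 0.001".  Each builder in :mod:`lbptriage.stats` returns structured
results; this module turns them into CSV-ready frames and aligned text.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .stats import (
    ContingencyTable,
    GroupSummary,
    TestResult,
    build_agreement_table,
    build_table1,
    build_table2,
    build_table4,
    round_half_up,
)
from .triage import combined_high_count

__all__ = [
    "summary_frame",
    "contingency_frame",
    "agreement_frame",
    "render_frame",
    "build_report",
]

#: variables printed with two decimals instead of one
_TWO_DP = ("EQ5D",)


def _decimals(variable: str, default: int = 1) -> int:
    return 2 if any(variable.startswith(p) for p in _TWO_DP) else default


def _cell(summary: GroupSummary, i: int, decimals: int) -> str:
    if summary.kind == "continuous":
        d = _decimals(summary.variable, decimals)
        return f"{summary.mean[i]:.{d}f} ({summary.sd[i]:.{d}f})"
    return f"{summary.count[i]} ({summary.percent[i]:.0f}%)"


def summary_frame(
    rows: Sequence[tuple[GroupSummary, TestResult]],
    group_names: tuple[str, str],
    decimals: int = 1,
) -> pd.DataFrame:
    """One row per variable: per-group n, formatted summary, and p-value."""
    g1, g2 = group_names
    out = []
    for summary, test in rows:
        out.append(
            {
                "variable": summary.variable,
                f"{g1}_n": summary.n[0],
                g1: _cell(summary, 0, decimals),
                f"{g2}_n": summary.n[1],
                g2: _cell(summary, 1, decimals),
                "statistic": round(test.statistic, 3),
                "df": test.df,
                "p_value": round(test.p_value, 6),
                "p": test.p_text,
            }
        )
    return pd.DataFrame(out)


def contingency_frame(table: ContingencyTable, percent_axis: int = 1) -> pd.DataFrame:
    """Counts with row-wise (axis=1) or column-wise (axis=0) percentages."""
    arr = table.array
    margins = arr.sum(axis=percent_axis, keepdims=True)
    out = table.to_frame().astype(object)
    for i, row_label in enumerate(table.row_labels):
        for j, col_label in enumerate(table.col_labels):
            denom = margins[i, 0] if percent_axis == 1 else margins[0, j]
            pct = round_half_up(100.0 * arr[i, j] / denom) if denom else 0.0
            out.loc[row_label, col_label] = f"{arr[i, j]} ({pct:.0f}%)"
    return out


def agreement_frame(table: ContingencyTable) -> pd.DataFrame:
    """Raw counts with margins for the instrument-agreement crosstab."""
    df = table.to_frame()
    df["total"] = df.sum(axis=1)
    df.loc["total"] = df.sum(axis=0)
    return df


def render_frame(df: pd.DataFrame, title: str, *, index: bool = False) -> str:
    body = df.to_string(index=index)
    rule = "-" * max(len(line) for line in body.splitlines())
    return f"{title}\n{rule}\n{body}\n"


def build_report(cohort, *, combine_variant: str = "or", decimals: int = 1) -> dict:
    """Assemble all four tables plus the combined-triage headline counts.

    Returns a dict with frames (``table1`` ... ``table4``), the raw
    agreement :class:`ContingencyTable`, and the combined high-risk count
    with both candidate denominators (agreement-complete n and LBP-group n),
    since screening studies report the percentage against either.
    """
    t1 = summary_frame(build_table1(cohort), ("lbp", "reference"), decimals)
    t2 = build_table2(cohort)
    agreement = build_agreement_table(cohort)
    crosstab = {
        (risk, bool(ms == "ms_cwp")): int(agreement.array[i, j])
        for i, ms in enumerate(agreement.row_labels)
        for j, risk in enumerate(agreement.col_labels)
    }
    high_n = combined_high_count(crosstab)
    t4 = summary_frame(
        build_table4(cohort, combine_variant=combine_variant),
        ("lower", "high"),
        decimals,
    )
    n_agree = agreement.total
    lbp_n = int(
        sum(n for n in (t1.loc[t1["variable"].str.startswith("Age"), "lbp_n"]))
    )
    return {
        "table1": t1,
        "table2_sbt": _screening_frame(*t2["sbt"]),
        "table2_ms_cwp": _screening_frame(*t2["ms_cwp"]),
        "table3": agreement_frame(agreement),
        "agreement": agreement,
        "table4": t4,
        "combined_high_count": high_n,
        "combined_high_pct_of_agreement_n": (
            round_half_up(100.0 * high_n / n_agree) if n_agree else None
        ),
        "combined_high_pct_of_group_n": (
            round_half_up(100.0 * high_n / lbp_n) if lbp_n else None
        ),
    }


def _screening_frame(table: ContingencyTable, test: TestResult) -> pd.DataFrame:
    # groups are rows in the ContingencyTable; print outcomes as rows
    flipped = ContingencyTable(
        table.col_labels, table.row_labels, tuple(map(tuple, table.array.T))
    )
    df = contingency_frame(flipped, percent_axis=0)
    df.loc["p"] = [test.p_text] + [""] * (len(df.columns) - 1)
    return df
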