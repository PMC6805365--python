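"""Descriptive and inferential cohort statistics.

Group comparisons use the two classical tests the design calls for:
Student's pooled-variance two-sample t-test for continuous outcomes and
Pearson's chi-square (no continuity correction) for categorical ones.  The
t-test operates on summary statistics (mean, SD, n per group), so it is
usable both on raw cohorts after complete-case reduction and on published
table rows.

Four report builders mirror the analysis of a two-group screening study:

* ``build_table1`` — self-reported health by group (means/SDs, percents,
  per-variable complete-case n, p-values);
* ``build_table2`` — screening outcome distributions by group (SBT risk
  3x2, MS-CWP 2x2) with chi-square tests;
* ``build_agreement_table`` — SBT risk x MS-CWP crosstab within the LBP
  group, both instruments complete;
* ``build_table4`` — self-reported health by combined-triage level within
  the LBP group.

P-values are rendered to three decimals, with values below 0.0005 shown as
"< 0.001"; percentages are rounded half-up to integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, PRO_FIELDS, assign_groups
from .mannequin import PainStatus, classify_mannequin
from .sbt import RiskLevel, sbt_result
from .triage import combine

__all__ = [
    "TestResult",
    "ContingencyTable",
    "GroupSummary",
    "pooled_t_test",
    "pearson_chi_square",
    "format_p",
    "round_half_up",
    "scored_frame",
    "build_table1",
    "build_table2",
    "build_agreement_table",
    "build_table4",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str  # "pooled_t" | "pearson_chi2"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")

    @property
    def p_text(self) -> str:
        return format_p(self.p_value)


def format_p(p: float, decimals: int = 3) -> str:
    """Render a p-value the way clinical tables print it."""
    floor = 10.0 ** (-decimals)
    if p < floor / 2:
        return f"< {floor:.{decimals}f}"
    return f"{p:.{decimals}f}"


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Student's two-sample t-test with pooled variance, two-sided.

    Pooled variance s2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2),
    df = n1+n2-2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0 and mean1 != mean2:
        raise ValueError("degenerate test: both SDs zero with unequal means")
    if sd1 == 0 and sd2 == 0:
        return TestResult(0.0, n1 + n2 - 2, 1.0, "pooled_t")
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return TestResult(float(t), float(n1 + n2 - 2), float(p), "pooled_t")


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]  # rows x cols

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def total(self) -> int:
        return int(self.array.sum())

    @property
    def row_margins(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self.array.sum(axis=1))

    @property
    def col_margins(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self.array.sum(axis=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.array, index=list(self.row_labels), columns=list(self.col_labels)
        )


def pearson_chi_square(table: ContingencyTable | Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction.

    Warns (does not fail) when any expected cell count is below 5.
    """
    arr = table.array if isinstance(table, ContingencyTable) else np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin: every row and column needs observations")
    chi2, p, df, expected = sps.chi2_contingency(arr, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} expected cell(s) below 5; "
            "chi-square approximation may be poor",
            UserWarning,
            stacklevel=2,
        )
    return TestResult(float(chi2), float(df), float(p), "pearson_chi2")


@dataclass(frozen=True)
class GroupSummary:
    """One table row: a variable summarized per group.

    ``kind`` is "continuous" (n, mean, SD per group) or "categorical"
    (n, count, percent per group).
    """

    variable: str
    kind: str
    groups: tuple[str, ...]
    n: tuple[int, ...]
    mean: Optional[tuple[float, ...]] = None
    sd: Optional[tuple[float, ...]] = None
    count: Optional[tuple[int, ...]] = None
    percent: Optional[tuple[float, ...]] = None


# --- per-record derived screening columns -------------------------------

_DERIVED_COLS = [
    "sbt_overall",
    "sbt_psych",
    "sbt_risk",
    "pain_status",
    "region_count",
    "ms_cwp",
    "combined_risk",
]


def scored_frame(cohort: Cohort, *, combine_variant: str = "or") -> pd.DataFrame:
    """Flatten a cohort into an analysis frame with derived screening columns.

    One row per record: group label, demographics, PRO totals, SBT scores
    and risk, mannequin classification and the combined triage level.
    Missing instruments yield NA in their derived columns.
    """
    part = assign_groups(cohort)
    group_of = {rid: "lbp" for rid in part.lbp}
    group_of.update({rid: "reference" for rid in part.reference})

    rows = []
    for r in cohort:
        row: dict = {
            "id": r.id,
            "group": group_of.get(r.id, pd.NA),
            "age": r.age,
            "sex": r.sex,
        }
        for name in PRO_FIELDS:
            row[name] = getattr(r, name)

        sbt = sbt_result(r)
        row["sbt_overall"] = sbt.overall if sbt else pd.NA
        row["sbt_psych"] = sbt.psychosocial if sbt else pd.NA
        row["sbt_risk"] = sbt.risk.value if sbt else pd.NA

        mann = (
            classify_mannequin(r.chronic_pain, r.regions or frozenset(), cohort.region_map)
            if r.mannequin_complete
            else None
        )
        row["pain_status"] = mann.status.value if mann else pd.NA
        row["region_count"] = mann.region_count if mann else pd.NA
        row["ms_cwp"] = mann.ms_cwp if mann else pd.NA

        combined = combine(
            sbt.risk if sbt else None,
            mann.ms_cwp if mann else None,
            variant=combine_variant,
        )
        row["combined_risk"] = combined.level if combined else pd.NA
        rows.append(row)

    df = pd.DataFrame(rows)
    df["group"] = df["group"].astype("object")
    return df


def _cont_row(
    df: pd.DataFrame, variable: str, column: str, groups: tuple[str, str]
) -> tuple[GroupSummary, TestResult]:
    stats_per_group = []
    for g in groups:
        vals = pd.to_numeric(
            df.loc[df["group"] == g, column], errors="coerce"
        ).dropna()
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values for {variable}")
        stats_per_group.append((len(vals), float(vals.mean()), float(vals.std(ddof=1))))
    (n1, m1, s1), (n2, m2, s2) = stats_per_group
    summary = GroupSummary(
        variable=variable,
        kind="continuous",
        groups=groups,
        n=(n1, n2),
        mean=(m1, m2),
        sd=(s1, s2),
    )
    return summary, pooled_t_test(m1, s1, n1, m2, s2, n2)


def _cat_row(
    df: pd.DataFrame,
    variable: str,
    indicator: pd.Series,
    groups: tuple[str, str],
) -> tuple[GroupSummary, TestResult]:
    ns, counts, pcts = [], [], []
    cells = []
    for g in groups:
        flags = indicator[df["group"] == g].dropna().astype(bool)
        n, k = len(flags), int(flags.sum())
        if n == 0:
            raise ValueError(f"group {g!r} has no values for {variable}")
        ns.append(n)
        counts.append(k)
        pcts.append(round_half_up(100.0 * k / n))
        cells.append([k, n - k])
    summary = GroupSummary(
        variable=variable,
        kind="categorical",
        groups=groups,
        n=tuple(ns),
        count=tuple(counts),
        percent=tuple(pcts),
    )
    table = ContingencyTable(
        groups, ("yes", "no"), tuple(tuple(c) for c in cells)
    )
    return summary, pearson_chi_square(table)


#: group-comparison table rows: (label, analysis column, kind)
TABLE1_VARIABLES = [
    ("Age (years)", "age", "continuous"),
    ("Sex (women)", "sex", "categorical"),
    ("SBT (0-9)", "sbt_overall", "continuous"),
    ("RMDQ (0-24)", "rmdq", "continuous"),
    ("EQ5D (0-1)", "eq5d_index", "continuous"),
    ("FABQ PA (0-24)", "fabq_pa", "continuous"),
    ("FABQ work (0-42)", "fabq_work", "continuous"),
    ("HAD anxiety (0-21)", "had_anxiety", "continuous"),
    ("HAD depression (0-21)", "had_depression", "continuous"),
    ("Pain NRS (0-10)", "nrs_pain", "continuous"),
    ("Regions with pain (0-18)", "region_count", "continuous"),
    ("CWP", "pain_status", "categorical"),
]

_GROUPS = ("lbp", "reference")


def build_table1(
    cohort: Cohort, variables=TABLE1_VARIABLES
) -> list[tuple[GroupSummary, TestResult]]:
    """Self-reported health by group, per-variable complete case."""
    df = scored_frame(cohort)
    for g in _GROUPS:
        if not (df["group"] == g).any():
            raise ValueError(f"group {g!r} is empty")
    out = []
    for label, column, kind in variables:
        if kind == "continuous":
            out.append(_cont_row(df, label, column, _GROUPS))
        elif column == "sex":
            out.append(_cat_row(df, label, df["sex"] == "female", _GROUPS))
        elif column == "pain_status":
            ind = df["pain_status"].map(
                lambda s: pd.NA if s is pd.NA else s == PainStatus.CWP.value
            )
            out.append(_cat_row(df, label, ind, _GROUPS))
        else:
            raise ValueError(f"unknown categorical variable {column!r}")
    return out


def build_table2(cohort: Cohort) -> dict[str, tuple[ContingencyTable, TestResult]]:
    """Screening-outcome distributions by group with chi-square tests.

    Returns the SBT risk-level distribution (3 levels x 2 groups) and the
    MS-CWP split (2 x 2), each complete-case for its own instrument.
    """
    df = scored_frame(cohort)
    out: dict[str, tuple[ContingencyTable, TestResult]] = {}

    risk_levels = tuple(level.value for level in RiskLevel)
    sbt_counts = []
    for g in _GROUPS:
        sub = df[(df["group"] == g) & df["sbt_risk"].notna()]
        sbt_counts.append(
            tuple(int((sub["sbt_risk"] == lev).sum()) for lev in risk_levels)
        )
    sbt_table = ContingencyTable(_GROUPS, risk_levels, tuple(sbt_counts))
    out["sbt"] = (sbt_table, pearson_chi_square(sbt_table))

    ms_counts = []
    for g in _GROUPS:
        sub = df[(df["group"] == g) & df["ms_cwp"].notna()]
        flags = sub["ms_cwp"].astype(bool)
        ms_counts.append((int(flags.sum()), int((~flags).sum())))
    ms_table = ContingencyTable(_GROUPS, ("ms_cwp", "no_ms_cwp"), tuple(ms_counts))
    out["ms_cwp"] = (ms_table, pearson_chi_square(ms_table))
    return out


def build_agreement_table(cohort: Cohort, group: str = "lbp") -> ContingencyTable:
    """SBT risk x MS-CWP crosstab on records with both instruments complete.

    Restricted to one group (the LBP group by default).  Rows are the
    mannequin outcome, columns the SBT risk level, matching the layout in
    which the instruments' disagreement is read off the off-diagonal cells.
    """
    df = scored_frame(cohort)
    sub = df[(df["group"] == group) & df["sbt_risk"].notna() & df["ms_cwp"].notna()]
    risk_levels = tuple(level.value for level in RiskLevel)
    rows = []
    for ms_flag in (False, True):
        rows.append(
            tuple(
                int(
                    (
                        (sub["sbt_risk"] == lev) & (sub["ms_cwp"].astype(bool) == ms_flag)
                    ).sum()
                )
                for lev in risk_levels
            )
        )
    return ContingencyTable(("no_ms_cwp", "ms_cwp"), risk_levels, tuple(rows))


#: combined-risk table rows (PRO comparisons by triage level)
TABLE4_VARIABLES = [
    ("RMDQ (0-24)", "rmdq"),
    ("EQ5D (0-1)", "eq5d_index"),
    ("FABQ PA (0-24)", "fabq_pa"),
    ("FABQ work (0-42)", "fabq_work"),
    ("HAD anxiety (0-21)", "had_anxiety"),
    ("HAD depression (0-21)", "had_depression"),
    ("Pain NRS (0-10)", "nrs_pain"),
]


def build_table4(
    cohort: Cohort, *, group: str = "lbp", combine_variant: str = "or"
) -> list[tuple[GroupSummary, TestResult]]:
    """PROs by combined-triage level (lower vs high) within one group."""
    df = scored_frame(cohort, combine_variant=combine_variant)
    sub = df[(df["group"] == group) & df["combined_risk"].notna()].copy()
    sub["group"] = sub["combined_risk"]
    out = []
    for label, column in TABLE4_VARIABLES:
        out.append(_cont_row(sub, label, column, ("lower", "high")))
    return out
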