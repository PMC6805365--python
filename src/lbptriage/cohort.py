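"""Cohort data model: respondent records, CSV I/O and group assignment.

One row per respondent: the group-defining question (low back pain during
the last week, yes/no), the 9 STarT Back items, the mannequin response
(chronicity question + 18 region marks), patient-reported outcomes (PROs)
and demographics.  Missingness is per instrument and per PRO: a blank cell
makes that PRO missing; a blank anywhere in the SBT block voids the whole
SBT; a blank chronicity answer or region cell voids the whole mannequin.
Every analysis downstream is complete-case within its own instrument, which
is what produces shifting denominators across tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .mannequin import BodyRegionMap, default_region_map

__all__ = [
    "PRO_RANGES",
    "IndividualRecord",
    "Cohort",
    "GroupPartition",
    "SchemaError",
    "ValidationError",
    "assign_groups",
    "read_cohort",
    "write_cohort",
    "cohort_columns",
]

#: Closed ranges of the patient-reported outcomes, as administered.
PRO_RANGES: dict[str, tuple[float, float]] = {
    "nrs_pain": (0, 10),
    "rmdq": (0, 24),
    "eq5d_index": (0.0, 1.0),
    "had_anxiety": (0, 21),
    "had_depression": (0, 21),
    "fabq_pa": (0, 24),
    "fabq_work": (0, 42),
}

PRO_FIELDS = tuple(PRO_RANGES)


class SchemaError(ValueError):
    """The file does not conform to the cohort CSV schema."""


class ValidationError(ValueError):
    """A cell value violates its declared range or coding."""


@dataclass(frozen=True)
class IndividualRecord:
    """One respondent.  ``None`` marks a missing answer/instrument."""

    id: str
    age: Optional[float] = None
    sex: Optional[str] = None  # "female" | "male"
    lbp_last_week: Optional[bool] = None
    sbt_items: Optional[tuple[int, ...]] = None  # 9 binary endorsements
    chronic_pain: Optional[bool] = None
    regions: Optional[frozenset[str]] = None
    nrs_pain: Optional[float] = None
    rmdq: Optional[float] = None
    eq5d_index: Optional[float] = None
    had_anxiety: Optional[float] = None
    had_depression: Optional[float] = None
    fabq_pa: Optional[float] = None
    fabq_work: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("female", "male"):
            raise ValidationError(f"record {self.id}: sex must be female/male")
        if self.sbt_items is not None:
            items = tuple(int(v) for v in self.sbt_items)
            if len(items) != 9 or any(v not in (0, 1) for v in items):
                raise ValidationError(
                    f"record {self.id}: sbt_items must be 9 binary values"
                )
            object.__setattr__(self, "sbt_items", items)
        for name in PRO_FIELDS:
            value = getattr(self, name)
            if value is None:
                continue
            lo, hi = PRO_RANGES[name]
            if not (lo <= value <= hi):
                raise ValidationError(
                    f"record {self.id}: {name}={value!r} outside range {lo}-{hi}"
                )

    @property
    def mannequin_complete(self) -> bool:
        return self.chronic_pain is not None and self.regions is not None

    @property
    def sbt_complete(self) -> bool:
        return self.sbt_items is not None


@dataclass(frozen=True)
class GroupPartition:
    """Exhaustive, disjoint split of record ids by the last-week LBP answer."""

    lbp: tuple[str, ...]
    reference: tuple[str, ...]
    unassigned: tuple[str, ...]


@dataclass(frozen=True)
class Cohort:
    records: tuple[IndividualRecord, ...]
    region_map: BodyRegionMap = field(default_factory=default_region_map)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dupes}")
        for r in self.records:
            if r.regions is not None:
                self.region_map.validate_subset(r.regions)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IndividualRecord]:
        return iter(self.records)

    def subset(self, ids: Iterable[str]) -> "Cohort":
        wanted = set(ids)
        return Cohort(
            tuple(r for r in self.records if r.id in wanted), self.region_map
        )


def assign_groups(cohort: Cohort) -> GroupPartition:
    """Partition the cohort by the last-week LBP question alone.

    yes → LBP group, no → reference group, missing → unassigned (excluded
    from every downstream group comparison).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    lbp, ref, un = [], [], []
    for r in cohort:
        if r.lbp_last_week is True:
            lbp.append(r.id)
        elif r.lbp_last_week is False:
            ref.append(r.id)
        else:
            un.append(r.id)
    return GroupPartition(tuple(lbp), tuple(ref), tuple(un))


# --- CSV schema ---------------------------------------------------------

_SBT_COLS = tuple(f"sbt{i}" for i in range(1, 10))


def cohort_columns(region_map: BodyRegionMap) -> list[str]:
    """Header of the cohort CSV for a given region map."""
    return (
        ["id", "age", "sex", "lbp_last_week"]
        + list(_SBT_COLS)
        + ["chronic_pain"]
        + [f"reg_{rid}" for rid in region_map.ids]
        + list(PRO_FIELDS)
    )


def _parse_binary(cell: str, column: str, row_id: str) -> int:
    if cell not in ("0", "1"):
        raise ValidationError(
            f"record {row_id}: column {column} must be 0/1, got {cell!r}"
        )
    return int(cell)


def _parse_sbt9(cell: str, row_id: str, raw: bool) -> int:
    if not raw:
        return _parse_binary(cell, "sbt9", row_id)
    # raw dialect: bothersomeness level 1-5, endorsed at "very much"/"extremely"
    if cell not in ("1", "2", "3", "4", "5"):
        raise ValidationError(
            f"record {row_id}: sbt9 raw level must be 1-5, got {cell!r}"
        )
    return int(int(cell) >= 4)


def read_cohort(
    path: str | Path,
    region_map: Optional[BodyRegionMap] = None,
    *,
    sbt9_raw: bool = False,
) -> Cohort:
    """Read a cohort CSV (UTF-8, comma separated, blanks = missing).

    ``sbt9_raw`` selects the dialect in which the bothersomeness item is
    stored as its raw 5-level code rather than pre-dichotomized 0/1.
    """
    region_map = region_map or default_region_map()
    expected = cohort_columns(region_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        extra = [c for c in df.columns if c not in expected]
        detail = []
        if missing:
            detail.append(f"missing column(s) {missing}")
        if extra:
            detail.append(f"unexpected column(s) {extra}")
        if not detail:
            detail.append("columns out of order")
        raise SchemaError(f"bad cohort header: {'; '.join(detail)}")

    records = []
    for _, row in df.iterrows():
        rid = row["id"].strip()
        if not rid:
            raise ValidationError("blank id cell")
        kwargs: dict = {"id": rid}

        age = row["age"].strip()
        kwargs["age"] = float(age) if age else None
        sex = row["sex"].strip()
        if sex:
            if sex not in ("F", "M"):
                raise ValidationError(f"record {rid}: sex must be F/M, got {sex!r}")
            kwargs["sex"] = "female" if sex == "F" else "male"
        lbp = row["lbp_last_week"].strip()
        if lbp:
            kwargs["lbp_last_week"] = bool(_parse_binary(lbp, "lbp_last_week", rid))

        sbt_cells = [row[c].strip() for c in _SBT_COLS]
        if all(sbt_cells):
            items = [
                _parse_binary(c, col, rid)
                for c, col in zip(sbt_cells[:8], _SBT_COLS[:8])
            ]
            items.append(_parse_sbt9(sbt_cells[8], rid, sbt9_raw))
            kwargs["sbt_items"] = tuple(items)

        chronic = row["chronic_pain"].strip()
        region_cells = {rid_: row[f"reg_{rid_}"].strip() for rid_ in region_map.ids}
        if chronic and all(region_cells.values()):
            kwargs["chronic_pain"] = bool(_parse_binary(chronic, "chronic_pain", rid))
            kwargs["regions"] = frozenset(
                name
                for name, cell in region_cells.items()
                if _parse_binary(cell, f"reg_{name}", rid)
            )

        for name in PRO_FIELDS:
            cell = row[name].strip()
            if cell:
                try:
                    value = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"record {rid}: {name} must be numeric, got {cell!r}"
                    ) from None
                lo, hi = PRO_RANGES[name]
                if not (lo <= value <= hi):
                    raise ValidationError(
                        f"record {rid}: {name}={cell} outside range {lo}-{hi}"
                    )
                kwargs[name] = value

        records.append(IndividualRecord(**kwargs))
    return Cohort(tuple(records), region_map)


def _fmt(value, integral: bool = False) -> str:
    if value is None:
        return ""
    if integral or float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the CSV schema (inverse of :func:`read_cohort`)."""
    rows = []
    for r in cohort:
        row: dict[str, str] = {
            "id": r.id,
            "age": _fmt(r.age),
            "sex": {"female": "F", "male": "M"}.get(r.sex or "", ""),
            "lbp_last_week": "" if r.lbp_last_week is None else str(int(r.lbp_last_week)),
        }
        for i, col in enumerate(_SBT_COLS):
            row[col] = "" if r.sbt_items is None else str(r.sbt_items[i])
        mann = r.mannequin_complete
        row["chronic_pain"] = str(int(r.chronic_pain)) if mann else ""
        for rid_ in cohort.region_map.ids:
            row[f"reg_{rid_}"] = str(int(rid_ in r.regions)) if mann else ""
        for name in PRO_FIELDS:
            row[name] = _fmt(getattr(r, name))
        rows.append(row)
    df = pd.DataFrame(rows, columns=cohort_columns(cohort.region_map))
    df.to_csv(path, index=False)
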