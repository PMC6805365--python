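"""Shared fixtures: region maps and programmatically built cohorts."""

from __future__ import annotations

import pytest

from lbptriage.cohort import Cohort, IndividualRecord
from lbptriage.mannequin import BodyRegion, BodyRegionMap, default_region_map

# SBT item patterns realizing each risk level
SBT_LOW = (0,) * 9  # overall 0, psych 0
SBT_MEDIUM = (1, 1, 1, 1, 0, 0, 0, 0, 0)  # overall 4, psych 0
SBT_HIGH = (0, 0, 0, 0, 1, 1, 1, 1, 0)  # overall 4, psych 4

# region sets realizing each mannequin outcome (with chronic pain)
REGIONS_MS_CWP = frozenset(
    {"lower_back", "upper_back", "shoulder_l", "shoulder_r", "hip_l", "knee_l", "knee_r"}
)  # widespread and 7 regions
REGIONS_REGIONAL = frozenset({"lower_back"})  # chronic regional pain only


@pytest.fixture(scope="session")
def region_map() -> BodyRegionMap:
    return default_region_map()


@pytest.fixture(scope="session")
def reduced_map() -> BodyRegionMap:
    """An 8-region chart exercising the same attribute logic exhaustively."""
    return BodyRegionMap(
        (
            BodyRegion("neck", True, "midline", "upper"),
            BodyRegion("lower_back", True, "midline", "lower"),
            BodyRegion("shoulder_l", False, "left", "upper"),
            BodyRegion("shoulder_r", False, "right", "upper"),
            BodyRegion("hip_l", False, "left", "lower"),
            BodyRegion("hip_r", False, "right", "lower"),
            BodyRegion("knee_l", False, "left", "lower"),
            BodyRegion("knee_r", False, "right", "lower"),
        )
    )


def make_record(i: int, **kwargs) -> IndividualRecord:
    return IndividualRecord(id=f"r{i:03d}", **kwargs)


@pytest.fixture()
def agreement_cohort(region_map) -> Cohort:
    """LBP cohort realizing the 3x2 agreement cells (28,4,0 / 11,4,1).

    48 LBP respondents with both screens complete, 4 LBP respondents with
    the SBT missing (so the group has 52), and 5 references.
    """
    cells = {
        (SBT_LOW, False): 28,
        (SBT_MEDIUM, False): 4,
        (SBT_HIGH, False): 0,
        (SBT_LOW, True): 11,
        (SBT_MEDIUM, True): 4,
        (SBT_HIGH, True): 1,
    }
    def pros(i: int, ms: bool) -> dict:
        jitter = i % 3
        return {
            "age": 50 + i % 15,
            "sex": "female" if i % 2 else "male",
            "nrs_pain": (6 if ms else 4) + jitter - 1,
            "rmdq": (8 if ms else 5) + jitter,
            "eq5d_index": (0.6 if ms else 0.7) + 0.02 * jitter,
            "had_anxiety": (9 if ms else 7) + jitter - 1,
            "had_depression": (5 if ms else 3) + jitter - 1,
            "fabq_pa": (9 if ms else 8) + jitter,
            "fabq_work": (20 if ms else 12) + jitter,
        }

    records = []
    i = 0
    for (items, ms), count in cells.items():
        for _ in range(count):
            records.append(
                make_record(
                    i,
                    lbp_last_week=True,
                    sbt_items=items,
                    chronic_pain=True,
                    regions=REGIONS_MS_CWP if ms else REGIONS_REGIONAL,
                    **pros(i, ms),
                )
            )
            i += 1
    for _ in range(4):  # SBT incomplete, mannequin complete
        records.append(
            make_record(
                i,
                lbp_last_week=True,
                sbt_items=None,
                chronic_pain=True,
                regions=REGIONS_REGIONAL,
                **pros(i, False),
            )
        )
        i += 1
    for _ in range(5):
        records.append(
            make_record(
                i,
                lbp_last_week=False,
                sbt_items=SBT_LOW,
                chronic_pain=False,
                regions=frozenset(),
                age=48 + i % 15,
                sex="female" if i % 2 else "male",
                nrs_pain=1 + i % 2,
                rmdq=2 + i % 2,
                eq5d_index=0.85 + 0.02 * (i % 2),
                had_anxiety=4 + i % 2,
                had_depression=2 + i % 2,
                fabq_pa=5 + i % 2,
                fabq_work=8 + i % 2,
            )
        )
        i += 1
    return Cohort(tuple(records))
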