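"""STarT Back Screening Tool (SBT) scoring and risk stratification.

Nine binary items: four physical risk factors (referred leg pain,
neck/shoulder pain, walking disability, difficulty dressing) followed by
five psychosocial factors (fear of movement, anxiety, catastrophizing,
feelings of depression, bothersomeness).  Items 1-8 are agree/disagree;
item 9 is asked on a 5-level bothersomeness scale and endorsed when the
answer is "very much" or "extremely".

Overall score = sum of all nine items (0-9, best to worst); the
psychosocial subscale = sum of items 5-9 (0-5).  Risk of a worse prognosis:

* **high** — psychosocial subscale >= 4;
* **medium** — overall >= 4 with psychosocial < 4;
* **low** — overall <= 3 (and psychosocial < 4).

The three rules are mutually consistent because the subscale is contained
in the total, so psychosocial >= 4 implies overall >= 4.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

PSYCHOSOCIAL_ITEMS = slice(4, 9)  # items 5-9, zero-based
HIGH_PSYCH_CUTOFF = 4
MEDIUM_OVERALL_CUTOFF = 4
BOTHERSOME_ENDORSED_LEVELS = (4, 5)  # "very much", "extremely" on 1-5 scale

__all__ = ["RiskLevel", "SbtResult", "score_sbt", "stratify_sbt", "sbt_result"]


class RiskLevel(str, enum.Enum):
    """Risk of persistent disabling back pain; ordered low < medium < high."""

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"

    @property
    def rank(self) -> int:
        return ("low", "medium", "high").index(self.value)


@dataclass(frozen=True)
class SbtResult:
    overall: int  # 0-9
    psychosocial: int  # 0-5
    risk: RiskLevel

    def __post_init__(self) -> None:
        if not (0 <= self.psychosocial <= self.overall <= 9):
            raise ValueError(
                f"invalid SBT scores: overall={self.overall}, "
                f"psychosocial={self.psychosocial}"
            )
        if self.psychosocial > 5:
            raise ValueError("psychosocial subscale exceeds 5")


def dichotomize_bothersomeness(level: int) -> int:
    """Collapse the 5-level bothersomeness response to a binary endorsement."""
    if level not in (1, 2, 3, 4, 5):
        raise ValueError(f"bothersomeness level must be 1-5, got {level!r}")
    return int(level in BOTHERSOME_ENDORSED_LEVELS)


def _check_items(items: Sequence[Optional[int]]) -> Optional[tuple[int, ...]]:
    if items is None:
        return None
    if len(items) != 9:
        raise ValueError(f"SBT has 9 items, got {len(items)}")
    if any(v is None for v in items):
        # partially answered instrument: no prorating, whole SBT is missing
        return None
    items = tuple(int(v) for v in items)
    if any(v not in (0, 1) for v in items):
        raise ValueError("SBT items must be binary endorsements")
    return items


def stratify_sbt(overall: int, psychosocial: int) -> RiskLevel:
    """Map (overall, psychosocial subscale) to the three-level risk group."""
    if psychosocial >= HIGH_PSYCH_CUTOFF:
        return RiskLevel.HIGH
    if overall >= MEDIUM_OVERALL_CUTOFF:
        return RiskLevel.MEDIUM
    return RiskLevel.LOW


def score_sbt(items: Sequence[Optional[int]]) -> Optional[SbtResult]:
    """Score one SBT response and stratify it.

    ``items`` are the nine binary endorsements in instrument order (item 9
    already dichotomized; see :func:`dichotomize_bothersomeness`).  Returns
    ``None`` when the instrument is missing or partially answered.
    """
    checked = _check_items(items)
    if checked is None:
        return None
    overall = sum(checked)
    psychosocial = sum(checked[PSYCHOSOCIAL_ITEMS])
    return SbtResult(overall, psychosocial, stratify_sbt(overall, psychosocial))


def sbt_result(record) -> Optional[SbtResult]:
    """Score the SBT of an :class:`~lbptriage.cohort.IndividualRecord`."""
    return score_sbt(record.sbt_items) if record.sbt_items is not None else None
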