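"""Combined two-instrument triage: SBT risk OR mannequin MS-CWP.

The combined screen flags a respondent as *high* risk of a worse prognosis
when either instrument does: SBT risk level high, or MS-CWP (chronic
widespread pain with >= 7 painful regions) on the mannequin.  Everyone
else — SBT low/medium and no MS-CWP — is *lower* risk.

Missing inputs propagate by three-valued OR logic: one triggering input is
enough to conclude high even if the other is missing, but a single
non-triggering input cannot rule high out, so the combined outcome is then
missing.  This makes the silent complete-case drop of partially screened
respondents explicit.

An alternative rule (``variant="medium_gate"``), in which MS-CWP upgrades
only respondents the SBT already places at medium risk, is provided for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .sbt import RiskLevel

__all__ = ["CombinedRisk", "combine", "combined_high_count", "VARIANTS"]

VARIANTS = ("or", "medium_gate")


@dataclass(frozen=True)
class CombinedRisk:
    """Two-level combined outcome plus which screen(s) triggered it."""

    level: str  # "lower" | "high"
    source: frozenset[str]  # subset of {"sbt_high", "ms_cwp"}

    def __post_init__(self) -> None:
        if self.level not in ("lower", "high"):
            raise ValueError(f"invalid combined level {self.level!r}")
        if (self.level == "high") != bool(self.source):
            raise ValueError("level is high exactly when a source triggered")


def _sbt_triggers(sbt_risk: Optional[RiskLevel], variant: str) -> Optional[bool]:
    if sbt_risk is None:
        return None
    return RiskLevel(sbt_risk) is RiskLevel.HIGH


def _mannequin_triggers(
    ms_cwp: Optional[bool], sbt_risk: Optional[RiskLevel], variant: str
) -> Optional[bool]:
    if ms_cwp is None:
        return None
    if variant == "medium_gate":
        # MS-CWP upgrades only SBT-medium respondents
        if not ms_cwp:
            return False
        if sbt_risk is None:
            return None
        return RiskLevel(sbt_risk) is RiskLevel.MEDIUM
    return bool(ms_cwp)


def combine(
    sbt_risk: Optional[RiskLevel],
    ms_cwp: Optional[bool],
    *,
    variant: str = "or",
) -> Optional[CombinedRisk]:
    """Combine the two screens; ``None`` inputs are missing answers.

    Returns ``None`` when high risk can neither be concluded nor excluded.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown combine variant {variant!r}")
    triggers = {
        "sbt_high": _sbt_triggers(sbt_risk, variant),
        "ms_cwp": _mannequin_triggers(ms_cwp, sbt_risk, variant),
    }
    fired = frozenset(k for k, v in triggers.items() if v is True)
    if fired:
        return CombinedRisk("high", fired)
    if any(v is None for v in triggers.values()):
        return None  # cannot rule out high
    return CombinedRisk("lower", frozenset())


def combined_high_count(crosstab: dict[tuple[str, bool], int]) -> int:
    """Number of combined-high respondents in an SBT-risk x MS-CWP crosstab.

    ``crosstab`` maps (risk level, ms_cwp flag) to a non-negative count over
    the six cells; combined-high = every MS-CWP cell plus (high, no MS-CWP).
    """
    total = 0
    for (risk, ms), count in crosstab.items():
        risk = RiskLevel(risk)
        if count < 0 or count != int(count):
            raise ValueError("cell counts must be non-negative integers")
        outcome = combine(risk, bool(ms))
        assert outcome is not None
        if outcome.level == "high":
            total += int(count)
    return total
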