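"""Pain-mannequin classification: chronic widespread pain and multisite pain.

The mannequin instrument has two parts: a single chronicity question (any
ache or pain lasting more than three months during the past twelve months)
and a body chart with 18 predefined regions on which the respondent marks
painful areas.  Classification follows the ACR-1990 convention:

* **NCP** — no chronic pain (chronicity answered "no");
* **CRP** — chronic regional pain: chronic, but the marked regions do not
  satisfy the widespread criterion;
* **CWP** — chronic widespread pain: chronic, with pain in the axial
  skeleton, on both sides of the body, and in the upper and lower body half.

Independently of the CWP rule, marking seven or more regions is *multisite*
pain (MS); CWP together with multisite pain is flagged **MS-CWP**, the
mannequin-based marker of high risk of a worse prognosis.

All logic is attribute-driven through :class:`BodyRegionMap`, so any
18-region chart with axial/side/body-half annotations can be substituted.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import FrozenSet, Iterable, Mapping, Optional

import yaml

MULTISITE_THRESHOLD = 7

__all__ = [
    "BodyRegion",
    "BodyRegionMap",
    "PainStatus",
    "MannequinResult",
    "default_region_map",
    "load_region_map",
    "is_widespread",
    "classify_mannequin",
    "has_lbp_region",
]


class PainStatus(str, enum.Enum):
    """Chronic-pain category under the ACR widespread-pain rule."""

    NCP = "NCP"
    CRP = "CRP"
    CWP = "CWP"


@dataclass(frozen=True)
class BodyRegion:
    id: str
    axial: bool
    side: str  # left | right | midline
    body_half: str  # upper | lower

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "midline"):
            raise ValueError(f"region {self.id!r}: invalid side {self.side!r}")
        if self.body_half not in ("upper", "lower"):
            raise ValueError(
                f"region {self.id!r}: invalid body_half {self.body_half!r}"
            )


@dataclass(frozen=True)
class BodyRegionMap:
    """The predefined mannequin regions with the attributes the CWP rule needs.

    The default map has 4 axial midline regions (head, neck, upper back,
    lower back) and 7 bilateral pairs; :func:`load_region_map` accepts any
    alternative chart as a YAML config.
    """

    regions: tuple[BodyRegion, ...]
    _by_id: Mapping[str, BodyRegion] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_id = {r.id: r for r in self.regions}
        if len(by_id) != len(self.regions):
            raise ValueError("duplicate region identifiers")
        if not any(r.axial for r in self.regions):
            raise ValueError("region map needs at least one axial region")
        for side in ("left", "right"):
            if not any(r.side == side for r in self.regions):
                raise ValueError(f"region map needs at least one {side}-side region")
        for half in ("upper", "lower"):
            if not any(r.body_half == half for r in self.regions):
                raise ValueError(f"region map needs at least one {half}-half region")
        object.__setattr__(self, "_by_id", by_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def __getitem__(self, region_id: str) -> BodyRegion:
        try:
            return self._by_id[region_id]
        except KeyError:
            raise KeyError(f"unknown region id {region_id!r}") from None

    def validate_subset(self, regions: Iterable[str]) -> frozenset[str]:
        regions = frozenset(regions)
        unknown = regions - set(self._by_id)
        if unknown:
            raise ValueError(f"unknown region id(s): {sorted(unknown)}")
        return regions


@dataclass(frozen=True)
class MannequinResult:
    """Outcome of classifying one mannequin response."""

    chronic: bool
    region_count: int
    status: PainStatus
    multisite: bool
    ms_cwp: bool


def load_region_map(path: str | Path) -> BodyRegionMap:
    """Read a region map from a YAML config (one entry per region)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _map_from_doc(doc)


def _map_from_doc(doc: dict) -> BodyRegionMap:
    entries = doc["regions"]
    return BodyRegionMap(
        tuple(
            BodyRegion(
                id=str(e["id"]),
                axial=bool(e["axial"]),
                side=str(e["side"]),
                body_half=str(e["body_half"]),
            )
            for e in entries
        )
    )


def default_region_map() -> BodyRegionMap:
    """The 18-region map shipped with the package."""
    text = (
        resources.files("lbptriage").joinpath("data/regions.yaml").read_text("utf-8")
    )
    rmap = _map_from_doc(yaml.safe_load(text))
    if len(rmap) != 18:
        raise RuntimeError("default region map must have exactly 18 regions")
    return rmap


def is_widespread(regions: Iterable[str], region_map: BodyRegionMap) -> bool:
    """ACR widespread-pain test on a set of marked regions.

    True iff the set touches the axial skeleton, the left and the right side
    of the body, and the upper and the lower body half.  Midline (axial)
    regions count toward neither side.
    """
    marked = [region_map[r] for r in region_map.validate_subset(regions)]
    return (
        any(r.axial for r in marked)
        and any(r.side == "left" for r in marked)
        and any(r.side == "right" for r in marked)
        and any(r.body_half == "upper" for r in marked)
        and any(r.body_half == "lower" for r in marked)
    )


def classify_mannequin(
    chronic: Optional[bool],
    regions: Iterable[str],
    region_map: BodyRegionMap,
) -> Optional[MannequinResult]:
    """Classify one mannequin response into NCP / CRP / CWP plus MS flags.

    Returns ``None`` (instrument missing) when the chronicity answer is
    missing.  A chronic respondent with an empty region set is classified
    CRP — chronic but demonstrably not widespread — with a warning, since
    the combination is internally inconsistent.
    """
    if chronic is None:
        return None
    marked = region_map.validate_subset(regions)
    count = len(marked)
    if not chronic:
        status = PainStatus.NCP
    elif is_widespread(marked, region_map):
        status = PainStatus.CWP
    else:
        if count == 0:
            warnings.warn(
                "chronic pain reported with no regions marked; classified CRP",
                UserWarning,
                stacklevel=2,
            )
        status = PainStatus.CRP
    multisite = count >= MULTISITE_THRESHOLD
    ms_cwp = (status is PainStatus.CWP) and multisite
    return MannequinResult(
        chronic=bool(chronic),
        region_count=count,
        status=status,
        multisite=multisite,
        ms_cwp=ms_cwp,
    )


def has_lbp_region(
    regions: Iterable[str],
    region_map: BodyRegionMap,
    lbp_region: str = "lower_back",
) -> bool:
    """Whether the lower-back region is marked on the mannequin."""
    return lbp_region in region_map.validate_subset(regions)
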