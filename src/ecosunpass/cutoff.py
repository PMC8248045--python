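"""Exclusion criteria that mark a UV filter as not ecofriendly at all.

A substance is excluded from the ecofriendliness ranking outright when it is
an endocrine disruptor (WHO definition, carried as an input flag), meets the
PBT or vPvB criteria, or is acutely (EC/LC50 < 0.1 mg/L) or chronically
(NOEC/EC10 < 0.01 mg/L) toxic to aquatic organisms.  Which criteria apply is
a regional regulatory choice: the EU profile enables all five, other regions
may drop the endocrine-disruptor or PBT/vPvB criteria or move the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .endpoint_data import (
    Chapter,
    CutoffFlag,
    SubstanceDossier,
    filter_reliable,
    select_driver,
)

__all__ = ["RegionProfile", "CutoffVerdict", "evaluate_cutoff", "REGION_PROFILES", "EU"]


@dataclass(frozen=True)
class RegionProfile:
    """Which exclusion criteria are active and at which aquatic thresholds."""

    name: str
    ed_enabled: bool = True
    pbt_enabled: bool = True
    vpvb_enabled: bool = True
    acute_threshold_mg_l: float = 0.1
    chronic_threshold_mg_l: float = 0.01


EU = RegionProfile(name="EU")

REGION_PROFILES: dict[str, RegionProfile] = {
    "EU": EU,
    # ED criterion has no regulatory anchor in some regions; PBT/vPvB kept.
    "no-ED": RegionProfile(name="no-ED", ed_enabled=False),
    # Aquatic-toxicity thresholds only.
    "permissive": RegionProfile(
        name="permissive", ed_enabled=False, pbt_enabled=False, vpvb_enabled=False
    ),
}


def get_region_profile(name: str | RegionProfile) -> RegionProfile:
    if isinstance(name, RegionProfile):
        return name
    try:
        return REGION_PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown region profile {name!r}; known: {sorted(REGION_PROFILES)}"
        ) from None


@dataclass(frozen=True)
class CutoffVerdict:
    substance: str
    reasons: tuple[str, ...]
    region_profile: str
    failed: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "failed", bool(self.reasons))


def evaluate_cutoff(
    dossier: SubstanceDossier, region_profile: str | RegionProfile = "EU"
) -> CutoffVerdict:
    """Test a dossier against the active exclusion criteria.

    Flags (ED/PBT/vPvB) are regulatory inputs on the dossier; the aquatic
    criteria are re-derived from the reliable (Klimisch 1-2) endpoint drivers.
    Values exactly at a threshold do not fail (strict ``<``).
    """
    profile = get_region_profile(region_profile)
    reasons: list[str] = []
    flags = dossier.cutoff_flags
    if profile.ed_enabled and CutoffFlag.ENDOCRINE_DISRUPTOR in flags:
        reasons.append("endocrine_disruptor")
    if profile.pbt_enabled and CutoffFlag.PBT in flags:
        reasons.append("pbt")
    if profile.vpvb_enabled and CutoffFlag.VPVB in flags:
        reasons.append("vpvb")

    reliable = filter_reliable(dossier.records)
    acute = select_driver(reliable, Chapter.ACUTE_AQUATIC)
    if CutoffFlag.ACUTE_TOXIC in flags or (
        acute is not None
        and not acute.no_effect_at_limit
        and acute.numeric_value < profile.acute_threshold_mg_l
    ):
        reasons.append("acute_lt_0.1")
    chronic = select_driver(reliable, Chapter.CHRONIC_AQUATIC)
    if CutoffFlag.CHRONIC_TOXIC in flags or (
        chronic is not None
        and not chronic.no_effect_at_limit
        and chronic.numeric_value < profile.chronic_threshold_mg_l
    ):
        reasons.append("chronic_lt_0.01")
    return CutoffVerdict(
        substance=dossier.name, reasons=tuple(reasons), region_profile=profile.name
    )
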