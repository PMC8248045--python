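"""Substance-level environmental evidence: endpoint records, dossiers, quality filtering.

The unit of evidence is an :class:`EndpointRecord` — one measured (or estimated)
ecotoxicological endpoint such as "EC50 algae 72h = 5 mg/L", graded for
reliability with a Klimisch code.  A :class:`SubstanceDossier` collects all
records for one UV filter together with its fate descriptors (biodegradation
category, log Pow, log Koc), regulatory cut-off flags and its mean specific
extinction <E11>.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

__all__ = [
    "Chapter",
    "Source",
    "BiodegradationClass",
    "CutoffFlag",
    "EndpointRecord",
    "SubstanceDossier",
    "filter_reliable",
    "select_driver",
]


class Chapter(str, enum.Enum):
    """The six environmental assessment compartments ("chapters")."""

    BIODEGRADATION = "biodegradation"
    BIOACCUMULATION = "bioaccumulation"
    ACUTE_AQUATIC = "acute_aquatic"
    CHRONIC_AQUATIC = "chronic_aquatic"
    SEDIMENT = "sediment"
    TERRESTRIAL = "terrestrial"


#: Chapters whose records carry a concentration driving a toxicity score.
TOXICITY_CHAPTERS = (
    Chapter.ACUTE_AQUATIC,
    Chapter.CHRONIC_AQUATIC,
    Chapter.SEDIMENT,
    Chapter.TERRESTRIAL,
)

#: Expected unit string per chapter (loader-enforced).
CHAPTER_UNITS = {
    Chapter.BIOACCUMULATION: "dimensionless",
    Chapter.ACUTE_AQUATIC: "mg/L",
    Chapter.CHRONIC_AQUATIC: "mg/L",
    Chapter.SEDIMENT: "mg/kg dw",
    Chapter.TERRESTRIAL: "mg/kg dw",
    Chapter.BIODEGRADATION: "dimensionless",
}


class Source(str, enum.Enum):
    """Provenance of a record; also the tie-break priority (study strongest)."""

    STUDY = "study"
    AUTHORITY = "authority"
    LITERATURE = "literature"
    QSAR = "qsar"
    EXPERT_JUDGEMENT = "expert_judgement"


#: Lower rank = higher priority when breaking ties between equal driver values.
_SOURCE_PRIORITY = {
    Source.STUDY: 0,
    Source.AUTHORITY: 1,
    Source.LITERATURE: 2,
    Source.QSAR: 3,
    Source.EXPERT_JUDGEMENT: 4,
}

#: QSAR estimates are considered too uncertain for these chapters and are
#: rejected at load time.
QSAR_FORBIDDEN_CHAPTERS = (Chapter.CHRONIC_AQUATIC, Chapter.TERRESTRIAL)


class BiodegradationClass(str, enum.Enum):
    READILY = "readily"
    BIODEGRADABLE = "biodegradable"
    PARTLY = "partly"
    POOR = "poor"
    NOT_APPLICABLE = "not_applicable"


class CutoffFlag(str, enum.Enum):
    """Regulatory exclusion flags carried on the dossier (inputs, not computed)."""

    ENDOCRINE_DISRUPTOR = "endocrine_disruptor"
    PBT = "pbt"
    VPVB = "vpvb"
    ACUTE_TOXIC = "acute_toxic"
    CHRONIC_TOXIC = "chronic_toxic"


@dataclass(frozen=True)
class EndpointRecord:
    """One piece of endpoint evidence for one chapter of one substance.

    Parameters
    ----------
    chapter
        Environmental chapter the endpoint belongs to.
    numeric_value
        Concentration (mg/L aquatic, mg/kg dry weight sediment/soil) or BCF
        (dimensionless).  Must be strictly positive for numeric records.
    endpoint_label
        Free text, e.g. ``"EC50 algae 72h"`` or ``"NOEC Daphnia 21d"``.
    quality_code
        Klimisch reliability grade, 1 (reliable without restriction) to 4
        (not assignable).
    source
        Provenance category; drives tie-breaking and QSAR admission rules.
    no_effect_at_limit
        True when the test showed no effect up to the highest concentration
        tested (or the solubility limit); such endpoints score the chapter
        minimum regardless of the numeric value, which then records the limit
        concentration.
    """

    chapter: Chapter
    numeric_value: float
    endpoint_label: str
    quality_code: int
    source: Source
    no_effect_at_limit: bool = False
    value_kind: str = "numeric"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chapter", Chapter(self.chapter))
        object.__setattr__(self, "source", Source(self.source))
        if self.quality_code not in (1, 2, 3, 4):
            raise ValueError(f"quality_code must be 1-4, got {self.quality_code!r}")
        if self.value_kind == "numeric" and not self.numeric_value > 0:
            raise ValueError(
                f"numeric_value must be > 0, got {self.numeric_value!r} "
                f"({self.endpoint_label!r})"
            )


@dataclass
class SubstanceDossier:
    """All environmental evidence for one UV filter.

    ``log_pow``/``log_koc`` are screening surrogates used when measured
    bioaccumulation or sediment/soil data are missing; ``cutoff_flags`` carry
    regulatory conclusions (ED, PBT, vPvB) that are inputs to this tool, not
    outputs.  ``mean_specific_extinction`` is <E11>, the 290-400 nm average
    specific extinction of a 1 wt% preparation at 1 cm pathlength.
    """

    name: str
    inci_abbreviation: str = ""
    is_inorganic: bool = False
    records: list[EndpointRecord] = field(default_factory=list)
    log_pow: float | None = None
    log_koc: float | None = None
    biodegradation_class: BiodegradationClass | None = None
    cutoff_flags: frozenset[CutoffFlag] = frozenset()
    mean_specific_extinction: float | None = None

    def __post_init__(self) -> None:
        if self.biodegradation_class is not None:
            self.biodegradation_class = BiodegradationClass(self.biodegradation_class)
        self.cutoff_flags = frozenset(CutoffFlag(f) for f in self.cutoff_flags)
        if self.is_inorganic:
            if self.biodegradation_class not in (None, BiodegradationClass.NOT_APPLICABLE):
                raise ValueError(
                    f"{self.name}: inorganic substances take biodegradation_class "
                    f"not_applicable, got {self.biodegradation_class}"
                )
            self.biodegradation_class = BiodegradationClass.NOT_APPLICABLE
        if self.mean_specific_extinction is not None and not self.mean_specific_extinction > 0:
            raise ValueError(f"{self.name}: mean_specific_extinction must be > 0")
        self.records = validate_records(self.records, substance=self.name)

    def records_for(self, chapter: Chapter) -> list[EndpointRecord]:
        chapter = Chapter(chapter)
        return [r for r in self.records if r.chapter is chapter]


def validate_records(
    records: list[EndpointRecord], substance: str = "?"
) -> list[EndpointRecord]:
    """Apply admission rules; QSAR records for chapters where QSAR is deemed
    inadequate (chronic aquatic, terrestrial) are dropped with a warning."""
    kept: list[EndpointRecord] = []
    for rec in records:
        if rec.source is Source.QSAR and rec.chapter in QSAR_FORBIDDEN_CHAPTERS:
            msg = (
                f"{substance}: rejecting QSAR record for chapter "
                f"{rec.chapter.value} ({rec.endpoint_label!r}); QSAR estimates "
                f"are not accepted for this endpoint"
            )
            warnings.warn(msg, stacklevel=2)
            logger.warning(msg)
            continue
        kept.append(rec)
    return kept


def filter_reliable(records: list[EndpointRecord]) -> list[EndpointRecord]:
    """Keep only records graded reliable on the Klimisch scale (codes 1-2).

    Order-preserving and idempotent; the input list is not modified.
    """
    return [r for r in records if r.quality_code in (1, 2)]


def select_driver(
    records: list[EndpointRecord], chapter: Chapter
) -> EndpointRecord | None:
    """Pick the most sensitive endpoint (lowest value) of a chapter.

    Ties are broken by source priority (study > authority > literature > qsar >
    expert judgement), then by endpoint label, so the result is independent of
    input order.  Returns ``None`` when the chapter has no record.
    """
    chapter = Chapter(chapter)
    candidates = [r for r in records if r.chapter is chapter]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda r: (r.numeric_value, _SOURCE_PRIORITY[r.source], r.endpoint_label),
    )
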