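"""Per-chapter hazard scoring and the overall environmental hazard score.

Each of six environmental chapters maps its evidence onto a 0.25-step score:
0.25 (benign) up to 1.0 for the two fate chapters (biodegradation,
bioaccumulation) and up to 1.25 for the four toxicity chapters, where a driver
one decade below the most hazardous regular band escalates the score by a
single +0.25.  The overall score is the plain sum over the six chapters and
therefore spans 1.5 (ecofriendly) to 7.0 (hazardous).

Data gaps are resolved three ways at once — a *best* case (gap scored at the
chapter minimum), a *worst* case (chapter maximum) and a *real* case that uses
fate-property screening (biodegradability, log Pow, log Koc) where regulatory
practice supports it.  The spread between best and worst quantifies how much
of the score rests on missing data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .endpoint_data import (
    Chapter,
    TOXICITY_CHAPTERS,
    BiodegradationClass,
    EndpointRecord,
    Source,
    SubstanceDossier,
    filter_reliable,
    select_driver,
)

__all__ = [
    "Case",
    "Basis",
    "ChapterScore",
    "HazardScore",
    "HazardTriple",
    "score_biodegradation",
    "score_bioaccumulation",
    "score_toxicity",
    "resolve_chapter",
    "overall_score",
    "hazard_triple",
    "CHAPTER_MIN",
    "OVERALL_MIN",
    "OVERALL_MAX",
]


class Case(str, enum.Enum):
    BEST = "best"
    REAL = "real"
    WORST = "worst"


class Basis(str, enum.Enum):
    """How a chapter score was obtained — auditable provenance."""

    MEASURED = "measured"
    SURROGATE = "surrogate"
    BEST_CASE_FILL = "best_case_fill"
    WORST_CASE_FILL = "worst_case_fill"


CHAPTER_MIN = 0.25
FATE_MAX = 1.0
TOXICITY_MAX = 1.25
OVERALL_MIN = 6 * CHAPTER_MIN            # 1.5
OVERALL_MAX = 2 * FATE_MAX + 4 * TOXICITY_MAX  # 7.0

#: log Pow at or above which a substance is treated as (very) bioaccumulative
#: when no measured BCF exists.
LOG_POW_BIOACC_THRESHOLD = 4.5
#: log Koc screening trigger for adsorption to organic matter (sediment/soil
#: dissemination); a conventional screening value, configurable by callers.
LOG_KOC_ADSORPTION_THRESHOLD = 3.0


@dataclass(frozen=True)
class ChapterScore:
    chapter: Chapter
    score: float
    basis: Basis

    def __post_init__(self) -> None:
        maximum = chapter_max(self.chapter)
        steps = round(self.score / 0.25, 9)
        if abs(steps - round(steps)) > 1e-9 or not CHAPTER_MIN <= self.score <= maximum:
            raise ValueError(
                f"{self.chapter.value}: score {self.score} outside the valid "
                f"0.25-step range [{CHAPTER_MIN}, {maximum}]"
            )


@dataclass(frozen=True)
class HazardScore:
    """Six chapter scores plus their sum, for one uncertainty case."""

    substance: str
    chapters: dict[Chapter, ChapterScore]
    case: Case

    def __post_init__(self) -> None:
        if set(self.chapters) != set(Chapter):
            missing = set(Chapter) - set(self.chapters)
            raise ValueError(f"{self.substance}: missing chapters {missing}")

    @property
    def overall(self) -> float:
        return sum(cs.score for cs in self.chapters.values())


@dataclass(frozen=True)
class HazardTriple:
    best: HazardScore
    real: HazardScore
    worst: HazardScore

    def __post_init__(self) -> None:
        if not self.best.overall <= self.real.overall <= self.worst.overall:
            raise ValueError(
                f"{self.best.substance}: case ordering violated "
                f"({self.best.overall}, {self.real.overall}, {self.worst.overall})"
            )

    @property
    def spread(self) -> float:
        return self.worst.overall - self.best.overall


def chapter_max(chapter: Chapter) -> float:
    return TOXICITY_MAX if Chapter(chapter) in TOXICITY_CHAPTERS else FATE_MAX


_BIODEG_SCORES = {
    BiodegradationClass.READILY: 0.25,
    BiodegradationClass.BIODEGRADABLE: 0.5,
    BiodegradationClass.PARTLY: 0.75,
    BiodegradationClass.POOR: 1.0,
}


def score_biodegradation(
    biodeg_class: BiodegradationClass | None, is_inorganic: bool = False
) -> ChapterScore:
    """Score degradability: readily 0.25 ... poor 1.0.

    Inorganic filters do not degrade at all, so they take the persistent-end
    score 1.0 on a surrogate basis rather than a measured category.
    """
    if is_inorganic:
        return ChapterScore(Chapter.BIODEGRADATION, 1.0, Basis.SURROGATE)
    if biodeg_class is None or biodeg_class is BiodegradationClass.NOT_APPLICABLE:
        raise ValueError("organic substance without a biodegradation class (data gap)")
    return ChapterScore(
        Chapter.BIODEGRADATION, _BIODEG_SCORES[BiodegradationClass(biodeg_class)], Basis.MEASURED
    )


def score_bioaccumulation(
    bcf: float | None, log_pow: float | None, worst_fill: bool = False
) -> ChapterScore:
    """Score bioaccumulation from BCF bands, or the log Pow surrogate.

    BCF bands: <500 -> 0.25, [500, 2000) -> 0.5, [2000, 5000) -> 0.75,
    >=5000 -> 1.0.  Without a BCF, log Pow >= 4.5 marks the substance
    bioaccumulative (0.75, or 1.0 under a worst-case reading of "very
    bioaccumulative"), below 4.5 not bioaccumulative (0.25).
    """
    if bcf is not None:
        if bcf < 500:
            s = 0.25
        elif bcf < 2000:
            s = 0.5
        elif bcf < 5000:
            s = 0.75
        else:
            s = 1.0
        return ChapterScore(Chapter.BIOACCUMULATION, s, Basis.MEASURED)
    if log_pow is not None:
        if log_pow >= LOG_POW_BIOACC_THRESHOLD:
            s = 1.0 if worst_fill else 0.75
        else:
            s = 0.25
        return ChapterScore(Chapter.BIOACCUMULATION, s, Basis.SURROGATE)
    raise ValueError("neither BCF nor log Pow available (data gap)")


# Regular band edges per toxicity chapter, most hazardous first, as
# (threshold, score-if-value-at-or-above).  A value below the last regular
# threshold first earns 1.0's escalation check.  `top_strict` encodes whether
# the most benign band requires strictly exceeding its edge (acute: EC50 > 100)
# or includes it (chronic/soil: NOEC >= 10 / >= 1000).
@dataclass(frozen=True)
class _BandTable:
    edges: tuple[float, ...]  # descending thresholds for 0.25, 0.5, 0.75, 1.0 bands
    top_strict: bool

    def score(self, value: float) -> float:
        e25, e50, e75, e100 = self.edges
        if value > e25 or (not self.top_strict and value == e25):
            return 0.25
        if value >= e50:
            return 0.5
        if value >= e75:
            return 0.75
        if value >= e100:
            return 1.0
        # one decade below the 1.0 band floor: +0.25 escalation, applied once
        return 1.25


BAND_TABLES: dict[Chapter, _BandTable] = {
    Chapter.ACUTE_AQUATIC: _BandTable(edges=(100.0, 10.0, 1.0, 0.1), top_strict=True),
    Chapter.CHRONIC_AQUATIC: _BandTable(edges=(10.0, 1.0, 0.1, 0.01), top_strict=False),
    Chapter.SEDIMENT: _BandTable(edges=(1000.0, 100.0, 10.0, 1.0), top_strict=False),
    Chapter.TERRESTRIAL: _BandTable(edges=(1000.0, 100.0, 10.0, 1.0), top_strict=False),
}


def score_toxicity(
    value: float | None,
    chapter: Chapter,
    no_effect_at_limit: bool = False,
) -> ChapterScore:
    """Band-score a toxicity driver (EC50 for acute, NOEC/EC10 otherwise).

    ``no_effect_at_limit`` — no effects up to the highest concentration tested
    or the solubility limit — earns the chapter minimum irrespective of the
    concentration.  A driver one decade below the 1.0 band escalates to 1.25.
    """
    chapter = Chapter(chapter)
    if chapter not in BAND_TABLES:
        raise ValueError(f"{chapter.value} is not a toxicity chapter")
    if no_effect_at_limit:
        return ChapterScore(chapter, 0.25, Basis.MEASURED)
    if value is None or not value > 0:
        raise ValueError(f"invalid toxicity driver value {value!r}")
    return ChapterScore(chapter, BAND_TABLES[chapter].score(value), Basis.MEASURED)


def _measured_chapter(dossier: SubstanceDossier, chapter: Chapter) -> ChapterScore | None:
    """Score a chapter from measured evidence, or None when data are missing."""
    if chapter is Chapter.BIODEGRADATION:
        if dossier.is_inorganic:
            return score_biodegradation(None, is_inorganic=True)
        cls = dossier.biodegradation_class
        if cls is None or cls is BiodegradationClass.NOT_APPLICABLE:
            return None
        return score_biodegradation(cls)
    # expert-judgement records are real-case fill overrides, not measured
    # evidence: they must not collapse the best/worst uncertainty range
    reliable = [
        r for r in filter_reliable(dossier.records)
        if r.source is not Source.EXPERT_JUDGEMENT
    ]
    driver = select_driver(reliable, chapter)
    if chapter is Chapter.BIOACCUMULATION:
        if driver is None:
            return None
        return score_bioaccumulation(bcf=driver.numeric_value, log_pow=None)
    if driver is None:
        return None
    return score_toxicity(driver.numeric_value, chapter, driver.no_effect_at_limit)


def _expert_fill(dossier: SubstanceDossier, chapter: Chapter) -> ChapterScore | None:
    """An explicit expert-judgement record overrides the real-case fill."""
    candidates = [
        r
        for r in dossier.records_for(chapter)
        if r.source is Source.EXPERT_JUDGEMENT and r.quality_code in (1, 2)
    ]
    if not candidates or chapter not in BAND_TABLES:
        return None
    driver = select_driver(candidates, chapter)
    assert driver is not None
    return score_toxicity(driver.numeric_value, chapter, driver.no_effect_at_limit)


def _screening_allows_best(dossier: SubstanceDossier) -> bool:
    """Low-adsorption screening: readily biodegradable and no sorption signal
    means no relevant transfer into sediment/soil."""
    readily = dossier.biodegradation_class is BiodegradationClass.READILY
    low_koc = dossier.log_koc is None or dossier.log_koc < LOG_KOC_ADSORPTION_THRESHOLD
    low_pow = dossier.log_pow is not None and dossier.log_pow < LOG_POW_BIOACC_THRESHOLD
    return readily and low_koc and low_pow


def resolve_chapter(
    dossier: SubstanceDossier, chapter: Chapter, case: Case = Case.REAL
) -> ChapterScore:
    """Score one chapter under one uncertainty case.

    Measured evidence settles all three cases identically.  Gaps are filled by
    case: *best* at 0.25, *worst* at the chapter maximum, and *real* by
    screening — a readily biodegradable, low-log Pow/log Koc substance is not
    expected in sediment or soil (0.25 there), log Pow substitutes for BCF in
    bioaccumulation, and all remaining gaps fall back to the worst case.
    """
    chapter, case = Chapter(chapter), Case(case)
    measured = _measured_chapter(dossier, chapter)
    if measured is not None:
        return measured
    if case is Case.BEST:
        return ChapterScore(chapter, CHAPTER_MIN, Basis.BEST_CASE_FILL)
    if case is Case.WORST:
        # chapter maximum regardless of surrogates: new measured data could
        # always land in the most hazardous band
        return ChapterScore(chapter, chapter_max(chapter), Basis.WORST_CASE_FILL)
    # real case
    if chapter is Chapter.BIOACCUMULATION and dossier.log_pow is not None:
        return score_bioaccumulation(None, dossier.log_pow)
    if chapter in (Chapter.SEDIMENT, Chapter.TERRESTRIAL):
        expert = _expert_fill(dossier, chapter)
        if expert is not None:
            return expert
        if _screening_allows_best(dossier):
            return ChapterScore(chapter, CHAPTER_MIN, Basis.BEST_CASE_FILL)
        return ChapterScore(chapter, chapter_max(chapter), Basis.WORST_CASE_FILL)
    expert = _expert_fill(dossier, chapter)
    if expert is not None:
        return expert
    return ChapterScore(chapter, chapter_max(chapter), Basis.WORST_CASE_FILL)


def overall_score(dossier: SubstanceDossier, case: Case = Case.REAL) -> HazardScore:
    """Sum of the six chapter scores under one case; always in [1.5, 7.0]."""
    chapters = {ch: resolve_chapter(dossier, ch, case) for ch in Chapter}
    return HazardScore(substance=dossier.name, chapters=chapters, case=Case(case))


def hazard_triple(dossier: SubstanceDossier) -> HazardTriple:
    """Best/real/worst scores; the spread is zero iff every chapter is measured."""
    return HazardTriple(
        best=overall_score(dossier, Case.BEST),
        real=overall_score(dossier, Case.REAL),
        worst=overall_score(dossier, Case.WORST),
    )
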