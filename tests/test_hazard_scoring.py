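"""Chapter band scoring, data-gap resolution and the best/real/worst triple."""

import numpy as np
import pytest

from ecosunpass.endpoint_data import (
    BiodegradationClass,
    Chapter,
    EndpointRecord,
    Source,
    SubstanceDossier,
)
from ecosunpass.hazard_scoring import (
    Basis,
    Case,
    chapter_max,
    hazard_triple,
    overall_score,
    resolve_chapter,
    score_bioaccumulation,
    score_biodegradation,
    score_toxicity,
)
from ecosunpass.registry import random_dossiers


def oracle_band_score(value: float, chapter: Chapter) -> float:
    """Literal re-statement of the printed scoring bands, kept independent of
    the implementation's band-table mechanics."""
    if chapter is Chapter.ACUTE_AQUATIC:
        if value > 100:
            return 0.25
        if 10 <= value <= 100:
            return 0.5
        if 1 <= value < 10:
            return 0.75
        if 0.1 <= value < 1:
            return 1.0
        return 1.25
    if chapter is Chapter.CHRONIC_AQUATIC:
        if value >= 10:
            return 0.25
        if 1 <= value < 10:
            return 0.5
        if 0.1 <= value < 1:
            return 0.75
        if 0.01 <= value < 0.1:
            return 1.0
        return 1.25
    # sediment and terrestrial share the mg/kg dw bands
    if value >= 1000:
        return 0.25
    if 100 <= value < 1000:
        return 0.5
    if 10 <= value < 100:
        return 0.75
    if 1 <= value < 10:
        return 1.0
    return 1.25


class TestBiodegradation:
    @pytest.mark.parametrize(
        "cls,expected",
        [
            (BiodegradationClass.READILY, 0.25),
            (BiodegradationClass.BIODEGRADABLE, 0.5),
            (BiodegradationClass.PARTLY, 0.75),
            (BiodegradationClass.POOR, 1.0),
        ],
    )
    def test_category_map(self, cls, expected):
        assert score_biodegradation(cls).score == expected

    def test_inorganic_is_persistent_surrogate(self):
        cs = score_biodegradation(None, is_inorganic=True)
        assert cs.score == 1.0 and cs.basis is Basis.SURROGATE

    def test_missing_class_is_a_data_gap(self):
        with pytest.raises(ValueError, match="data gap"):
            score_biodegradation(None)


class TestBioaccumulation:
    @pytest.mark.parametrize(
        "bcf,expected",
        [(300, 0.25), (499.9, 0.25), (500, 0.5), (1999, 0.5), (2000, 0.75),
         (4999, 0.75), (5000, 1.0), (20000, 1.0)],
    )
    def test_bcf_bands(self, bcf, expected):
        cs = score_bioaccumulation(bcf, None)
        assert cs.score == expected and cs.basis is Basis.MEASURED

    def test_log_pow_surrogate(self):
        assert score_bioaccumulation(None, 5.1).score == 0.75
        assert score_bioaccumulation(None, 5.1).basis is Basis.SURROGATE
        assert score_bioaccumulation(None, 2.0).score == 0.25
        assert score_bioaccumulation(None, 5.1, worst_fill=True).score == 1.0

    def test_both_absent(self):
        with pytest.raises(ValueError, match="data gap"):
            score_bioaccumulation(None, None)


class TestToxicityBands:
    @pytest.mark.parametrize(
        "value,chapter,expected",
        [
            (150, Chapter.ACUTE_AQUATIC, 0.25),
            (100, Chapter.ACUTE_AQUATIC, 0.5),
            (0.05, Chapter.CHRONIC_AQUATIC, 1.0),
            (0.05, Chapter.ACUTE_AQUATIC, 1.25),  # one decade below the 1.0 band
            (1000, Chapter.TERRESTRIAL, 0.25),
            (10, Chapter.CHRONIC_AQUATIC, 0.25),
            (0.005, Chapter.CHRONIC_AQUATIC, 1.25),
            (0.5, Chapter.SEDIMENT, 1.25),
        ],
    )
    def test_band_examples(self, value, chapter, expected):
        assert score_toxicity(value, chapter).score == expected

    def test_no_effect_at_limit_scores_minimum(self):
        assert score_toxicity(80.0, Chapter.ACUTE_AQUATIC, no_effect_at_limit=True).score == 0.25

    def test_invalid_value(self):
        with pytest.raises(ValueError):
            score_toxicity(-1.0, Chapter.ACUTE_AQUATIC)
        with pytest.raises(ValueError):
            score_toxicity(None, Chapter.ACUTE_AQUATIC)

    def test_matches_band_oracle_on_random_drivers(self, rng):
        """1,000 log-uniform drivers per toxicity chapter against the literal
        band re-statement."""
        for chapter in (Chapter.ACUTE_AQUATIC, Chapter.CHRONIC_AQUATIC,
                        Chapter.SEDIMENT, Chapter.TERRESTRIAL):
            values = 10 ** rng.uniform(-4, 4, size=1000)
            for v in values:
                assert score_toxicity(float(v), chapter).score == oracle_band_score(v, chapter)

    def test_monotone_in_driver(self, rng):
        """More toxic (lower) driver values never lower the score."""
        for chapter in (Chapter.ACUTE_AQUATIC, Chapter.SEDIMENT):
            values = np.sort(10 ** rng.uniform(-4, 4, size=200))
            scores = [score_toxicity(float(v), chapter).score for v in values]
            assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_escalation_capped_at_1_25(self):
        assert score_toxicity(1e-9, Chapter.CHRONIC_AQUATIC).score == 1.25


def make_dossier(**kw):
    defaults = dict(name="X", biodegradation_class=None, records=[])
    defaults.update(kw)
    return SubstanceDossier(**defaults)


def tox_record(chapter, value, no_effect=False):
    return EndpointRecord(
        chapter=chapter, numeric_value=value, endpoint_label=f"NOEC {chapter.value}",
        quality_code=1, source=Source.STUDY, no_effect_at_limit=no_effect,
    )


class TestResolveChapter:
    def test_measured_settles_all_cases(self):
        d = make_dossier(records=[tox_record(Chapter.ACUTE_AQUATIC, 40.0)])
        scores = {c: resolve_chapter(d, Chapter.ACUTE_AQUATIC, c).score for c in Case}
        assert scores == {Case.BEST: 0.5, Case.REAL: 0.5, Case.WORST: 0.5}

    def test_missing_sediment_screened_benign(self):
        d = make_dossier(
            biodegradation_class=BiodegradationClass.READILY, log_pow=2.0
        )
        assert resolve_chapter(d, Chapter.SEDIMENT, Case.REAL).score == 0.25
        assert resolve_chapter(d, Chapter.SEDIMENT, Case.BEST).score == 0.25
        assert resolve_chapter(d, Chapter.SEDIMENT, Case.WORST).score == 1.25

    def test_missing_sediment_poorly_degradable_goes_worst(self):
        d = make_dossier(biodegradation_class=BiodegradationClass.POOR, log_pow=6.0)
        assert resolve_chapter(d, Chapter.SEDIMENT, Case.REAL).score == 1.25

    def test_high_log_koc_blocks_benign_screen(self):
        d = make_dossier(
            biodegradation_class=BiodegradationClass.READILY, log_pow=2.0, log_koc=4.5
        )
        assert resolve_chapter(d, Chapter.TERRESTRIAL, Case.REAL).score == 1.25

    def test_bioaccumulation_real_uses_log_pow(self):
        d = make_dossier(log_pow=5.1)
        assert resolve_chapter(d, Chapter.BIOACCUMULATION, Case.REAL).score == 0.75
        assert resolve_chapter(d, Chapter.BIOACCUMULATION, Case.WORST).score == 1.0

    def test_expert_judgement_overrides_real_fill(self):
        expert = EndpointRecord(
            chapter=Chapter.CHRONIC_AQUATIC, numeric_value=5.0,
            endpoint_label="expert NOEC", quality_code=2,
            source=Source.EXPERT_JUDGEMENT,
        )
        d = make_dossier(records=[expert], biodegradation_class=BiodegradationClass.POOR)
        assert resolve_chapter(d, Chapter.CHRONIC_AQUATIC, Case.REAL).score == 0.5
        # the fill override does not touch best/worst
        assert resolve_chapter(d, Chapter.CHRONIC_AQUATIC, Case.BEST).score == 0.25


class TestOverallAndTriple:
    def test_extremes_span_printed_range(self):
        best = make_dossier(
            biodegradation_class=BiodegradationClass.READILY,
            records=[tox_record(Chapter.BIOACCUMULATION, 100.0)]
            + [tox_record(ch, 1e6) for ch in
               (Chapter.ACUTE_AQUATIC, Chapter.CHRONIC_AQUATIC, Chapter.SEDIMENT,
                Chapter.TERRESTRIAL)],
        )
        worst = make_dossier(
            biodegradation_class=BiodegradationClass.POOR,
            records=[tox_record(Chapter.BIOACCUMULATION, 6000.0)]
            + [tox_record(ch, 1e-6) for ch in
               (Chapter.ACUTE_AQUATIC, Chapter.CHRONIC_AQUATIC, Chapter.SEDIMENT,
                Chapter.TERRESTRIAL)],
        )
        assert overall_score(best).overall == 1.5
        assert overall_score(worst).overall == 7.0

    def test_overall_equals_chapter_sum(self, rng):
        for d in random_dossiers(seed=7, n_substances=20, completeness=0.6).values():
            hs = overall_score(d, Case.REAL)
            assert hs.overall == pytest.approx(sum(c.score for c in hs.chapters.values()))
            assert 1.5 <= hs.overall <= 7.0

    def test_complete_dossier_collapses_triple(self, dossiers):
        t = hazard_triple(dossiers["EHT"])
        assert t.best.overall == t.real.overall == t.worst.overall == 3.0
        assert t.spread == 0

    def test_acute_only_dossier_fill(self):
        d = make_dossier(records=[tox_record(Chapter.ACUTE_AQUATIC, 150.0)])
        t = hazard_triple(d)
        assert t.best.overall == 1.5
        assert t.worst.overall == 0.25 + 1.0 + 1.0 + 1.25 + 1.25 + 1.25

    def test_case_ordering_fuzzed(self):
        for seed in range(5):
            for d in random_dossiers(seed=seed, n_substances=30, completeness=0.5).values():
                t = hazard_triple(d)
                assert t.best.overall <= t.real.overall <= t.worst.overall

    def test_adding_measured_chapter_never_widens_spread(self, rng):
        for d in random_dossiers(seed=11, n_substances=20, completeness=0.4).values():
            before = hazard_triple(d).spread
            missing = [
                ch for ch in (Chapter.ACUTE_AQUATIC, Chapter.CHRONIC_AQUATIC,
                              Chapter.SEDIMENT, Chapter.TERRESTRIAL)
                if not d.records_for(ch)
            ]
            if not missing:
                continue
            d.records.append(tox_record(missing[0], float(10 ** rng.uniform(-2, 3))))
            assert hazard_triple(d).spread <= before

    def test_all_scores_quarter_steps(self):
        for d in random_dossiers(seed=3, n_substances=20, completeness=0.7).values():
            for case in Case:
                for cs in overall_score(d, case).chapters.values():
                    assert (cs.score * 4) == int(cs.score * 4)
                    assert 0.25 <= cs.score <= chapter_max(cs.chapter)
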