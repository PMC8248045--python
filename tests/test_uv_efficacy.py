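"""<E11>, film transmission and the SPF / UVA-PF dose ratios."""

import numpy as np
import pytest

from ecosunpass.mixture import Formulation
from ecosunpass.uv_efficacy import (
    HOMOGENEOUS,
    WAVELENGTHS,
    FilmModel,
    FilterSpectrum,
    erythema_action_spectrum,
    gaussian_spectrum,
    mean_e11,
    ppd_action_spectrum,
    spf,
    transmission,
    uva_pf,
)


def flat_spectrum(e=400.0, name="FLAT", ps=1.0):
    return FilterSpectrum(name, WAVELENGTHS, np.full_like(WAVELENGTHS, e), ps)


class TestMeanE11:
    def test_constant(self):
        assert mean_e11(flat_spectrum(400.0)) == pytest.approx(400.0)

    def test_triangle_matches_analytic_area(self):
        # symmetric triangle peaking at 345 nm, height h, half-width 55 nm:
        # area = h*55, mean = h/2 on the 110 nm window
        h = 600.0
        e11 = np.maximum(0.0, h * (1 - np.abs(WAVELENGTHS - 345.0) / 55.0))
        s = FilterSpectrum("TRI", WAVELENGTHS, e11)
        assert mean_e11(s) == pytest.approx(h / 2, rel=1e-12)

    def test_gaussian_fixture_hits_target(self):
        s = gaussian_spectrum("BEMT", 527.0, [(310, 13, 1.0), (348, 15, 0.9)])
        assert mean_e11(s) == pytest.approx(527.0, rel=0.01)

    def test_grid_must_cover_uv_range(self):
        with pytest.raises(ValueError, match="cover"):
            FilterSpectrum("X", np.arange(300, 401.0), np.ones(101))


class TestTransmission:
    def test_no_filters_is_unity(self):
        f = Formulation("empty-ish", (("F", 1e-12),))
        t = transmission(f, {"F": flat_spectrum(0.0)}, HOMOGENEOUS)
        assert np.allclose(t, 1.0)

    def test_homogeneous_beer_lambert(self):
        # choose concentration so mean-film absorbance is exactly 1
        film = HOMOGENEOUS
        c = 1.0 / (400.0 * film.mean_path_cm)
        f = Formulation("f", (("F", c),))
        t = transmission(f, {"F": flat_spectrum(400.0)}, film)
        assert np.allclose(t, 0.1, rtol=1e-12)

    def test_two_step_direct_formula(self):
        film = FilmModel(model_kind="two_step", fractions=(0.5, 0.5), thicknesses=(0.0, 2.0))
        c = 1.0 / (400.0 * film.mean_path_cm)
        f = Formulation("f", (("F", c),))
        t = transmission(f, {"F": flat_spectrum(400.0)}, film)
        assert np.allclose(t, 0.5 + 0.5 * 1e-2, rtol=1e-12)

    def test_gamma_closed_form(self):
        film = FilmModel(model_kind="gamma", gamma_shape=2.0)
        c = 1.0 / (400.0 * film.mean_path_cm)
        f = Formulation("f", (("F", c),))
        t = transmission(f, {"F": flat_spectrum(400.0)}, film)
        expected = (1 + np.log(10) / 2) ** -2.0
        assert np.allclose(t, expected, rtol=1e-12)

    def test_gamma_matches_numeric_quadrature(self):
        from scipy import integrate, stats

        film = FilmModel(model_kind="gamma", gamma_shape=3.0)
        a = 1.7
        closed = film.transmit(np.array([a]))[0]
        pdf = stats.gamma(a=3.0, scale=1 / 3.0).pdf
        numeric, _ = integrate.quad(lambda h: pdf(h) * 10 ** (-a * h), 0, 60)
        assert closed == pytest.approx(numeric, rel=1e-8)

    def test_missing_spectrum_raises(self):
        f = Formulation("f", (("GHOST", 1.0),))
        with pytest.raises(KeyError, match="GHOST"):
            transmission(f, {})


class TestProtectionFactors:
    def test_transparent_film_spf_1(self):
        f = Formulation("f", (("F", 1e-12),))
        assert spf(f, {"F": flat_spectrum(0.0)}, HOMOGENEOUS) == pytest.approx(1.0)
        assert uva_pf(f, {"F": flat_spectrum(0.0)}, HOMOGENEOUS) == pytest.approx(1.0)

    def test_uniform_transmission_is_its_reciprocal(self):
        film = HOMOGENEOUS
        c = 1.0 / (400.0 * film.mean_path_cm)  # A == 1 -> T == 0.1
        f = Formulation("f", (("F", c),))
        assert spf(f, {"F": flat_spectrum(400.0)}, film) == pytest.approx(10.0, rel=1e-9)
        half = Formulation("f", (("F", c * np.log10(2)),))  # T == 0.5
        assert uva_pf(half, {"F": flat_spectrum(400.0)}, film) == pytest.approx(2.0, rel=1e-9)

    def test_homogeneous_flat_closed_form(self):
        """Flat spectrum + homogeneous film: SPF = 10^(E c d/d_ref) exactly."""
        film = HOMOGENEOUS
        for e, c in [(271.0, 7.0), (100.0, 3.0), (46.0, 10.0)]:
            f = Formulation("f", (("F", c),))
            expected = 10 ** (e * c * film.mean_path_cm)
            assert spf(f, {"F": flat_spectrum(e)}, film) == pytest.approx(expected, rel=1e-9)

    def test_uvb_only_filter_has_unit_uva_pf(self):
        e11 = np.where(WAVELENGTHS < 320, 500.0, 0.0)
        s = FilterSpectrum("UVB", WAVELENGTHS, e11)
        f = Formulation("f", (("UVB", 5.0),))
        assert uva_pf(f, {"UVB": s}, HOMOGENEOUS) == pytest.approx(1.0, rel=1e-12)

    def test_monotone_in_concentration(self, spectra):
        concs = [1.0, 2.0, 4.0, 8.0]
        values_spf = []
        values_uva = []
        for c in concs:
            f = Formulation("f", (("BEMT", c),))
            values_spf.append(spf(f, spectra))
            values_uva.append(uva_pf(f, spectra))
        assert all(a < b for a, b in zip(values_spf, values_spf[1:]))
        assert all(a < b for a, b in zip(values_uva, values_uva[1:]))

    def test_film_irregularity_penalty(self, spectra, formulations):
        """Uneven films transmit more (convexity), so the two-step SPF can
        never exceed the homogeneous Beer-Lambert limit."""
        for f in formulations.values():
            assert spf(f, spectra) <= spf(f, spectra, HOMOGENEOUS) + 1e-9

    def test_photostability_scales_like_concentration(self, formulations):
        base = {"F": flat_spectrum(300.0, ps=0.6)}
        equiv = {"F": flat_spectrum(300.0, ps=1.0)}
        f1 = Formulation("f", (("F", 5.0),))
        f2 = Formulation("f", (("F", 5.0 * 0.6),))
        assert spf(f1, base) == pytest.approx(spf(f2, equiv), rel=1e-12)

    def test_calibration_anchor_mid_teens(self):
        """The default two-step film puts a flat <E11>=271 mono-filter at
        7 wt% in the mid-teens SPF range."""
        f = Formulation("ref", (("F", 7.0),))
        value = spf(f, {"F": flat_spectrum(271.0)})
        assert 12 <= value <= 18

    def test_fine_grid_quadrature_agreement(self, spectra):
        """1 nm trapezoidal integration against a 0.1 nm refinement for an
        SPF-30-like composition."""
        f = Formulation("f", (("EHT", 2.5), ("BEMT", 2.5), ("PBSA", 2.0), ("DHHB", 4.0)))
        coarse = spf(f, spectra)
        fine_grid = np.arange(290.0, 400.0 + 0.1, 0.1)
        fine = spf(f, spectra, wavelengths=fine_grid)
        assert coarse == pytest.approx(fine, rel=0.15)


class TestActionSpectra:
    def test_erythema_piecewise_values(self):
        wl = np.array([290.0, 298.0, 308.0, 328.0, 360.0, 400.0])
        ser = erythema_action_spectrum(wl)
        assert ser[0] == 1.0 and ser[1] == 1.0
        assert ser[2] == pytest.approx(10 ** (0.094 * -10))
        assert ser[3] == pytest.approx(10 ** (0.094 * -30))
        assert ser[4] == pytest.approx(10 ** (0.015 * (140 - 360)))
        assert np.all(np.diff(ser) <= 0)

    def test_ppd_zero_below_uva(self):
        w = ppd_action_spectrum(WAVELENGTHS)
        assert np.all(w[WAVELENGTHS < 320] == 0)
        assert w[WAVELENGTHS == 320] == pytest.approx(1.0)


class TestFilmModelValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FilmModel(model_kind="two_step", fractions=(0.3, 0.3), thicknesses=(0, 1))

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            FilmModel(model_kind="porous")
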