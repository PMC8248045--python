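"""In-silico sun protection: <E11>, film transmission, SPF and UVA-PF.

A UV filter's efficacy is summarised by its specific extinction E11(lambda) —
the extinction of a 1 wt% preparation at 1 cm pathlength — averaged over
290-400 nm to give <E11>.  A formulation's protection factors are computed by
Beer-Lambert absorbance of the filter mixture through a model of the uneven
sunscreen film on skin, weighted by a solar source spectrum and the erythema
(SPF) or persistent-pigment-darkening (UVA-PF) action spectrum:

    SPF = sum S(l) ser(l) dl / sum S(l) ser(l) T(l) dl        (290-400 nm)

with the analogous UVA-PF over 320-400 nm.  Film irregularity matters: because
transmission is convex in local thickness, any uneven film transmits more than
the homogeneous film of equal mean thickness, which is why real sunscreens
underperform their Beer-Lambert limit.

The erythema action spectrum is the standard CIE piecewise-exponential form.
The PPD action spectrum and the midsummer midday solar spectrum shipped here
are smooth synthetic analytic stand-ins with the accepted qualitative shape
(PPD weight decaying across the UVA range; solar irradiance rising steeply
through the UVB and flattening in the UVA); they are not measured tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WAVELENGTHS",
    "FilterSpectrum",
    "FilmModel",
    "gaussian_spectrum",
    "mean_e11",
    "erythema_action_spectrum",
    "ppd_action_spectrum",
    "solar_source_spectrum",
    "absorbance",
    "transmission",
    "spf",
    "uva_pf",
]

UV_MIN, UV_MAX = 290.0, 400.0
UVA_MIN = 320.0
#: default wavelength grid: 290-400 nm at 1 nm
WAVELENGTHS = np.arange(UV_MIN, UV_MAX + 1.0, 1.0)

#: reference pathlength of the E11 definition (cm)
E11_REF_PATH_CM = 1.0
#: nominal product application (mg/cm^2); at unit density this maps to the
#: mean film thickness in cm via 1 mg/cm^2 = 1e-3 cm
DEFAULT_APPLICATION_MG_CM2 = 2.0


@dataclass(frozen=True)
class FilterSpectrum:
    """Specific extinction E11(lambda) of one UV filter on a wavelength grid.

    ``photostability_factor`` in (0, 1] scales the effective concentration to
    account for photodegradation losses (1.0 = photostable).
    """

    substance: str
    wavelengths: np.ndarray
    e11: np.ndarray
    photostability_factor: float = 1.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        e = np.asarray(self.e11, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "e11", e)
        if wl.shape != e.shape or wl.ndim != 1:
            raise ValueError(f"{self.substance}: wavelength/e11 shape mismatch")
        if not np.all(np.diff(wl) > 0):
            raise ValueError(f"{self.substance}: wavelength grid must strictly increase")
        if wl[0] > UV_MIN or wl[-1] < UV_MAX:
            raise ValueError(
                f"{self.substance}: spectrum must cover [{UV_MIN}, {UV_MAX}] nm, "
                f"got [{wl[0]}, {wl[-1]}]"
            )
        if np.any(e < 0):
            raise ValueError(f"{self.substance}: negative extinction")
        if not 0 < self.photostability_factor <= 1:
            raise ValueError(f"{self.substance}: photostability_factor must be in (0, 1]")

    def on_grid(self, grid: np.ndarray) -> np.ndarray:
        return np.interp(grid, self.wavelengths, self.e11)

    @property
    def mean_specific_extinction(self) -> float:
        return mean_e11(self)


def mean_e11(spectrum: FilterSpectrum) -> float:
    """<E11>: trapezoidal mean of E11 over 290-400 nm."""
    grid = WAVELENGTHS
    return float(np.trapezoid(spectrum.on_grid(grid), grid) / (UV_MAX - UV_MIN))


def gaussian_spectrum(
    substance: str,
    target_mean_e11: float,
    bands: list[tuple[float, float, float]],
    photostability_factor: float = 1.0,
    wavelengths: np.ndarray | None = None,
) -> FilterSpectrum:
    """Build a synthetic absorption spectrum from Gaussian bands.

    ``bands`` is a list of (center_nm, width_nm, relative_height); the summed
    profile is rescaled by a single factor so the trapezoidal mean over
    290-400 nm equals ``target_mean_e11`` exactly.
    """
    wl = WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, dtype=float)
    profile = np.zeros_like(wl)
    for center, width, height in bands:
        if width <= 0 or height <= 0:
            raise ValueError(f"{substance}: band width/height must be positive")
        profile += height * np.exp(-0.5 * ((wl - center) / width) ** 2)
    raw = FilterSpectrum(substance, wl, profile, photostability_factor)
    current = mean_e11(raw)
    if current <= 0:
        raise ValueError(f"{substance}: bands contribute nothing in 290-400 nm")
    return FilterSpectrum(
        substance, wl, profile * (target_mean_e11 / current), photostability_factor
    )


# --- film models -----------------------------------------------------------


@dataclass(frozen=True)
class FilmModel:
    """Distribution of local film thickness relative to the mean.

    * ``homogeneous`` — single thickness.
    * ``two_step`` — fractions ``f`` of the skin carry relative thicknesses
      ``h`` (an uncovered/thin fraction plus a thicker remainder is the classic
      minimal model of film irregularity).
    * ``gamma`` — local thickness Gamma-distributed with ``shape`` k and mean
      1; the transmission integral has the closed form (1 + A ln10 / k)^-k.

    ``application_mg_cm2`` sets the mean pathlength: at unit film density,
    2 mg/cm^2 is a 20 um film.
    """

    model_kind: str = "two_step"
    fractions: tuple[float, ...] = (0.07, 0.93)
    thicknesses: tuple[float, ...] = (0.0, 1.0 / 0.93)
    gamma_shape: float = 1.0
    application_mg_cm2: float = DEFAULT_APPLICATION_MG_CM2

    def __post_init__(self) -> None:
        if self.model_kind not in ("homogeneous", "two_step", "gamma"):
            raise ValueError(f"unknown film model {self.model_kind!r}")
        if self.model_kind == "two_step":
            f = np.asarray(self.fractions, float)
            h = np.asarray(self.thicknesses, float)
            if f.shape != h.shape:
                raise ValueError("fractions/thicknesses length mismatch")
            if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0) or np.any(h < 0):
                raise ValueError("step fractions must be >=0 and sum to 1; thicknesses >=0")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.application_mg_cm2 <= 0:
            raise ValueError("application must be positive")

    @property
    def mean_path_cm(self) -> float:
        # 1 mg/cm^2 of a unit-density film is 10 um = 1e-3 cm
        return self.application_mg_cm2 * 1e-3

    def transmit(self, absorbance: np.ndarray) -> np.ndarray:
        """Mean transmission through the thickness distribution for mean-film
        absorbance values (Beer-Lambert per thickness class)."""
        a = np.asarray(absorbance, dtype=float)
        if self.model_kind == "homogeneous":
            return 10.0 ** (-a)
        if self.model_kind == "two_step":
            f = np.asarray(self.fractions, float)
            h = np.asarray(self.thicknesses, float)
            return (f[:, None] * 10.0 ** (-np.outer(h, a))).sum(axis=0)
        k = self.gamma_shape
        # E[10^(-A h)] for h ~ Gamma(k, 1/k): MGF at t = -A ln 10
        return (1.0 + a * np.log(10.0) / k) ** (-k)


HOMOGENEOUS = FilmModel(model_kind="homogeneous")
DEFAULT_FILM = FilmModel()


# --- weighting spectra -----------------------------------------------------


def erythema_action_spectrum(wavelengths: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """CIE erythema action spectrum (piecewise log-linear, unity below 298 nm)."""
    wl = np.asarray(wavelengths, dtype=float)
    ser = np.ones_like(wl)
    mid = (wl > 298) & (wl <= 328)
    ser[mid] = 10.0 ** (0.094 * (298.0 - wl[mid]))
    hi = wl > 328
    ser[hi] = 10.0 ** (0.015 * (140.0 - wl[hi]))
    return ser


def ppd_action_spectrum(wavelengths: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Persistent-pigment-darkening action spectrum, 320-400 nm (synthetic).

    Smooth exponential decay across the UVA band, normalised to 1 at 320 nm
    and zero below 320 nm — a stand-in with the accepted qualitative shape,
    not a measured standard table.
    """
    wl = np.asarray(wavelengths, dtype=float)
    w = np.exp(-(wl - UVA_MIN) / 80.0)
    w[wl < UVA_MIN] = 0.0
    return w


def solar_source_spectrum(wavelengths: np.ndarray = WAVELENGTHS) -> np.ndarray:
    """Relative midday midsummer terrestrial solar irradiance (synthetic).

    Logistic rise through the ozone-filtered UVB edge flattening across the
    UVA, normalised to 1 at 400 nm; a qualitative stand-in for a measured
    reference spectrum.
    """
    wl = np.asarray(wavelengths, dtype=float)
    s = 1.0 / (1.0 + np.exp(-(wl - 308.0) / 4.0))
    return s / s.max()


# --- protection factors ----------------------------------------------------


def _resolve_components(
    formulation, spectra: dict[str, FilterSpectrum]
) -> list[tuple[str, float, FilterSpectrum]]:
    out = []
    for name, conc in formulation.components:
        if name not in spectra:
            raise KeyError(f"no UV spectrum for component {name!r}")
        out.append((name, conc, spectra[name]))
    return out


def absorbance(
    formulation,
    spectra: dict[str, FilterSpectrum],
    film: FilmModel = DEFAULT_FILM,
    wavelengths: np.ndarray = WAVELENGTHS,
) -> np.ndarray:
    """Mean-film absorbance A(lambda) = sum_k E11_k(l) c_k p_k d/d_ref."""
    a = np.zeros_like(np.asarray(wavelengths, dtype=float))
    scale = film.mean_path_cm / E11_REF_PATH_CM
    for _, conc, spec in _resolve_components(formulation, spectra):
        a += spec.on_grid(wavelengths) * conc * spec.photostability_factor * scale
    return a


def transmission(
    formulation,
    spectra: dict[str, FilterSpectrum],
    film: FilmModel = DEFAULT_FILM,
    wavelengths: np.ndarray = WAVELENGTHS,
) -> np.ndarray:
    """Film-averaged spectral transmission T(lambda) of the formulation."""
    return film.transmit(absorbance(formulation, spectra, film, wavelengths))


def _protection_factor(
    t: np.ndarray, source: np.ndarray, action: np.ndarray, wavelengths: np.ndarray
) -> float:
    w = source * action
    num = np.trapezoid(w, wavelengths)
    den = np.trapezoid(w * t, wavelengths)
    return float(num / den)


def spf(
    formulation,
    spectra: dict[str, FilterSpectrum],
    film: FilmModel = DEFAULT_FILM,
    wavelengths: np.ndarray = WAVELENGTHS,
    source: np.ndarray | None = None,
    action: np.ndarray | None = None,
) -> float:
    """Sun protection factor: erythema-weighted dose ratio over 290-400 nm."""
    wl = np.asarray(wavelengths, dtype=float)
    source = solar_source_spectrum(wl) if source is None else source
    action = erythema_action_spectrum(wl) if action is None else action
    t = transmission(formulation, spectra, film, wl)
    return _protection_factor(t, source, action, wl)


def uva_pf(
    formulation,
    spectra: dict[str, FilterSpectrum],
    film: FilmModel = DEFAULT_FILM,
    wavelengths: np.ndarray = WAVELENGTHS,
    source: np.ndarray | None = None,
    action: np.ndarray | None = None,
) -> float:
    """UVA protection factor: PPD-weighted dose ratio over 320-400 nm."""
    wl = np.asarray(wavelengths, dtype=float)
    source = solar_source_spectrum(wl) if source is None else source
    action = ppd_action_spectrum(wl) if action is None else action
    t = transmission(formulation, spectra, film, wl)
    mask = wl >= UVA_MIN
    return _protection_factor(t[mask], source[mask], action[mask], wl[mask])
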