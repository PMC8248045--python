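"""Run configuration: region profile, uncertainty case, thresholds, film model, paths."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hazard_scoring import OVERALL_MAX
from .mixture import ESP_THRESHOLD
from .uv_efficacy import DEFAULT_APPLICATION_MG_CM2, FilmModel

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    region_profile: str = "EU"
    case: str = "real"  # best | real | worst | all
    esp_threshold: float = ESP_THRESHOLD
    max_chapter_sum: float = OVERALL_MAX
    film_model: str = "two_step"
    film_fractions: tuple[float, ...] = (0.07, 0.93)
    film_thicknesses: tuple[float, ...] = (0.0, 1.0 / 0.93)
    film_gamma_shape: float = 1.0
    application_mg_cm2: float = DEFAULT_APPLICATION_MG_CM2
    dossier_master: str | None = None
    dossier_records: str | None = None
    spectra_dir: str | None = None
    formulations: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.esp_threshold <= 0:
            raise ValueError("esp_threshold must be positive")
        if self.case not in ("best", "real", "worst", "all"):
            raise ValueError(f"unknown case {self.case!r}")

    def film(self) -> FilmModel:
        return FilmModel(
            model_kind=self.film_model,
            fractions=tuple(self.film_fractions),
            thicknesses=tuple(self.film_thicknesses),
            gamma_shape=self.film_gamma_shape,
            application_mg_cm2=self.application_mg_cm2,
        )


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("film_fractions", "film_thicknesses"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return RunConfig(**doc)
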