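"""Formulation-level ecofriendliness ranking and the EcoSun Pass value.

Each UV filter's overall hazard score (1.5-7.0) is weighted by its
concentration in the product; the concentration-weighted sum is the
formulation's *ecorank*, and relating it to the theoretical maximum
(every filter at the worst score 7.0) gives the ecofriendliness percentage

    a = (1 - ecorank / max_ecorank) * 100.

Efficiency enters by multiplying a with the protection delivered per unit of
filter load:

    ESP = a * (SPF + UVA-PF) / c_total

where c_total is the summed UV-filter concentration in wt%.  A formulation is
ecofriendly when ESP exceeds 200 (strict).  Any component failing a regional
cut-off criterion zeroes the whole formulation's ESP.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cutoff import CutoffVerdict, RegionProfile, evaluate_cutoff
from .endpoint_data import SubstanceDossier
from .hazard_scoring import OVERALL_MAX, Case, HazardScore, overall_score

__all__ = [
    "Formulation",
    "EspResult",
    "ecorank",
    "ecofriendliness",
    "esp_value",
    "evaluate_formulation",
    "ESP_THRESHOLD",
]

#: ESP above which a formulation counts as ecofriendly (strict inequality).
ESP_THRESHOLD = 200.0


@dataclass(frozen=True)
class Formulation:
    """A named UV-filter composition: (substance, concentration wt%) pairs.

    Concentrations are of active matter; aqueous/dispersion trade forms must
    be entered at their active content.  The same substance may appear in
    several components (e.g. two trade forms); ranking is split-invariant.
    """

    name: str
    components: tuple[tuple[str, float], ...]
    spf_class: str = ""

    def __post_init__(self) -> None:
        comps = tuple((str(n), float(c)) for n, c in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError(f"{self.name}: formulation has no components")
        for n, c in comps:
            if c <= 0:
                raise ValueError(f"{self.name}: non-positive concentration for {n}")
        if self.total_concentration > 100:
            raise ValueError(f"{self.name}: total concentration exceeds 100 wt%")

    @property
    def total_concentration(self) -> float:
        return sum(c for _, c in self.components)


@dataclass(frozen=True)
class EspResult:
    formulation: str
    ecorank: float
    max_ecorank: float
    ecofriendliness_a: float
    spf: float
    uva_pf: float
    esp_value: float
    c_total: float
    cutoff_triggered: bool
    cutoff_verdicts: tuple[CutoffVerdict, ...] = ()
    case: Case = Case.REAL

    @property
    def ecofriendly(self) -> bool:
        return self.esp_value > ESP_THRESHOLD


def ecorank(
    formulation: Formulation,
    scores: dict[str, HazardScore],
    max_score: float = OVERALL_MAX,
) -> tuple[float, float]:
    """Concentration-weighted hazard sum and its theoretical maximum.

    max_ecorank assumes every component at the worst attainable overall score
    (7.0 by default), i.e. ``max_score * c_total``.
    """
    rank = 0.0
    for name, conc in formulation.components:
        if name not in scores:
            raise KeyError(f"{formulation.name}: no hazard score for component {name!r}")
        rank += scores[name].overall * conc
    return rank, max_score * formulation.total_concentration


def ecofriendliness(ecorank_value: float, max_ecorank: float) -> float:
    """Percentage a = (1 - ecorank/max_ecorank) * 100, in [0, 100]."""
    if max_ecorank <= 0:
        raise ValueError("max_ecorank must be positive (empty formulation?)")
    return (1.0 - ecorank_value / max_ecorank) * 100.0


def esp_value(
    a: float,
    spf: float,
    uva_pf: float,
    c_total: float,
    cutoff_triggered: bool = False,
) -> float:
    """EcoSun Pass value a*(SPF+UVA-PF)/c_total; zero under a cut-off."""
    if c_total <= 0:
        raise ValueError("total UV filter concentration must be positive")
    if cutoff_triggered:
        return 0.0
    return a * (spf + uva_pf) / c_total


def evaluate_formulation(
    formulation: Formulation,
    dossiers: dict[str, SubstanceDossier],
    region_profile: str | RegionProfile = "EU",
    case: Case = Case.REAL,
    spf: float = 1.0,
    uva_pf: float = 1.0,
) -> EspResult:
    """Full formulation assessment: cut-offs, ecorank, a, and the ESP value.

    ``spf``/``uva_pf`` are the simulated protection factors of the composition
    (see :mod:`ecosunpass.uv_efficacy`); one failing component zeroes the ESP
    but the hazard bookkeeping is still reported.
    """
    for name, _ in formulation.components:
        if name not in dossiers:
            raise KeyError(f"{formulation.name}: unresolved substance {name!r}")
    verdicts = tuple(
        evaluate_cutoff(dossiers[name], region_profile)
        for name in dict(formulation.components)
    )
    triggered = any(v.failed for v in verdicts)
    scores = {
        name: overall_score(dossiers[name], case)
        for name, _ in formulation.components
    }
    rank, max_rank = ecorank(formulation, scores)
    a = ecofriendliness(rank, max_rank)
    esp = esp_value(a, spf, uva_pf, formulation.total_concentration, triggered)
    return EspResult(
        formulation=formulation.name,
        ecorank=rank,
        max_ecorank=max_rank,
        ecofriendliness_a=a,
        spf=spf,
        uva_pf=uva_pf,
        esp_value=esp,
        c_total=formulation.total_concentration,
        cutoff_triggered=triggered,
        cutoff_verdicts=tuple(v for v in verdicts if v.failed),
        case=Case(case),
    )
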