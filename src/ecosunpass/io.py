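"""Plain-text I/O: dossiers, formulations, spectra, score and result tables.

All formats are auditable CSV/JSON/YAML with explicit unit columns.  A
substance dossier set is a pair of CSVs — a master table (one row per
substance) plus a records table (one row per endpoint) — or one JSON document
per substance.  Writing then reading any object reproduces it exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cutoff import RegionProfile
from .endpoint_data import (
    CHAPTER_UNITS,
    Chapter,
    BiodegradationClass,
    CutoffFlag,
    EndpointRecord,
    Source,
    SubstanceDossier,
)
from .hazard_scoring import HazardTriple
from .mixture import EspResult, Formulation
from .uv_efficacy import FilterSpectrum

__all__ = [
    "write_dossiers_csv",
    "read_dossiers_csv",
    "dossier_to_json",
    "dossier_from_json",
    "write_formulations_csv",
    "read_formulations_csv",
    "read_formulations_yaml",
    "write_spectrum",
    "read_spectrum",
    "triples_to_frame",
    "results_to_frame",
    "format_report",
    "read_region_profiles",
]

MASTER_COLUMNS = [
    "name", "inci_abbreviation", "is_inorganic", "log_pow", "log_koc",
    "biodegradation_class", "cutoff_flags", "mean_specific_extinction",
]
RECORD_COLUMNS = [
    "substance", "chapter", "value_kind", "numeric_value", "unit",
    "endpoint_label", "quality_code", "source", "no_effect_at_limit",
]


# --- dossiers --------------------------------------------------------------


def write_dossiers_csv(
    dossiers: dict[str, SubstanceDossier], master_path: str | Path, records_path: str | Path
) -> None:
    master_rows, record_rows = [], []
    for key, d in dossiers.items():
        master_rows.append(
            {
                "name": d.name,
                "inci_abbreviation": d.inci_abbreviation or key,
                "is_inorganic": d.is_inorganic,
                "log_pow": d.log_pow,
                "log_koc": d.log_koc,
                "biodegradation_class": d.biodegradation_class.value
                if d.biodegradation_class
                else "",
                "cutoff_flags": ";".join(sorted(f.value for f in d.cutoff_flags)),
                "mean_specific_extinction": d.mean_specific_extinction,
            }
        )
        for r in d.records:
            record_rows.append(
                {
                    "substance": d.inci_abbreviation or key,
                    "chapter": r.chapter.value,
                    "value_kind": r.value_kind,
                    "numeric_value": r.numeric_value,
                    "unit": CHAPTER_UNITS[r.chapter],
                    "endpoint_label": r.endpoint_label,
                    "quality_code": r.quality_code,
                    "source": r.source.value,
                    "no_effect_at_limit": r.no_effect_at_limit,
                }
            )
    pd.DataFrame(master_rows, columns=MASTER_COLUMNS).to_csv(master_path, index=False, float_format="%.17g")
    pd.DataFrame(record_rows, columns=RECORD_COLUMNS).to_csv(records_path, index=False, float_format="%.17g")


def _parse_record(row: pd.Series) -> EndpointRecord:
    chapter = Chapter(row["chapter"])
    expected = CHAPTER_UNITS[chapter]
    unit = str(row["unit"]).strip()
    if unit != expected:
        raise ValueError(
            f"{row['substance']}/{chapter.value}: unit {unit!r} rejected "
            f"(expected {expected!r})"
        )
    return EndpointRecord(
        chapter=chapter,
        numeric_value=float(row["numeric_value"]),
        endpoint_label=str(row["endpoint_label"]),
        quality_code=int(row["quality_code"]),
        source=Source(row["source"]),
        no_effect_at_limit=_as_bool(row.get("no_effect_at_limit", False)),
        value_kind=str(row.get("value_kind", "numeric")),
    )


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v) and not (isinstance(v, float) and np.isnan(v))


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, str) and not v.strip()):
        return None
    f = float(v)
    return None if np.isnan(f) else f


def read_dossiers_csv(
    master_path: str | Path, records_path: str | Path
) -> dict[str, SubstanceDossier]:
    master = pd.read_csv(master_path, float_precision="round_trip")
    if master.empty:
        raise ValueError(f"{master_path}: no substances")
    records = pd.read_csv(records_path, float_precision="round_trip") if Path(records_path).exists() else pd.DataFrame(
        columns=RECORD_COLUMNS
    )
    by_substance: dict[str, list[EndpointRecord]] = {}
    for _, row in records.iterrows():
        by_substance.setdefault(str(row["substance"]), []).append(_parse_record(row))
    out: dict[str, SubstanceDossier] = {}
    for _, row in master.iterrows():
        abbrev = str(row["inci_abbreviation"])
        cls = str(row.get("biodegradation_class", "") or "")
        if isinstance(row.get("biodegradation_class"), float):
            cls = ""
        flags = str(row.get("cutoff_flags", "") or "")
        if isinstance(row.get("cutoff_flags"), float):
            flags = ""
        out[abbrev] = SubstanceDossier(
            name=str(row["name"]),
            inci_abbreviation=abbrev,
            is_inorganic=_as_bool(row["is_inorganic"]),
            log_pow=_opt_float(row.get("log_pow")),
            log_koc=_opt_float(row.get("log_koc")),
            biodegradation_class=BiodegradationClass(cls) if cls else None,
            cutoff_flags=frozenset(
                CutoffFlag(f) for f in flags.split(";") if f
            ),
            records=by_substance.get(abbrev, []),
            mean_specific_extinction=_opt_float(row.get("mean_specific_extinction")),
        )
    return out


def dossier_to_json(dossier: SubstanceDossier) -> str:
    doc = {
        "name": dossier.name,
        "inci_abbreviation": dossier.inci_abbreviation,
        "is_inorganic": dossier.is_inorganic,
        "log_pow": dossier.log_pow,
        "log_koc": dossier.log_koc,
        "biodegradation_class": dossier.biodegradation_class.value
        if dossier.biodegradation_class
        else None,
        "cutoff_flags": sorted(f.value for f in dossier.cutoff_flags),
        "mean_specific_extinction": dossier.mean_specific_extinction,
        "records": [
            {
                "chapter": r.chapter.value,
                "value_kind": r.value_kind,
                "numeric_value": r.numeric_value,
                "unit": CHAPTER_UNITS[r.chapter],
                "endpoint_label": r.endpoint_label,
                "quality_code": r.quality_code,
                "source": r.source.value,
                "no_effect_at_limit": r.no_effect_at_limit,
            }
            for r in dossier.records
        ],
    }
    return json.dumps(doc, indent=2)


def dossier_from_json(text: str) -> SubstanceDossier:
    doc = json.loads(text)
    records = []
    for r in doc.get("records", []):
        chapter = Chapter(r["chapter"])
        if r.get("unit", CHAPTER_UNITS[chapter]) != CHAPTER_UNITS[chapter]:
            raise ValueError(
                f"{doc['name']}/{chapter.value}: unit {r['unit']!r} rejected"
            )
        records.append(
            EndpointRecord(
                chapter=chapter,
                numeric_value=r["numeric_value"],
                endpoint_label=r["endpoint_label"],
                quality_code=r["quality_code"],
                source=Source(r["source"]),
                no_effect_at_limit=r.get("no_effect_at_limit", False),
                value_kind=r.get("value_kind", "numeric"),
            )
        )
    return SubstanceDossier(
        name=doc["name"],
        inci_abbreviation=doc.get("inci_abbreviation", ""),
        is_inorganic=doc.get("is_inorganic", False),
        log_pow=doc.get("log_pow"),
        log_koc=doc.get("log_koc"),
        biodegradation_class=doc.get("biodegradation_class"),
        cutoff_flags=frozenset(CutoffFlag(f) for f in doc.get("cutoff_flags", [])),
        records=records,
        mean_specific_extinction=doc.get("mean_specific_extinction"),
    )


# --- formulations ----------------------------------------------------------


def write_formulations_csv(formulations: list[Formulation], path: str | Path) -> None:
    rows = [
        {
            "formulation": f.name,
            "substance": name,
            "concentration_wt_pct": conc,
            "spf_class": f.spf_class,
        }
        for f in formulations
        for name, conc in f.components
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_formulations_csv(path: str | Path) -> list[Formulation]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no formulation rows")
    out = []
    for name, group in df.groupby("formulation", sort=False):
        comps = tuple(
            (str(r["substance"]), float(r["concentration_wt_pct"]))
            for _, r in group.iterrows()
        )
        spf_class = str(group["spf_class"].iloc[0]) if "spf_class" in group else ""
        out.append(Formulation(str(name), comps, spf_class=spf_class))
    return out


def read_formulations_yaml(path: str | Path) -> list[Formulation]:
    doc = yaml.safe_load(Path(path).read_text())
    out = []
    for item in doc["formulations"]:
        comps = tuple((c["substance"], float(c["concentration_wt_pct"])) for c in item["components"])
        out.append(Formulation(item["name"], comps, spf_class=str(item.get("spf_class", ""))))
    return out


# --- spectra ---------------------------------------------------------------


def write_spectrum(spectrum: FilterSpectrum, path: str | Path) -> None:
    """Two-column table (wavelength_nm, e11); photostability in a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# substance: {spectrum.substance}\n")
        fh.write(f"# photostability_factor: {spectrum.photostability_factor!r}\n")
        fh.write("wavelength_nm,e11\n")
        for wl, e in zip(spectrum.wavelengths, spectrum.e11):
            fh.write(f"{float(wl)!r},{float(e)!r}\n")


def read_spectrum(path: str | Path) -> FilterSpectrum:
    substance, photostability = Path(path).stem, 1.0
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("# substance:"):
            substance = line.split(":", 1)[1].strip()
        elif line.startswith("# photostability_factor:"):
            photostability = float(line.split(":", 1)[1])
    data = pd.read_csv(path, comment="#", float_precision="round_trip")
    return FilterSpectrum(
        substance,
        data["wavelength_nm"].to_numpy(float),
        data["e11"].to_numpy(float),
        photostability,
    )


# --- result tables ---------------------------------------------------------


def triples_to_frame(triples: dict[str, HazardTriple]) -> pd.DataFrame:
    """Long-format chapter scores: substance, chapter, score, basis, case."""
    rows = []
    for key, t in triples.items():
        for score in (t.best, t.real, t.worst):
            for ch, cs in score.chapters.items():
                rows.append(
                    {
                        "substance": key,
                        "chapter": ch.value,
                        "score": cs.score,
                        "basis": cs.basis.value,
                        "case": score.case.value,
                    }
                )
            rows.append(
                {
                    "substance": key,
                    "chapter": "overall",
                    "score": score.overall,
                    "basis": "",
                    "case": score.case.value,
                }
            )
    return pd.DataFrame(rows)


def results_to_frame(results: list[EspResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "formulation": r.formulation,
                "c_total_wt_pct": r.c_total,
                "ecorank": r.ecorank,
                "max_ecorank": r.max_ecorank,
                "ecofriendliness_a": r.ecofriendliness_a,
                "spf": r.spf,
                "uva_pf": r.uva_pf,
                "esp_value": r.esp_value,
                "cutoff_triggered": r.cutoff_triggered,
                "ecofriendly": r.ecofriendly,
            }
            for r in results
        ]
    )


def format_report(results: list[EspResult]) -> str:
    """Human-readable one-row-per-formulation report."""
    lines = [
        f"{'formulation':<12} {'c_total':>8} {'SPF':>6} {'UVA-PF':>7} "
        f"{'a[%]':>7} {'ESP':>8}  verdict"
    ]
    for r in results:
        c_total = r.c_total
        verdict = "ecofriendly" if r.ecofriendly else "not ecofriendly"
        if r.cutoff_triggered:
            reasons = sorted({x for v in r.cutoff_verdicts for x in v.reasons})
            verdict += f" (cut-off: {', '.join(reasons)})"
        lines.append(
            f"{r.formulation:<12} {c_total:>8.1f} {r.spf:>6.1f} {r.uva_pf:>7.1f} "
            f"{r.ecofriendliness_a:>7.2f} {r.esp_value:>8.1f}  {verdict}"
        )
    return "\n".join(lines)


def read_region_profiles(path: str | Path) -> dict[str, RegionProfile]:
    """Load custom region profiles from YAML/JSON config."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    out = {}
    for item in doc["region_profiles"]:
        out[item["name"]] = RegionProfile(
            name=item["name"],
            ed_enabled=item.get("ed_enabled", True),
            pbt_enabled=item.get("pbt_enabled", True),
            vpvb_enabled=item.get("vpvb_enabled", True),
            acute_threshold_mg_l=item.get("acute_threshold_mg_l", 0.1),
            chronic_threshold_mg_l=item.get("chronic_threshold_mg_l", 0.01),
        )
    return out
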