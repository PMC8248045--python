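"""Score the bundled 24-filter set and print best/real/worst hazard triples.

Each UV filter is scored 0.25 (benign) to 1.0/1.25 (hazardous) on six
environmental chapters — biodegradation, bioaccumulation, acute and chronic
aquatic, sediment and terrestrial toxicity — and the chapter scores are
summed into an overall hazard score between 1.5 and 7.0.  Data gaps are
resolved as a best/real/worst triple; a wide best-worst range means the
assessment still rests on missing data.
"""

from ecosunpass import canonical_dossiers, hazard_triple

dossiers = canonical_dossiers(seed=0)
print(f"{'filter':<8} {'best':>5} {'real':>5} {'worst':>5}  spread")
for key in sorted(dossiers):
    t = hazard_triple(dossiers[key])
    print(
        f"{key:<8} {t.best.overall:>5.2f} {t.real.overall:>5.2f} "
        f"{t.worst.overall:>5.2f}  {t.spread:.2f}"
    )
print()
print("real = current evidence; best/worst = bounds if every data gap resolved")
print("favourably/unfavourably. Curated anchors: EHT 3.0, DBT 5.25, TiO2 2.75,")
print("ZnO 4.25 (fully measured, so their spread is 0).")
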