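"""Rank the nine worked sunscreen formulations by EcoSun Pass value.

For each composition: every filter's hazard score is weighted by its wt%
concentration (ecorank), converted to a %ecofriendliness
a = (1 - ecorank/max_ecorank)*100, and combined with simulated protection
factors into ESP = a*(SPF+UVA-PF)/c_total.  ESP > 200 means ecofriendly;
a formulation containing any filter that fails a cut-off criterion (here
octocrylene, chronically toxic to aquatic life) scores ESP = 0 outright.
"""

from ecosunpass import (
    canonical_dossiers,
    canonical_spectra,
    evaluate_formulation,
    example_formulations,
    spf,
    uva_pf,
)
from ecosunpass.io import format_report

dossiers = canonical_dossiers(seed=0)
spectra = canonical_spectra()

results = []
for form in example_formulations():
    s = spf(form, spectra)
    u = uva_pf(form, spectra)
    results.append(evaluate_formulation(form, dossiers, "EU", spf=s, uva_pf=u))

print(format_report(results))
print()
print("The two octocrylene-containing compositions (SPF30-1, SPF50-1) are")
print("zeroed by the chronic aquatic cut-off regardless of their efficacy.")
print("SPF/UVA-PF come from the bundled synthetic spectra and step-film model,")
print("so the ESP magnitudes are illustrative; the ranking logic is exact.")
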