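# ecosunpass

Environmental hazard scoring and ecofriendliness ranking of UV filters and
sunscreen formulations — an implementation of the EcoSun Pass (ESP) method
for cosmetic chemists, ecotoxicologists and formulators who want to compare
sunscreen compositions on a single, auditable environmental metric.

## The method

**Per-substance hazard score.** Every UV filter is assessed on six
environmental chapters — biodegradation, bioaccumulation, acute aquatic,
chronic aquatic, sediment and chronic terrestrial toxicity. Each chapter maps
its most sensitive reliable endpoint (Klimisch code 1–2) onto a 0.25-step
score: 0.25 (benign) up to 1.0 for the two fate chapters and up to 1.25 for
the toxicity chapters, where a driver one decade below the most hazardous
regular band (e.g. EC50 < 0.1 mg/L acute) escalates once by +0.25. The
overall score is the sum over the six chapters,

```
overall = Σ_chapters score_ch   ∈  [1.5, 7.0]
```

computed three ways: *real* (current evidence, with fate-property screening
for gaps), *best* and *worst* (gaps resolved at the chapter minimum /
maximum). The best–worst spread quantifies data-gap uncertainty.

**Cut-off criteria.** A filter that is an endocrine disruptor, PBT or vPvB,
or acutely (EC/LC50 < 0.1 mg/L) or chronically (NOEC/EC10 < 0.01 mg/L) toxic
to aquatic organisms is "not ecofriendly at all" — excluded from ranking
outright. Which criteria apply is a configurable regional profile (the EU
profile enables all five).

**Formulation ranking.** With c_k the wt% concentration of filter k:

```
ecorank     = Σ_k score_k · c_k          max-ecorank = 7.0 · Σ_k c_k
a           = (1 − ecorank/max-ecorank) · 100        (%ecofriendliness)
ESP         = a · (SPF + UVA-PF) / c_total
```

A formulation is **ecofriendly iff ESP > 200** (strict); any component
failing a cut-off zeroes its ESP.

**UV efficacy.** SPF and UVA-PF are simulated from each filter's specific
extinction spectrum E11(λ) (extinction of a 1 wt% preparation at 1 cm;
its 290–400 nm mean is ⟨E11⟩) via Beer–Lambert transmission through a
two-step film model of the irregular sunscreen layer, weighted by the CIE
erythema action spectrum (SPF, 290–400 nm) or a PPD action spectrum
(UVA-PF, 320–400 nm).

## Worked example

```bash
python examples/rank_formulations.py
```

prints, for the nine bundled worked compositions (abridged):

```
formulation   c_total    SPF  UVA-PF    a[%]      ESP  verdict
SPF30-1          28.0   14.2    12.0   34.57      0.0  not ecofriendly (cut-off: chronic_lt_0.01)
SPF30-4          11.0   14.2     9.4   42.53     91.2  not ecofriendly
SPF50-1          24.0   14.3    12.9   36.16      0.0  not ecofriendly (cut-off: chronic_lt_0.01)
SPF50-4          13.5   14.2    11.0   38.10     71.3  not ecofriendly
```

Reading: `a` is the hazard-only ecofriendliness of the filter system (100 =
every filter at the best possible score); ESP folds in protection per unit
filter load. The two octocrylene-containing rows are zeroed by the chronic
aquatic cut-off irrespective of their efficacy. SPF/UVA-PF here come from the
bundled *synthetic* spectra and film calibration, so ESP magnitudes are
illustrative — the scoring, cut-off and ranking arithmetic is exact.

Other entry points: `examples/score_uv_filters.py` (hazard triples for the
24-filter registry), `examples/simulate_spf.py` (film-model behaviour), and a
CLI (`ecosunpass score|esp|spf|fixtures --help`) for file-based workflows.

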