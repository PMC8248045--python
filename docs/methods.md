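# Methods

## Scope and model

`ecosunpass` scores the environmental hazard of individual UV filters across
six compartments, applies regulatory exclusion (cut-off) criteria, aggregates
concentration-weighted scores over a sunscreen formulation, and folds in
simulated UV efficacy to a single EcoSun Pass (ESP) value with a pass/fail
threshold. The package computes with user-supplied (or bundled synthetic)
substance dossiers; it performs no QSAR estimation and holds no connection to
regulatory databases — QSAR values and ED/PBT/vPvB conclusions enter as
tagged inputs.

## Evidence handling

An endpoint record carries a chapter, a numeric driver (mg/L for aquatic
endpoints, mg/kg dry weight for sediment/soil, dimensionless BCF), a Klimisch
reliability code and a source tag. Choices made where regulatory practice,
not the method definition, had to settle the rule:

- **Reliability.** Klimisch codes 1–2 are accepted, 3–4 rejected — the
  conventional "reliable" set.
- **Driver selection.** Within a chapter the *most sensitive* (lowest-value)
  reliable endpoint drives the score. Ties break by source priority
  (study > authority > literature > QSAR > expert judgement), then endpoint
  label, making the result independent of record order.
- **QSAR admission.** QSAR records are rejected at load time (with a warning)
  for chronic aquatic and terrestrial toxicity, where structure-based
  estimates are too uncertain; they are accepted for bioaccumulation and the
  log Pow surrogate route.
- **Expert judgement.** Expert-judgement records act as real-case fill
  overrides only: they never count as measured evidence and therefore never
  narrow the best–worst uncertainty range.
- **No-effect tests.** A test showing no effects up to the highest tested
  concentration (or the solubility limit) earns the chapter minimum 0.25;
  the flag lives on the record.

## Scoring bands

Fate chapters: biodegradation readily/biodegradable/partly/poor →
0.25/0.5/0.75/1.0; inorganic filters do not degrade and take 1.0 on a
surrogate basis. Bioaccumulation by BCF: <500 → 0.25, [500, 2000) → 0.5,
[2000, 5000) → 0.75, ≥5000 → 1.0; without a BCF, log Pow ≥ 4.5 marks the
substance bioaccumulative (0.75 real case; the worst case is the generic
1.0 fill), < 4.5 not bioaccumulative (0.25).

Toxicity chapters (driver EC50 acute; NOEC/EC10 otherwise):

| score | acute aquatic (mg/L) | chronic aquatic (mg/L) | sediment & soil (mg/kg dw) |
|------:|---------------------|------------------------|----------------------------|
| 0.25  | > 100 (or no effect) | ≥ 10                  | ≥ 1000                     |
| 0.5   | [10, 100]            | [1, 10)               | [100, 1000)                |
| 0.75  | [1, 10)              | [0.1, 1)              | [10, 100)                  |
| 1.0   | [0.1, 1)             | [0.01, 0.1)           | [1, 10)                    |
| 1.25  | < 0.1                | < 0.01                | < 1                        |

Band edges follow each chapter's printed convention (acute's top band is
strict `> 100`, the others' top bands include their edge); interior edges are
lower-bound-inclusive so that ties resolve to the hazard-conservative side.
The +0.25 escalation — a driver one decade below the 1.0 band — applies once
and caps at 1.25; the overall range [1.5, 7.0] (2·1.0 + 4·1.25) forces that
cap.

## Data-gap resolution (best/real/worst)

A measured chapter settles all three cases identically. For gaps: *best*
fills 0.25, *worst* fills the chapter maximum (1.0 fate / 1.25 toxicity) —
unconditionally, since new data can always land in the worst band. The *real*
case uses screening where practice supports it: a readily biodegradable
substance with log Pow < 4.5 and log Koc < 3.0 (or absent) is not expected to
reach sediment or soil, so those chapters fill at 0.25; otherwise they take
the worst-case fill. The log Koc trigger of 3.0 is a conventional screening
value and is configurable (`hazard_scoring.LOG_KOC_ADSORPTION_THRESHOLD`).
Real-case fills for the remaining chapters default to the worst case —
deliberately conservative — overridable per dossier by an explicit
expert-judgement record. Consequences verified by tests: best ≤ real ≤ worst
always, and the spread is zero exactly when every chapter is measured.

## Cut-off criteria

ED, PBT and vPvB are input flags; the aquatic criteria (acute < 0.1 mg/L,
chronic < 0.01 mg/L, both strict) are re-derived from the reliable drivers.
Values exactly at a threshold pass. Region profiles toggle ED/PBT/vPvB and
move the thresholds; the shipped `EU` profile enables everything. Because the
thresholds sit one decade below the 1.0-band floors, a cut-off-failing driver
always also carries the escalated 1.25 chapter score.

## Formulation ranking

ecorank = Σ score·c over components; max-ecorank is defined as 7.0 (the
theoretical chapter-sum maximum, configurable) times total concentration —
this makes a = (1 − ecorank/max-ecorank)·100 a composition-independent
baseline that reaches 0 only for uniformly worst filters. ESP =
a·(SPF+UVA-PF)/c_total, with ESP > 200 (strict) as the ecofriendliness
verdict. One failing component zeroes the whole formulation's ESP; the
hazard bookkeeping is still reported. Concentrations are active-matter wt%;
trade forms (aqueous dispersions) must be entered at active content, and the
ranking is invariant to splitting a substance across components. The default
ranking case is *real*; the CLI can compute all three for an ESP range.

## UV efficacy model

E11(λ) is the specific extinction of a 1 wt% preparation at 1 cm; ⟨E11⟩ its
trapezoidal mean over 290–400 nm. Mean-film absorbance is
A(λ) = Σ_k E11_k(λ)·c_k·p_k·(d/d_ref) with p_k a static photostability
factor (default 1.0; dynamic photodegradation is out of scope) and d the
mean film thickness from the application dose (default 2.0 mg/cm², i.e.
20 µm at unit density against the 1 cm reference path).

Film models: homogeneous (T = 10^−A), two-step (T = Σ f_j·10^(−A·h_j), step
fractions f summing to 1, relative thicknesses h), and a Gamma-thickness
closed form (1 + A ln10/k)^−k. The default two-step parameters — 7 % of the
area effectively uncovered (h = 0), the rest at h = 1/0.93 — were calibrated
once so a flat-spectrum mono-filter reference with ⟨E11⟩ = 271 at 7 wt%
lands in the mid-teens SPF, a realistic in-use value; they live in
`config.RunConfig`, not in the model code. Because transmission is convex in
thickness, any irregular film transmits more than the homogeneous film of
equal mean thickness (Jensen), which the tests assert.

SPF is the source×erythema-weighted dose ratio over 290–400 nm on a 1 nm
trapezoidal grid; UVA-PF the source×PPD-weighted ratio over 320–400 nm. The
erythema action spectrum is the standard CIE piecewise-exponential closed
form. The PPD action spectrum (exponential decay across the UVA, scale
80 nm) and the solar source (logistic rise centred at 308 nm, width 4 nm)
are smooth **synthetic stand-ins** with the accepted qualitative shapes, not
measured standard tables; absolute SPF/UVA-PF values therefore carry no
metrological meaning and published protection values are not reproduced —
only ratios, monotonicity, closed-form limits and model orderings are
asserted.

## Synthetic data

No per-filter regulatory dossiers are published, so the bundled 24-filter
set is synthetic. Five filters are curated to their published anchors:
overall real-case scores 3.0 (EHT), 5.25 (DBT), 2.75 (TiO2), 4.25 (ZnO), and
octocrylene with a chronic aquatic NOEC of 0.005 mg/L that triggers the
cut-off — the chapter-level breakdowns behind those sums were never
published; the ones here are one consistent choice. The remaining 19
dossiers are drawn reproducibly from the seed with chapter completeness 0.8
(a data-rich but not complete registry, matching a set where most chapters
support conclusions); their aquatic drivers stay above the cut-off
thresholds so that, as in the study set, exactly one filter fails. Filter
spectra are 1–3 Gaussian bands with plausible UVB/UVA placement, rescaled so
the 290–400 nm mean equals the registry ⟨E11⟩ exactly. The generator does
not emulate inter-endpoint correlations, congener-specific band structure,
or literature heterogeneity — passing tests show the scoring/ranking
machinery is correct, not that real dossiers would reproduce any particular
published score.

## Numerical and degenerate-input choices

All scores are exact multiples of 0.25 (no floating-point accumulation
issues at these magnitudes; the chapter sum of six quarter-steps is exact in
binary). Empty formulations, non-positive concentrations or totals over
100 wt% are rejected at construction; an unresolved substance names the
offending component. CSV writers use 17-significant-digit floats and readers
round-trip parsing, so write→read reproduces objects bit-exactly. One
published worked-example total is inconsistent with its own printed
component list; the component list is authoritative throughout.

## Known limitations

- Absolute SPF/UVA-PF (and hence ESP magnitudes) depend on spectra and a
  film/photostability parameterisation that were never published; this
  package's values are internally consistent but not comparable to printed
  protection factors.
- Co-formulants (emollients, thickeners, preservatives) are outside the
  ranking — by design, as they do not discriminate between formulations.
- The ED/PBT/vPvB conclusions are inputs; the package does not assess them.
- Real-case fills for non-sediment chapters are conservative (worst-case)
  unless an expert-judgement record says otherwise.
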