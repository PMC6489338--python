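# Methods

## The model

`aquarisk` implements a screening-level cumulative risk assessment for
drinking-water contaminants in community water systems, combining two
complementary metrics.

**Additive lifetime cancer risk.** Each carcinogen *i* is characterised by
its one-in-a-million concentration `C⁶ᵢ` — the concentration that, over a
lifetime of exposure, yields a 10⁻⁶ excess cancer risk. A system's
per-contaminant risk at arithmetic-mean concentration `cᵢ` is

    rᵢ = (cᵢ / C⁶ᵢ) × 10⁻⁶

and the cumulative risk is the plain sum `R = Σᵢ rᵢ`, capped at 1. The
additive form is the one used by the EPA National Air Toxics Assessment: it
assumes no chemical interactions (neither synergistic nor antagonistic)
and independent, linear low-dose dose–response for every carcinogen. It is
a burden characterisation, not a precise individual probability. Expected
lifetime cases for a system are `R × population served`; a statewide total
is annualised by dividing by the typical lifetime (default 70 years,
configurable on the registry).

Systems are binned into four risk tiers with upper-inclusive boundaries —
`>1e-3`, `(1e-4, 1e-3]`, `(1e-5, 1e-4]`, `≤1e-5` — so a risk of exactly
10⁻³ falls in the second tier; the published convention reports the top
tier strictly as "> 10⁻³" and does not state the boundary rule, so the
upper-inclusive reading is a declared choice, centralised in
`cancer.classify_tier`. Group contributions attribute each system's cases
proportionally to per-contaminant risk (exact whenever the probability cap
is inactive, which holds for all realistic inputs).

**Relative Health Indicator (RHI).** The RHI puts cancer and non-cancer
endpoints on one severity-weighted scale:

    cancer score     = r × SF_cancer × K
    non-cancer score = HQ × SF × IF × K

where `HQ = c / reference_conc` is the hazard quotient, `SF` is a Global
Burden of Disease disability weight in [0, 1] for the contaminant's
critical health effect, `IF` is the incidence factor (the assumed fraction
of the exposed population experiencing that effect, default 1%), and
`K = 10⁶` is a display scale chosen so that a 10⁻⁶ risk with severity 1
scores 1. No incidence factor applies to the cancer score: the lifetime
risk already is an outcome probability, so the cancer score is invariant
under the non-cancer sensitivity parameters. Contaminants with both
endpoint types (arsenic, hexavalent chromium) contribute to both sums.
Scores rank water-quality scenarios; they are not disease probabilities.

## Benchmark calibration

The arsenic constants are pinned jointly by the standard worked example —
1 μg/L ⇒ lifetime risk 2.5×10⁻⁴ ⇒ cancer score 180 — and the 3×3
sensitivity grid spanning cumulative scores 276–2169:

* `C⁶ = 10⁻⁶ / 2.5×10⁻⁴ = 0.004 μg/L`
* `SF_cancer = 180 / (2.5×10⁻⁴ × 10⁶) = 0.72`
* `reference_conc = 0.179 × 0.01 × 10⁶ / (2169 − 180) ≈ 0.9 μg/L`

The system is over-determined: with these three constants the formulas
also reproduce the grid's non-cancer-fraction range 35–92% and the 72%
non-cancer share at severity 0.041 / incidence 1%, all after
nearest-integer (scores) and nearest-percent (fractions) rounding — the
reporting convention used throughout. `tests/test_rhi.py` re-derives the
constants by independent algebraic inversion and checks all seven
quantities.

Two numerical details worth stating. First, the two epidemiology-derived
incidence factors come from cardiovascular mortality rates of 214 and 271
per 100,000 person-years; the grid uses them as the *reported* two-decimal
percents (0.21% → 0.0021, 0.27% → 0.0027), since the raw quotients
(0.00214, 0.00271) would shift the grid minimum from 276 to 277. Second,
arsenic's three non-cancer severity options 0.041 / 0.072 / 0.179 are the
GBD mild/moderate/severe heart-failure disability weights; the first
(most conservative) option is the default for distribution runs.

Every benchmark for contaminants other than arsenic — the nine
carcinogenic disinfection byproducts, hexavalent chromium, uranium,
tetrachloroethylene, and the non-cancer set chlorate, manganese, nitrate
and vanadium — is a **placeholder** loosely informed by California public
health goals and notification levels, shipped so the pipeline runs
end-to-end. Real analyses should load a vetted registry via
`load_registry`; units (μg/L for chemicals, pCi/L for radionuclides) are
declared per contaminant and never converted implicitly.

## Non-detect handling

Monitoring records below the reporting limit arrive with no numeric value.
Aggregation to per-system arithmetic means imputes them under a stated
policy: `zero` (default), `half_limit`, or `full_limit`. Zero substitution
matches the framing of the published estimates as conservative lower
bounds — for several common carcinogens the 10⁻⁶ concentration lies below
the official reporting limit, so censored mass may still carry risk. The
three policies are ordered (`zero ≤ half_limit ≤ full_limit` per mean) and
coincide on fully detected data; the alternatives exist for sensitivity
work, not as a censored-data estimator (no MLE or Kaplan–Meier-style
imputation is attempted). All samples in the input window are pooled with
equal weight, with no per-sampling-point pre-averaging or time weighting.

## Synthetic data

`synthetic.generate` emulates the structure the analysis assumes, not any
specific state's data: lognormal population served (default median 1,000,
log-sd 1.8 — many small systems, few large ones), independent Bernoulli
occurrence per contaminant (default 0.5), lognormal sample concentrations,
and left-censoring applied at generation time (the draw is discarded, the
limit kept — mirroring how utilities report). Default carcinogen medians
sit at 100 × C⁶ (per-contaminant risk ≈ 10⁻⁴, the bulk of the observed
distribution) and non-cancer medians at reference/5; reporting limits
equal the medians so roughly half of the draws are censored and the
non-detect machinery is always exercised. Systems under 10,000 people get
their concentration medians multiplied by 3 by default, which reproduces
the qualitative pattern that the highest cumulative risks concentrate in
small systems (negative population–risk rank correlation).

Deliberately **not** emulated: joint contaminant correlations, temporal
trends, spatial clustering, and source-water chemistry. Passing tests on
synthetic data therefore validate the arithmetic, conservation and
censoring behaviour of the pipeline — not the statewide numeric totals,
which depend on the real monitoring datasets.

`generate_tiered_scenario` back-solves single-carcinogen concentrations
from risks sampled log-uniformly strictly inside requested tier bounds, so
tier-table counts match targets exactly by construction; it exists for
round-trip testing of the classifier and reporting chain.

Test and acceptance runs use scaled-down problem sizes chosen for tight
Monte-Carlo checks at negligible cost: 10⁴ draws for the censoring-rate
comparison against the lognormal CDF (3 standard-error band), 40–200
systems for pipeline properties, and a handful of seeds for the
rank-correlation sign check.

## Known limitations

* Additivity ignores interaction; the true cumulative risk may differ in
  either direction.
* The constant incidence factor contradicts dose–response ("the dose makes
  the poison") and is the dominant RHI uncertainty — hence the sensitivity
  grid as a first-class output.
* Placeholder benchmarks (above) make the default registry suitable for
  method validation and illustration only.
* Population served is a static head count; no demographic weighting or
  exposure-duration modelling.
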