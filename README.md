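# aquarisk

Cumulative risk assessment for drinking-water contaminants in community
water systems — for environmental-health researchers and water-quality
analysts who need screening-level, population-scale answers from routine
monitoring data.

Regulatory practice evaluates each tap-water contaminant against its own
standard, one at a time. Real water contains mixtures. `aquarisk`
implements two metrics that treat co-occurring contaminants jointly:

* **Additive cumulative lifetime cancer risk.** Each carcinogen's risk at
  mean concentration *c* is `r = (c / C⁶) × 10⁻⁶`, where `C⁶` is its
  one-in-a-million concentration; a system's cumulative risk is `R = Σ r`,
  and expected lifetime cancer cases are `R × population served`. Systems
  are binned into risk tiers (`>10⁻³`, `10⁻⁴–10⁻³`, `10⁻⁵–10⁻⁴`, `<10⁻⁵`)
  with case counts, exposed population and per-group contributions, and
  statewide totals are annualised over a 70-year lifetime.
* **Relative Health Indicator (RHI) scores.** Cancer and non-cancer
  endpoints on one severity-weighted scale:
  `cancer = r × SF × 10⁶` and `non-cancer = HQ × SF × IF × 10⁶`, where
  `HQ = c / reference concentration` is the hazard quotient, `SF` a Global
  Burden of Disease disability weight, and `IF` the incidence factor
  (default 1%). A severity × incidence sensitivity grid brackets the score
  under parameter uncertainty.

The pipeline: a benchmark **registry** (YAML, shipped defaults calibrated
to the standard arsenic worked example) → monitoring-record **ingestion**
with explicit non-detect policies (`zero` default, `half_limit`,
`full_limit`) → per-system arithmetic-mean profiles → **cancer-risk** and
**rhi** scoring → delimited-text tables with a run manifest. A seeded
**synthetic-data generator** (lognormal populations and concentrations,
left-censoring at reporting limits, elevated medians in small systems)
makes every stage testable without the real regulatory datasets. See
`docs/methods.md` for assumptions, calibration and limitations.

## Worked example

Arsenic at 1 μg/L is the canonical single-contaminant case: lifetime
cancer risk 2.5×10⁻⁴ and cancer RHI score 180 with the built-in registry.
The sensitivity grid over three severity factors and three incidence
factors:

```
$ aquarisk sensitivity arsenic --conc 1.0 --out-dir sens
 severity  incidence  cancer_score  noncancer_score  total_score  noncancer_percent
    0.041     0.0021           180               96          276                 35
    0.041     0.0027           180              123          303                 41
    0.041     0.0100           180              456          636                 72
    0.072     0.0021           180              168          348                 48
    0.072     0.0027           180              216          396                 55
    0.072     0.0100           180              800          980                 82
    0.179     0.0021           180              418          598                 70
    0.179     0.0027           180              537          717                 75
    0.179     0.0100           180             1989         2169                 92
min 276, max 2169
```

The cancer score is constant — it depends only on the concentration and
the published risk benchmark — while the cumulative score spans 276–2169
and the non-cancer share spans 35–92%, which is why the incidence factor
is the model's dominant uncertainty. At the defaults used for
distribution runs (severity 0.041, incidence 1%), non-cancer effects make
up 72% of arsenic's cumulative score of 636.

The full pipeline on synthetic data:

```
$ aquarisk simulate --n-systems 50 --seed 7 --out-dir sim
wrote 1680 records for 50 systems to sim
$ aquarisk cancer-risk sim/records.csv sim/populations.csv --out-dir risk
50 systems; 279.2 expected lifetime cases; 4 annual cases over a 70-year lifetime
```

which writes `tier_table.csv`, `per_system_risk.csv`,
`group_contributions.csv`, `summary.json` and a `manifest.json` tracing
the run. `aquarisk rhi` produces the analogous score tables.

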