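# hhseg

Household-level segmentation of linked health and social-care records:
a case-finding pipeline for households with children who have complex
cross-sectoral needs.

The pipeline derives analysis households from pseudonymised address
identifiers, evaluates a four-criterion rule set on each household with
children, attaches cost-weighted utilisation, and produces descriptive
profiling and an unmet-need contrast:

1. **Adult comorbidity** — at least one adult with a physical long-term
   condition and at least one adult (possibly a different one) with a
   mental health condition.
2. **Child problem** — at least one child (0–16) with a health/social
   problem code or an in-care marker.
3. **Social vulnerability** — any of: homelessness, frequent A&E use
   (>5 attendances/year for any member), substance abuse, lone
   parenthood, a child in care, living in the most deprived 20% of
   addresses, or use of ≥3 distinct care sectors.
4. **High spend** — per-capita cost-weighted utilisation in the top
   quartile of households with children (nearest-rank, ties included).

A household is in the segment only when all four hold simultaneously.
Because real linked records are not distributable, a synthetic
generator (`hhseg.synthetic_data`) emits person/condition/contact tables
with household clustering, mental–physical comorbidity coupling,
sector-specific contact rates and *planted* segment membership, so every
stage can be tested against ground truth.

## Command line

```bash
# generate a synthetic linked population (persons/conditions/contacts/truth)
hhseg simulate --config cfg.yaml --out data/ --seed 7

# evaluate the four criteria -> one row per household with children
hhseg segment --persons data/persons.csv --conditions data/conditions.csv \
              --contacts data/contacts.csv --config cfg.yaml --out segments.csv

# descriptive profiling tables (criteria table, prevalence, cost shares,
# service intersections, mental-health breakdowns)
hhseg profile --persons ... --conditions ... --contacts ... --out report/

# stratified emergency mental-health odds ratios
hhseg unmet-need --persons ... --conditions ... --contacts ... --out strata.csv

# everything end to end, reproducibly
hhseg all --config cfg.yaml --seed 7 --out run/
```

Every stage writes a `manifest.json` with input digests, exclusion
counts (people without an address link, oversize address groups) and
timings. Identical inputs, config and seed produce byte-identical CSV
outputs.

### Configuration

`cfg.yaml` is optional everywhere; absent keys fall back to shipped
defaults. The main blocks:

```yaml
physical_conditions: [asthma, diabetes, ...]    # condition taxonomy
mental_conditions: [anxiety, depression, ...]
vulnerability_codes:
  homelessness: [homelessness]
  substance_abuse: [substance_abuse]
  child_in_care: [child_in_care]
tariffs:                 # unit cost per sector (row-level overrides win)
  primary_care: 40.0
  ae: 180.0
  # ... all eight sectors
thresholds:
  ae_visits_per_year: 5       # flag is strictly greater than
  distinct_services_min: 3
  spend_quantile: 0.75
  deprivation_quantile: 0.20
  child_age_max: 16
  max_household_size: 10
synthetic:               # used by `simulate` / `all`
  n_households: 2000
  planted_complex_fraction: 0.08
```

## Layout

- `src/hhseg/io_config.py` — table schemas, validation, run configuration
- `src/hhseg/synthetic_data.py` — seeded generator with planted truth
- `src/hhseg/household_builder.py` — address groups → households, cohort
- `src/hhseg/segmentation.py` — the four-criterion rule set
- `src/hhseg/cost_model.py` — tariffs → person/household/per-capita cost
- `src/hhseg/profiling.py` — criteria/prevalence/intersection reports
- `src/hhseg/unmet_need.py` — stratified 2×2 odds ratios, dual-path checked
- `src/hhseg/cli.py` — the `hhseg` command
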