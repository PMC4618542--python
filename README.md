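# mrruf

Analysis of **mortality-related resource utilization** in inpatient care of
hypoplastic left heart syndrome (HLHS), the severe congenital heart defect
managed by staged surgical palliation (Norwood → Glenn → Fontan).
Intended for outcomes researchers working with hospital administrative
claims: admission-level records carrying institution, year, age, length of
stay (LOS), billed charges (BC) and discharge status.

## The statistic

The **mortality-related resource utilization fraction (MRRUF)** asks how
much of the total inpatient investment is expended during hospitalizations
that end in inpatient death:

```
MRRUF_LOS = Σ LOS over admissions ending in death / Σ LOS over all admissions
MRRUF_BC  = Σ BC  over admissions ending in death / Σ BC  over all admissions
```

As a ratio of like-denominated sums it is immune to inflation and to
charge-to-cost conversion error, and it obeys a pooling identity: for any
partition of a cohort into strata, the whole-cohort MRRUF equals the
resource-weighted mean of the per-stratum MRRUFs.

The package provides:

- `mrruf.records` — admission data model, CSV I/O, validation;
- `mrruf.strata` — age bands (<1, 1, 2–4, 5–12, >12 years), hospital
  volume strata, and the low-volume/zero-mortality exclusion filter;
- `mrruf.core` — MRRUF in both domains, mortality rate, stratified
  summaries, pooling;
- `mrruf.stats` — chi-square homogeneity with pairwise Bonferroni
  comparisons, Mann–Whitney U (exact permutation p under midrank ties),
  Spearman ρ, least-squares trend with adjusted r²;
- `mrruf.synthetic` — a seeded cohort generator calibrated to the
  published marginals of a 43-hospital US pediatric registry (PHIS,
  2004–2013; 11,122 HLHS admissions), plus the closed-form expected
  statistics for any configuration;
- `mrruf.report` / the `mrruf` CLI — table-structured reports.

## Worked example

```python
from mrruf import default_paper_config, generate, build_report

cohort, spec = generate(default_paper_config(seed=7))
report = build_report(cohort)
print(report.overall)
```

prints (seed 7; 11,901 simulated admissions):

```
{'n_admissions': 11901, 'n_deaths': 1168, 'mortality_pct': 9.8,
 'total_los_days': 291980, 'total_charges_usd': 5396216110.8,
 'mrruf_los': 0.151, 'mrruf_charges': 0.197,
 'mrruf_los_pct': 15.1, 'mrruf_charges_pct': 19.7}
```

So 9.8% of simulated admissions end in inpatient death, yet those
admissions absorb 15.1% of all inpatient-days and 19.7% of all billed
charges — the decedent hospitalizations are disproportionately resource
intensive, as in the real registry (10.3%, 16%, 21%). The age-band block
of the same report flags the intermediate bands (1, 2–4, 5–12) as having
significantly lower mortality than infants under one year (Bonferroni-
corrected p < 0.05) while the >12 band is not distinguishable, and the
trends block shows a declining institution-year mortality trend
(slope −0.005/year, p < 0.001) with no MRRUF–volume association
(ρ = −0.03, p = 0.84) — the structural pattern reported for the real
cohort.

The same pipeline runs from a shell:

```
mrruf simulate --seed 7 --out cohort.csv
mrruf analyze cohort.csv --report report.json
mrruf compare-ages cohort.csv
mrruf trends cohort.csv
```

To analyze real data, supply a CSV with columns
`institution_id, year, age_years, los_days, billed_charges,
discharge_status`.

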