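# Methods

## The statistic and its properties

For a cohort of hospital admissions, the mortality-related resource
utilization fraction in resource domain *r* (length of stay in
inpatient-days, or billed charges in dollars) is

    MRRUF_r = Σ_{i: died} r_i / Σ_i r_i .

It is a ratio estimator on admission-level totals, bounded in [0, 1],
invariant to any positive rescaling of the resource (hence to inflation
and to charge-to-cost conversion), and satisfies the exact pooling
identity: for any partition of the cohort into strata g with per-stratum
fractions f_g and resource totals w_g,

    MRRUF = Σ_g f_g w_g / Σ_g w_g .

The identity is what lets whole-cohort fractions be recovered from
published stratum tables alone; it is property-tested to 1e-12 on random
cohorts and random partitions. A zero denominator (empty cohort, or no
resource) makes the fraction undefined; it is carried as NaN and rendered
"NA", never coerced to zero.

Analysis is strictly admission-level: no patient linkage, no readmission
or transfer modeling, no surgical-procedure subanalysis, no cost-benefit
conversion. These are deliberate non-goals.

## Grouping conventions

Age bands are `{0}, {1}, {2–4}, {5–12}, {13–21}` completed years; this is
the table convention of the source registry analysis (its methods prose
gives "5–13, 14–21", which contradicts the printed tables; the bands are
a declarative constant in `mrruf.strata`, YAML-serializable, so the
alternate convention can be swapped in). Hospital volume is total
admissions over the 10-year window divided by 10 (admissions/year) as a
continuous variable; volume *strata* bin the total 10-year count at
100/200/300/500. LOS counts whole inpatient-days with a minimum of 1; the
admission/discharge-day convention is unspecified in the source, and any
convention consistent with integer days ≥ 1 is acceptable — the generator
rounds a continuous stay *up* to a whole day.

Hospitals with volume below 1 admission/year and zero deaths can be
excluded as non-representative ("low-volume exclusion"). The published
analysis excluded three such hospitals but printed no threshold; the
1.0/year default is an explicit, auditable choice exposed in
`ReportOptions.max_volume_threshold`. Exclusion is applied only to the
trend/correlation analyses by default, since the published overall totals
(11,122 admissions) evidently include all 43 hospitals.

## Hypothesis tests

- **Chi-square homogeneity** of mortality across groups: Pearson, no
  continuity correction, df = groups − 1 (scipy backend). On a 2×2 table
  it equals the squared pooled two-proportion z statistic (tested).
- **Pairwise comparisons against the "<1" reference band**: one 2×2
  chi-square per band; Bonferroni correction (p × k, capped at 1) by
  default, selectable to "none". The source does not name its
  multiple-comparison procedure; Bonferroni is the conservative,
  auditable default.
- **Mann–Whitney U** with midrank ties. For n_x·n_y ≤ 400 the two-sided p
  is exact: a dynamic program counts, over all C(n, n_x) equally likely
  assignments of the combined observations to the first sample, the
  distribution of the rank-sum (midranks doubled to keep sums integral,
  counts kept as exact integers); p = 2·min(P(U ≤ u), P(U ≥ u)) capped at
  1. Above the limit, the normal approximation with tie-corrected
  variance and no continuity correction is used; the two agree within
  0.02 at the switch boundary (tested). The exact path is hand-written
  because a permutation-exact p under ties is required at small n.
- **Spearman ρ**: Pearson correlation of midranks; exact permutation p
  for n ≤ 8 (all n! orderings), otherwise the t-approximation with
  n − 2 df.
- **Least-squares trend**: simple OLS with adjusted
  r² = 1 − (1 − r²)(n − 1)/(n − 2) and the two-sided slope t test.

Units of analysis for trends are config-visible choices: institution-year
for calendar trends, institution (after low-volume exclusion, n = 40 in
the published setting) for volume correlations — the only units that make
the published analyses computable from admission records.

The published point values for these tests (adjusted r² = 0.060,
ρ = 0.039/0.097) depend on the proprietary row-level data and are *not*
reproduction targets; only their structural direction (declining
mortality over calendar time; no MRRUF–volume association) is checked on
synthetic cohorts. The published ρ/p pair (larger ρ with much larger p at
common n) is internally inconsistent and is recorded as such.

## Synthetic cohort generator

`mrruf.synthetic.generate` draws, per configuration: hospital volumes
from a truncated normal (mean 259, sd 181, min 1, rounded — the only
published moments); per admission a uniform year in 2004–2013, an age
band from the published mixture (7585, 484, 2422, 531, 100 of 11,122), an
integer age uniform within band, a death indicator with band rate
(13.9, 4.5, 1.7, 3.3, 8.0)%, a log-normal stay length, and charges =
continuous stay × an independent log-normal per-diem rate. All randomness
flows through one `numpy` generator seeded from the config; identical
configs give identical cohorts.

**Why log-normal.** Only medians, means and IQRs are published, and all
show strong right skew (overall LOS median 12 vs mean 24.9 days);
log-normal is the minimal two-parameter skewed family consistent with
them. Matching the published IQRs as well would over-determine the two
parameters, so medians (and the constraints below) are prioritized; the
implied survivor LOS quartiles (≈5.4–26.5 days) land close to the
published overall 6–29 anyway.

**Calibration (closed form, in `default_paper_config`).** With overall
death mixture p̄ = Σ π_g p_g ≈ 0.1027 and log-normal mean = median ·
exp(σ²/2):

- status LOS medians are fixed at 17 (died) and 12 (alive) days;
- the two LOS log-sigmas (σ_d ≈ 1.284, σ_a ≈ 1.152) are solved from
  E[LOS] = 24.9 days and expected MRRUF_LOS = 0.16;
- per-diem medians are the status charge-median targets divided by the
  LOS medians ($409,000/17 and $163,000/12 per day), so the status
  charge medians are exact by the product rule for independent
  log-normals — this is why charges use the *continuous* stay draw
  rather than the day-rounded one, which would bias the decedent charge
  median up ~3%;
- the decedent per-diem log-sigma is fixed at 0.25 and the survivor one
  (≈0.734) solved from expected MRRUF_BC = 0.21, which also yields the
  decedent-per-diem > survivor-per-diem ordering that makes
  MRRUF_BC > MRRUF_LOS structurally rather than by accident.

A consequence of forcing MRRUF_BC = 0.21 with per-diem rates independent
of stay length is that the expected overall mean charge (≈$4.6e5)
exceeds the published $3.53e5; charge medians by status and both MRRUF
expectations are matched exactly instead. The calendar effect is an
additive trend on the death log-odds (default −0.05/year, a modest
decline chosen once; the magnitude is unpublished), with each band's
intercept re-solved so the window-average rate equals the band's
calibrated rate — the trend never moves the marginal calibration.

`expected_statistics` gives the closed-form mortality, both MRRUF
expectations, mean LOS and status-conditional medians implied by any
configuration (mixture medians by CDF root-finding); generated cohorts
recover them within 3 standard errors at n ≥ 50,000 (binomial SE for
mortality, ratio-estimator SE for MRRUF, density-at-median SE for
medians). This is the generator's headline correctness property.

**What passing tests do and do not show.** The generator reproduces the
published *marginals* (mixtures, rates, medians, headline fractions) and
the qualitative trend structure. It does not model institutional
case-mix, within-hospital correlation of outcomes, readmission of the
same child, transfers, charge–LOS dependence beyond the shared stay
factor, or band-specific LOS distributions (all bands share the status
distributions by default, though the config admits per-band values).
Agreement on synthetic data therefore validates the *pipeline*, not any
clinical claim about real HLHS care.

## Numerical choices and problem sizes

Percentages are reported to one decimal and fractions to three, with raw
values retained in machine output; table charges are additionally shown
in $ × 10⁶, the published display unit. Degenerate inputs (empty
cohorts, zero denominators, constant inputs to correlations) return
explicit undefined markers or raise with named fields. The test suite
and the acceptance script use cohorts of ~12,000 admissions (the
published scale, 43 hospitals) for pipeline checks and ~52,000–58,000
admissions (200 hospitals at the same volume distribution) for
parameter-recovery and decedent-median checks; both complete in seconds.
The decedent LOS median of a generated cohort sits at 17–18 days rather
than exactly 17 because the continuous median 17.0 falls on the
day-rounding boundary; the ±1-day tolerance reflects that discretization.
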