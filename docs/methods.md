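# Methods

## Model and assumptions

The pipeline implements a comparative-risk-assessment estimate of dietary
cancer burden. Its core is the categorical population attributable fraction
with a continuous dose–response:

* A published relative risk per dose increment (RR per x units/day) is
  converted to a per-unit log-risk slope, `Rg = ln(RR)/x` for detrimental
  exposures and `Rg = ln(1/RR)/x` for protective ones. This assumes
  log-linearity of risk in daily consumption, so the RR at any departure G
  from the guideline is `exp(Rg·G)`.
* Consumption in each stratum (age band × sex × race/ethnicity) is reduced
  to K categories with prevalence `p_x` and median consumption; the
  category's average departure from the guideline reference is
  `G_x = max(0, median − reference)` (detrimental) or
  `max(0, reference − median)` (protective). Clamping at zero means
  over-adherence confers no modeled benefit beyond the reference, and
  compliant categories contribute nothing. Using only the categories with
  positive departure would be numerically identical.
* `PAF = S/(1+S)` with `S = Σ p_x (exp(Rg·G_x) − 1)`. For a single factor
  with non-negative slope this lies in [0, 1), equals zero iff no
  non-compliant mass (or zero slope), and is strictly increasing in the
  slope, in any category's departure, and in non-compliant prevalence.
* Exposure acts with a fixed 10-year latency: the PAF computed from an
  exposure-side age band multiplies the case count of the incidence band 10
  years older. The youngest incidence band takes the youngest exposure band;
  the oldest exposure band carries forward to the open-ended oldest
  incidence band (dietary-recall surveys do not cover the oldest ages).
* Age aggregation is case-weighted (`PAF = Σ excess / Σ cases`), which
  preserves `excess = PAF × cases` exactly through aggregation. Multi-factor
  burden is **additive in excess cases**; the combined PAF is the sum of
  single-factor PAFs. Additivity ignores joint exposure and can exceed 1,
  in which case a warning is attached; a complement-multiplicative
  combination `1 − Π(1 − PAF_f)` is available as a sensitivity mode but is
  not the reporting default, since the reference analysis sums excess cases.
* The all-cancer share keeps the colorectal excess numerator and widens the
  denominator to all invasive cancers excluding BCC/SCC of the skin.
* No confidence intervals are computed anywhere; the reference analysis
  deliberately reports point estimates only, and uncertainty propagation
  for PAFs has no agreed standard.

## Stratification and pooling

Sex takes values men/women/persons and race/ethnicity takes non-Hispanic
White, non-Hispanic Black, Hispanic, Other, and all. Pooled cells
(`persons`, `all`) are always computed by pooling individual records, never
by averaging sub-stratum summaries; consequently persons-row results are not
sex-averages, and race-subgroup excess totals need not sum to the pooled
total. Sex-specific report rows use the sex-specific RR; persons rows use
the persons RR with pooled prevalence (configurable via `rr_policy`).

Default age bands: exposure side 18–24, 25–34, 35–44, 45–54, 55–59, 60–69;
incidence side 25–34, 35–44, 45–54, 55–64, 65–69, 70+. This is the unique
non-overlapping band set consistent with both anchor pairings of the
10-year latency rule (25–34 exposure → 35–44 incidence; 60–69 → 70+
carry-forward). Band sets are configurable, and incidence files must match
the configured set exactly — no re-binning is attempted.

## Category schemes

The reference analysis did not publish its category boundaries, counts, or
medians, so the scheme is explicit and configurable:

* `quantile` (default, K = 5): category 1 is the compliant side of the
  reference; the non-compliant side is split at weighted quartiles. The
  reference level is always a boundary, which makes non-adherence
  prevalence exactly the summed prevalence of the categories with positive
  departure.
* `fixed`: user-supplied bin edges, half-open `[lower, upper)`, to mimic any
  published categorization.
* `per_value`: one category per distinct consumption value — the full
  refinement, used to compare the categorical estimator against
  individual-level enumeration.

Weighted medians interpolate to the midpoint when the half-weight point
falls exactly on a value boundary, so they reduce to the ordinary sample
median under unit weights; otherwise they take the smallest value whose
cumulative weight fraction reaches one half. Consumption exactly at a
reference level counts as compliant in both directions (≤60 g/day,
≥28 g/day).

## Synthetic data generator

Real inputs are 24-hour-recall consumption records (with survey weights) and
registry counts; neither ships with the package, so a generator emulates
their shape with a known data-generating process:

* Per factor, daily consumption is a zero-inflated log-normal: a point mass
  `pi0` of never-consumers plus `exp(N(mu, sigma))`. Zero inflation matters
  for processed meat, whose guideline reference is 0 g/day (any consumption
  is non-compliant, but never-consumers are compliant).
* Defaults (per factor: pi0 / mu / sigma): red meat 0.05 / 4.254 / 0.75,
  processed meat 0.14 / 3.40 / 0.90, fiber 0 / 2.638 / 0.45, calcium
  0 / 6.809 / 0.50, with additive log-mean shifts by sex and
  race/ethnicity. The base means are calibrated so the *pooled* analytic
  non-adherence equals the published national prevalences (52.7% red meat,
  86.0% processed meat, 92.0% fiber, 63.0% calcium), and the shifts
  qualitatively reproduce the published contrasts (men eat more meat;
  fiber and calcium deficits are largest in non-Hispanic Blacks). Implied
  median intakes are realistic (≈66 g/day red meat among consumers,
  ≈15 g/day fiber, ≈870 mg/day calcium, pooled).
* The exact non-adherence probability implied by any configuration is
  available in closed form (`analytic_nonadherence`), so parameter-recovery
  tests compare empirical prevalence against an analytic value, not against
  another simulation.
* Incidence counts scale a counterfactual baseline (default 120 colorectal
  cases per band × sex × race cell) by the stratum's mean individual
  relative risk `exp(Σ_f Rg_f·G_f,i)`; allocation is
  expectation-proportional with largest-remainder rounding by default
  (a Poisson mode exists for stochastic tests). The generator returns the
  enumerated true attributable fraction `(E[RR]−1)/E[RR]` per stratum,
  which the categorical estimator must approach under refinement — at
  `per_value` refinement with a single factor the two agree to machine
  precision by construction.

What the generator does **not** emulate: usual-intake (measurement-error)
modeling of single recalls, survey design effects beyond a scalar weight,
within-person day-to-day variance, correlation between factors, and secular
consumption trends. Passing tests therefore validate the estimator and the
pipeline plumbing, not the representativeness of any real survey.

## Numerical conventions

* All internal computation keeps full double precision; rounding happens
  only at report time — PAF percentages to 1 decimal place, excess cases
  summed unrounded then rounded to the nearest integer, per-unit slopes
  displayed at 4 decimal places, all half-up (`decimal`-based, matching the
  reference tables rather than banker's rounding).
* Distribution prevalences must sum to 1 within 1e-9; CSV round-trips write
  full `repr` precision and are lossless.
* Slope round-trip (RR → Rg → RR) holds to 1e-12 relative error.
* Degenerate strata with zero cases yield PAFs with zero excess, not errors;
  empty strata (no records) and missing count cells are hard errors, never
  silent zeros.
* Pipeline outputs contain no timestamps; identical inputs and configuration
  produce byte-identical files.

## Problem sizes

The validation scenario uses 210 records per stratum cell (6 bands × 2
sexes × 4 races ≈ 10,000 people pooled), where the binomial standard error
on a prevalence is about 0.5 percentage points and enumeration of the true
attributable fraction is instantaneous. The full pipeline demo runs the
same population through 150 result cells in a few seconds.

## Known limitations

* Published stratum-level results cannot be reproduced cell-for-cell from
  raw inputs because the reference analysis' category boundaries, medians,
  age-specific prevalences, and stratified colorectal counts are
  unpublished; reproduction is therefore anchored on arithmetic identities
  of the printed tables plus property-based validation with synthetic
  ground truth.
* Additive factor combination double-counts individuals exposed to several
  factors; treat combined PAFs near or above 1 with suspicion (a warning is
  emitted).
* The log-linear dose–response extrapolates published increment-scale RRs
  to large departures (e.g. heavy red-meat consumers), where the true
  relation is unknown.
* Point estimates only; between-study heterogeneity in the RRs and survey
  sampling error are not propagated.
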