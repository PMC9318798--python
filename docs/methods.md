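# Methods

## Statistical model

### Detection prevalence from binary trials

Whether an infant's serum concentration of an analyte exceeds the assay
LOD is modelled as a Bernoulli draw with unknown population probability
*p*. With a uniform prior on *p* and *k* detects in *n* tested, the
posterior is Beta(*k*+1, *n*−*k*+1):

- point estimate (posterior mean, the rule of succession):
  (*k*+1)/(*n*+2);
- posterior SD: √[(*k*+1)(*n*−*k*+1) / ((*n*+2)²(*n*+3))];
- two-sided interval: point ± *z*(level)·SD, clipped to [0, 1], with
  *z*(0.90) = 1.645 from the standard normal.

The uniform prior keeps the estimator defined and sensible at the
boundary cases this data set actually contains (*k* = 0 and *k* = *n*):
zero detects among 101 still yields an expected ~1% population
prevalence, and all-positive still leaves room for non-detects in the
population. The normal approximation to the Beta posterior is the
reference behaviour; exact Clopper–Pearson or Jeffreys intervals are
deliberately out of scope.

For an all-positive sample the package also provides the even-odds
construction: the *p* at which an all-positive sample of size *n* occurs
with probability ½ solves *pⁿ* = ½, giving *p* = 0.5^(1/*n*); tail
probabilities α and 1−α give the interval (α^(1/*n*), (1−α)^(1/*n*)) at
confidence level 1−2α (α = 0.05 at the 90% level).

Both closed forms are cross-checked in the test suite against brute-force
oracles that share no code with them: trapezoidal integration of
*pᵏ*(1−*p*)^(*n*−*k*) on a dense grid (all *n* ≤ 12, *k* ≤ *n*, within
10⁻⁶), and bisection on *pⁿ* = tail (within 10⁻⁹).

### Percent rendering

Reported percents round half-up to the integer, except estimates below
2.5%, which keep one decimal (so 1.94% renders as 1.9, not 2). Rounding
happens only at the rendering layer; all output tables carry
full-precision columns alongside.

### Median age trends

For each analyte the per-month (0–11 completed months) median
concentration is computed — even-sized groups average the middle pair —
and an **unweighted** ordinary least-squares line of median on month
index summarises the first-year trend. The median, not the mean, is the
per-month summary because the columns are small (5–13 infants) and
strongly right-skewed, and because below-LOD substitution placeholders
distort means far more than medians. Months are not weighted by bin size
and no robust regression is applied: the 12 medians enter the fit
symmetrically. Age "<1 month" maps to x = 0.

A slope within ±0.1 ng/mL per month is labelled *flat* (the boundary is
excluded), a threshold that separates the five analytes whose medians
are essentially constant over infancy (|slope| ≤ 0.065) from the clearly
declining PFOS (−0.575); it is configurable everywhere it appears.

### Outlier flagging

Within each age group (or pooled, by option), values more than
`z_threshold` (default 3) **sample** standard deviations (n−1
denominator) from the group mean are flagged. Groups with fewer than 3
values are skipped with a log notice — a 2-value SD would make every
group its own outlier test. The sample-SD convention matters at these
sizes: for the 13 three-month PFOS values it gives SD 25.3 (population
SD would give 24.3) and a z of 3.12 for the 99.2 ng/mL value.

## LOD censoring policy

Non-detects are substituted with LOD/√2 by default — the NHANES
convention, and the one the packaged data visibly follow (the repeated
0.14 ng/mL placeholder equals LOD 0.2/√2 at the published 2-decimal
rounding). LOD/2, zero and as-is are selectable. Substitution never
changes a record's censoring flag, only its placeholder value, so
detection counts are invariant to the policy.

## The packaged cohort and its audit

The packaged data are the published individual serum concentrations for
the six analytes with per-infant values (PFOA, PFNA, PFHxS, PFDA,
N-MeFOSAA, PFOS; 601 records), the 12-analyte panel with LODs, and
detect/tested counts for all twelve analytes over the 101 tested
infants. Values are stored exactly as published (2-decimal rounding
preserved, no back-transformation). Infant sex is published only as
per-month totals, so records carry `sex=unknown`.

Auditing the columns against the published per-month counts and median
rows found, and the provenance sidecar records:

- **Months 4 and 8**: every analyte column holds 9 and 6 values where
  the published per-month summary says 8 and 7 (totals still 101, and
  all published medians agree with the columns); the columns are treated
  as authoritative.
- **PFOA month 3**: in the available transcription the column duplicates
  month 2 plus one remnant value; its true 13 values are unrecoverable.
  The published month-3 median (3.9 ng/mL, n = 13) is recorded as a
  *median override* and used wherever per-month medians are summarised.
- **PFDA**: the individual-value table cannot be reconciled with either
  its own median row (which exceeds every value in several of its
  columns) or the per-month counts; the five-analyte summary table's
  PFDA median row — which is internally consistent with its published
  slope and intercept — is recorded as the authoritative median series.
- Four panel analytes (PFNA, PFOSA, PFUnDA, PFDoDA) have no published
  LOD and are stored with LOD unknown.
- Below-LOD flags are inferred from the repeated substitution
  placeholders (0.14 = LOD/√2 for PFDA; 0.12 for N-MeFOSAA and 0.14 for
  PFNA inferred from the repetition of the column minima).

Median overrides are explicit data (`nhanes_median_overrides()`), passed
as an argument into `build_age_series`/`trend_table`; nothing is patched
silently inside the estimators.

## Synthetic cohort generator

The generator emulates the structure of the packaged cohort: per month
*m*, log₁₀ concentration ~ Normal(log₁₀ GM₀ + β·*m*, σ), censored below
the analyte LOD with the same substitution policy as real data. The
lognormal choice is the package's own modelling decision — the published
analysis states no distributional assumptions — and is standard for
serum biomarkers, consistent with the right skew of the packaged columns
(e.g. a 99.2 ng/mL PFOS value against a month median of 11).

Defaults: the month-bin sizes copy the published design
(8, 9, 7, 13, 8, 6, 10, 5, 7, 12, 9, 7; 101 infants), so simulated power
mirrors the real study. The packaged three-analyte design spans the
panel's range: a high declining analyte (GM 15 ng/mL, β = −0.02/month,
σ = 0.30, LOD 0.2), a moderate flat one (GM 3.5, σ = 0.25, LOD 0.1) and
a heavily censored low one (GM 0.25, σ = 0.35, LOD 0.2; ~58% detectable).

The per-draw detection probability is available analytically,
1 − Φ((log₁₀ LOD − μₘ)/σ), and the true median-scale trend is obtained
by fitting the same OLS to the noise-free population medians 10^μₘ, so
recovery experiments compare estimator and truth on the same ng/mL
scale. Randomness follows one named, seeded generator per cohort
(`numpy.random.default_rng`); replicate seeds are spawned from a root
generator, and identical config + seed reproduces byte-identical output.

What the generator does **not** emulate: within-infant correlation
across analytes (records are drawn independently), measurement rounding
to 2 decimals, assay batch effects, survey weighting, and any
pharmacokinetics (body-mass growth, lactational transfer, elimination
half-life). Passing recovery tests therefore show the estimators are
calibrated for independent lognormal censored sampling at these bin
sizes — not that the real cohort satisfies those assumptions.

## Verification summary

The test suite regenerates the published analysis from the packaged
data: the detection-percentage panel (point estimates exact for every
partial-detection analyte; interval endpoints within one integer percent
of the published rendering), the six slope/intercept pairs at published
precision, the three-month PFOS outlier (group mean 20, SD 25, z > 3),
and the all-positive worked example (0.917 with 90% interval
(0.6877, 0.994)). Simulation checks at the published design size
(n = 101): 90% interval coverage between 0.85 and 0.95 at p ∈
{0.1, 0.5, 0.9} over 2,000 binomial replicates, point-estimate bias
below 0.02 and null-trend slope bias within two Monte-Carlo standard
errors over 1,000 synthetic cohorts.

The published all-detect rows are rendered as 98% with interval
(96, 100); the posterior mean at k = n = 101 is 102/103 = 99.0%, and no
prior consistent with the other ten rows reproduces 98/96. Those two
rendered numbers are documented here as irreproducible and excluded from
the verification targets; the package reports 99%.

## Known limitations

- The detection interval is a normal approximation to the Beta
  posterior; it degrades for very small *n* (the all-positive
  construction is the better tool there, and coverage is only asserted
  at the published n = 101).
- Trend fits use 12 medians with no uncertainty propagation; they
  summarise, rather than test, change over age. Censored-regression or
  mixed models are out of scope by design.
- The cohort is cross-sectional: age trends are between-infant
  comparisons, not within-infant trajectories.
- Two source columns (PFOA month 3; the PFDA individual table) are
  reconstructed at the median level only, as documented above; analyses
  needing those individual values (e.g. PFDA outlier flags) inherit the
  source's inconsistency.
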