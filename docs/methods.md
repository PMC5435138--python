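# Methods

## Setting and estimands

Adult patients recovering from anesthesia are monitored with per-minute
pulse oximetry for at least two hours in the PACU. The binary outcome is
early postoperative respiratory complication (PRC): reintubation or new
intubation within three days of anesthesia end — rare, on the order of
0.3%. The exposures are patient-level desaturation phenotypes derived
from the SpO₂ stream; the secondary endpoints are hospital charges,
length of stay and ventilatory support compared between
propensity-matched groups with long versus short oxygen-therapy
exposure.

## Stream metrics

* **Censoring.** Central-tendency and duration measures use only the
  first 120 monitored minutes (minute indices are 0-based, half-open
  [0, 120)); nadir and oxygen exposure use the full stay through PACU
  discharge, because the lowest saturation and oxygen weaning are part
  of the phenotype wherever they occur. A flag
  (`nadir_full_stay=False`) restricts the nadir to the censored span.
* **Artifact floor.** Saturations below 60% are set missing everywhere:
  pulse oximetry is not validated below that value and sensor
  dislodgement dominates there.
* **Median of sliding medians.** 5-minute windows advanced 1 minute at a
  time; a window must contain at least ⌈w/2⌉ non-missing samples to
  contribute (prevents near-empty "medians"; threshold configurable).
  Even-length medians average the two central order statistics.
* **Duration.** 60 × (non-missing minutes below the level) / (non-missing
  minutes). The level is a parameter; in the pipeline it defaults to
  the population median cutoff (the 10th centile of per-patient
  medians), i.e. duration is read as time below the median *threshold*,
  not below each patient's own median.
* **Nadir.** Minimum over all valid continuous samples plus manual
  room-air entries whose surrounding run of oxygen-off continuous
  minutes lasts ≥ 5 minutes. The run rule is our operationalization of
  "room air exposure for five minutes": charting practices differ and
  no stricter definition is recoverable from a minute-grid record.

## Population thresholds and exposures

Quantiles use linear interpolation between order statistics (position
1 + p(n−1)); the convention is recorded in the run report because none
is canonical. Boundary conventions: strict `<` for the lower-tail cuts
(nadir, median), `≥` for the duration cut and every 75th-centile flag.
Oxygen exposure is ordinalized by fraction-of-stay quartiles; the
familiar minute labels (≤30 / 31–60 / 61–90 / >90 min) are provided as
the 120-minute rendering of the same quartiles, and both modes are
available because a fraction-based and a fixed-minute reading are both
defensible. NMBA and opioid doses are normalized per Devine ideal body
weight per hour of anesthesia; opioid → morphine-equivalent factors
(morphine 1, hydromorphone 6.67, fentanyl 100 per mg) ship as an
editable configuration and are assumptions, not measurements. The
surgical complexity score is the fitted linear predictor of a
region-indicator logistic model for the outcome; that model is
saturated, so when ML separates (a region with no events) the
continuity-corrected empirical log-odds — the same quantity with cells
padded by 0.5 — is used and flagged.

## Univariate statistics

2×2 odds ratios with Woolf intervals; the Haldane–Anscombe 0.5
correction is applied only when a zero cell occurs and the row is
marked. Pearson chi-square without continuity correction; Student t or
Mann–Whitney U for continuous variables. Variables with more than 5%
missingness are flagged and audited with an unadjusted 2×2 of outcome
against missingness. Report rendering follows clinical-table style
(integer percentages, 1-decimal ORs).

## Adjusted models

Plain maximum-likelihood logistic regression (Newton/IRLS, tolerance
1e-8, ≤100 iterations; no Firth correction, mirroring the source
analysis; |coefficient| > 15 is treated as quasi-separation and raised
as an error). Ordinal covariates keep ordinal coding when their
per-level empirical logits are monotone with steps within 0.15 of the
mean step, else they are recoded as indicators; zero-event levels get a
flagged 0.5 continuity correction.

**Change-in-estimate selection.** From the full model, the removable
covariate with the largest Wald p (ties broken by candidate-list order)
is tentatively removed; Δ = |ln(AOR_current / AOR_reduced)| on the
primary exposure (the maximum over exposure terms when there are
several). Δ > 0.10 restores the covariate and stops the procedure at
that first retained covariate; Δ ≤ 0.10 drops it permanently. Two
documented alternatives sit behind flags: comparing each reduced model
to the original full model rather than the current one
(`from_full_model`), and continuing to screen the remaining candidates
after the first retention (`stop_at_first_retained=False`) — the prose
descriptions of this class of procedure support both readings. Every
step is recorded in a ledger; refitting the final term set reproduces
the final estimates (tested).

**Interaction and stratification.** A product-term model yields a 2×2
matrix of cell AORs against the joint reference with Wald p-values from
the linear combinations; the stratification decision is product-term
p < 0.05 (the conventional level; no numeric threshold is inherited).
When triggered, the full selection pipeline runs independently per
stratum with failures isolated per stratum.

**Diagnostics.** c-statistic as case/control concordance of fitted
risks (ties ½) with the Hanley–McNeil standard error; Hosmer–Lemeshow
over deciles of risk (duplicate edges collapse groups with a warning,
df = groups − 2); VIF from auxiliary regressions on the design matrix;
condition indices from the singular values of the column-equilibrated
design including the intercept; omnibus likelihood-ratio chi-square
against the intercept-only model with df = number of non-intercept
coefficients.

## Propensity matching

Exposure: oxygen-therapy duration above the lowest quartile. Procedure
categories with fewer than 50 patients are excluded first. The
propensity model is a logistic fit on pre/intra-operative covariates
plus body-region indicators — post-PACU variables are deliberately
inadmissible, as they may be consequences of the exposure. Matching is
greedy 1:1 nearest neighbor without replacement, walking exposed
patients in descending score order (common practice; a seeded random
order is available for sensitivity), each taking the unused control
with minimal |Δ score|, ties to the lowest control index; no caliper by
default, configurable width. Balance uses standardized mean differences
(difference in means over the pooled SD; pooled binomial SD for binary
variables) plus the univariate tests. Matched outcomes are compared
with independent-sample tests to match the presentation convention of
such tables; McNemar-style paired analysis is a noted possible
extension.

## Synthetic cohort generator

The generator emulates what the analysis assumes about the world:

* **SpO₂ process.** Per-patient resting level ~ N(97, 1.5²) between
  patients with N(0, 1²) minute noise; episodic desaturation events as
  homogeneous Poisson onsets (0.2 / 1.0 / 3.0 events·h⁻¹ for
  low/moderate/high OSA-risk phenotypes, population shares
  0.48/0.44/0.08), exponential durations (mean 3 min), Gaussian depths
  (8 ± 3%), values rounded to integer percent and clipped to [60, 100]
  as clinical monitors report.
* **Nurse response.** After 2 consecutive minutes below the 90% alarm
  threshold, oxygen is applied (uplift +4%) until the event ends plus a
  10-minute washout; independently, 85% of patients arrive on
  prophylactic oxygen for a uniform 5-to-stay-length duration, which
  gives the oxygen-fraction distribution realistic quartiles. Manual
  room-air entries are charted with probability 0.3 per oxygen-off
  epoch of ≥ 5 minutes.
* **Outcome.** Logistic on the latent phenotype and covariates:
  intercept logit(0.0015), phenotype log-odds 0.9 (moderate) and 1.8
  (high), plus comorbidity effects (e.g. COPD ln 2.5) — marginal
  incidence ≈ 0.3–0.5%. Covariate prevalences follow a large clinical
  cohort's frequency distribution (COPD 6%, renal disease 9%, …).
* **Charges.** Log-normal by realized oxygen-duration stratum, with
  location parameters rising from exp(9.23) ≈ \$10.2k in the lowest
  quartile to exp(10.08) ≈ \$24k in the upper ones, matching the
  skewness and ordering reported for such data.
* **Seeding.** One master seed; each patient's substream key is derived
  by stable hashing of the patient id mixed with the master seed, so
  growing the cohort preserves existing patients. Event onsets come
  from a fixed block of Exp(1) gaps divided by the rate, making the
  event set (and hence desaturation burden) monotone in the configured
  rate for a fixed substream.

What the generator does *not* emulate — and therefore what passing
tests do not show about real data: autocorrelated drift and motion
artifacts beyond the 60% floor, oxygen titration (flow rates are
binary), inter-covariate correlation (comorbidities are independent
Bernoulli draws), covariate-driven oxygen prescribing (so the cohort
demo's propensity scores are nearly flat and matching has little
confounding to remove — the matching machinery is instead validated on
a dedicated planted-confounder study), and informative PACU discharge.
The outcome depends on the latent phenotype, not the realized stream,
so the fitted association of a derived exposure such as low-nadir is
attenuated relative to the phenotype effect (nondifferential
misclassification); end-to-end runs show marginal nadir AORs around
1.5 rather than the phenotype's generating odds ratios.

## Validation studies and problem sizes

The adjusted estimates of the motivating analysis cannot be reproduced
without its (undeposited) cohort, so the modeling pipeline is validated
by its operating characteristics on synthetic data, all driven by the
patient-level fast path of the generator:

* parameter recovery: 100 cohorts of n = 20,000 with rare outcomes
  (intercept −4.0, exposure log-odds 0.7 ⇒ AOR 2.01): mean bias and
  95% CI coverage of the exposure estimate;
* selection correctness: planted confounder (log-odds 1.5 on exposure
  assignment, 1.2 on outcome) retained and pure-noise covariate
  dropped, each replicate's Δ cross-checked against refitting both
  models independently;
* interaction decision: size under a null product term and power under
  log-odds 0.6, 100 replicates of n = 20,000 each arm;
* metric fidelity: 1,000 random messy streams (≤ 200 min, dropouts,
  artifacts, manual entries) with every metric compared exactly to a
  brute-force recomputation from the definitions;
* matching: greedy output equal to an exhaustive trace on ≤ 50-patient
  fixtures with deliberate score ties, and a planted confounder's SMD
  falling from > 0.4 pre-match to < 0.1 post-match.

The end-to-end pipeline demonstration runs at n = 20,000 with full
stream rendering; the repeated studies skip stream rendering because
the quantities they measure are functions of the patient-level table
only.

## Numerical and degenerate-input choices

Quantile interpolation is type-7 linear; medians of even counts average
the central pair; constant pooled data in a two-group comparison
returns p = 1 with a warning; zero-margin contingency rows/columns are
dropped with a warning; an all-missing measure leaves its threshold
absent and its downstream exposure missing; matching ties resolve to
the lowest control index, making the whole pipeline deterministic given
seed and configuration; every intermediate is plain CSV (missing =
empty field, UTF-8) so stages can be inspected and replayed
independently.
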