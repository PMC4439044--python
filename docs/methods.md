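# Methods

This note documents the models implemented in `otoscape`, the assumptions
behind the synthetic-data generator, and the numerical and design choices
made where the procedure left room.

## Trap-efficiency model and Monte-Carlo expansion

A rotary screw trap catches a fraction p of the fish passing it. The
capture probability is modelled on the logit scale from mark-release
trials as

    logit p = b0 + b1·log(flow) + phenotype offsets (fry reference),

fitted as a binomial GLM. Recapture counts are overdispersed relative to
the binomial, so the quasibinomial dispersion φ = Pearson χ²/df scales the
coefficient covariance; φ is also carried into catch simulation. Covariate
terms are dropped automatically when constant in the trial data (an
intercept-only design fits a single shared efficiency), and rank-deficient
designs or separation are reported rather than silently absorbed.

Daily catches are apportioned to fry/parr/smolt using the measured-fish
proportions of the same day; a day with catch but no measurements borrows
the nearest measured day's proportions (allocation is proportional, so
phenotype counts always sum to the raw count exactly). Missing trap days
are filled per phenotype with a triangular weighted mean over observed
neighbours within ±3 days, weight 1 − |offset|/4; the half-window is a
package choice (exposed as `interp_window`) since only the weighting shape
is prescribed.

Seasonal passage per phenotype is estimated by Monte Carlo (default
n = 2000 draws). Per draw:

1. sample a coefficient vector from MVN(β̂, Σ̂);
2. compute the daily efficiency from flow and phenotype;
3. provisional daily passage N = catch/p, rounded to the nearest integer
   ≥ catch (the beta-binomial needs integer trials);
4. re-simulate the catch c* ~ BetaBinomial(N, p, φ), parameterized via the
   intra-class correlation ρ = (φ−1)/(N−1) so that Var(c*) = N p(1−p) φ;
   ρ ≤ 0 degenerates to the binomial;
5. final daily passage = c*/p; seasonal totals sum the days.

The point estimate is the **median** of draws and the CI the 2.5/97.5
percentiles. The draw distribution is right-skewed at low catch and low
efficiency, so the median can sit below the raw catch for sparse strata —
the same zero-inflation caveat that motivates reporting passage at the
phenotype level rather than per 2-mm length bin. Efficiencies are clamped
below at 10⁻⁴ before division so an extreme coefficient draw cannot
produce unbounded passage; no upper clamp is applied because an
inverse-logit never exceeds 1 and a clamp at 1−ε would make the
perfect-efficiency limit (p ≡ 1 ⇒ passage ≡ catch) stochastic.

Because step 4 re-draws sampling noise that the observed catch already
contains, the interval slightly over-covers (~97% empirically against a
95% nominal level); this is inherent to the procedure and is left as is.

Phenology is summarized from the efficiency-corrected daily series: the
range is the first/last day with nonzero passage, quartile dates are where
cumulative passage first reaches 25/75%, and the median date uses the
weighted-median convention (midpoint of the lower and upper median
positions) so a symmetric season peaks at its centre even when the
cumulative sum hits 50% exactly.

## Isoscape classifier and natal-exit detection

The isoscape is one analyte (⁸⁷Sr/⁸⁶Sr), so linear discriminant analysis
reduces to per-site Gaussians with a pooled within-site variance and equal
priors; decision boundaries are midpoints between site means, and the
implementation is verified in tests against both a brute-force
nearest-mean rule and scikit-learn's LDA. Otolith and water reference
samples are pooled with equal weight. Leave-one-out (jackknife)
reclassification of the references gives the confusion matrix and per-site
correct-classification scores; single-sample sites are excluded with a
warning.

A fish's natal value is the precision-weighted (1/SE²) mean of the first
three spots beyond the core/yolk-sac region (default core radius 120 μm —
the region reflects maternally derived material, and the window size is a
package choice since no numeric rule is prescribed); per-spot SEs are
otherwise recorded for QC only, as the between-site variance dominates.
Ties in the posterior argmax break toward the focal site (conservative
stray-calling). Fish assigned away from the focal site are strays and are
excluded downstream.

Natal exit is a two-source transition (focal river → immediate downstream
source), so the exit scan restricts the classifier to those two sites and
walks the profile outward: exit is the spot before the first spot whose
focal posterior both dropped by more than 0.3 from the previous spot and
fell below 0.5. Gradual ramps that never trigger the rule fall back to the
last spot within 2 focal SDs of the focal mean before the first departure;
a profile that never leaves the natal signature is flagged undefined
(incomplete transect or death in river) rather than assigned an exit. The
quantitative rule is applied to every fish; no visual-inflection branch
exists.

## Size back-calculation and phenotype proportions

Exit FL is the OLS line FL = a·OR + b evaluated at the exit radius;
non-positive predictions are flagged as out of calibration. Left and right
otoliths are treated as interchangeable. β_i is the share of fish whose
predicted exit FL falls in bin i at zero perturbation; the CI resamples
the calibration residuals onto each fish's prediction (default n = 5000)
and reclassifies. The line is **not** refit per replicate (the stated
procedure resamples residuals only); `resample_fish=True` additionally
bootstraps fish, as a documented alternative. 2-mm binning is a reporting
convention only and never enters the β computation.

## Survival and error propagation

E_n for a cohort sums, over return ages a, the total escapement of year
cohort+a × (1 − adclip stray rate) × the age-a fraction, then removes
unmarked strays: this fixes one ordering of the stray-removal and
age-split steps (stray fractions estimated on the pooled cohort sample are
applied after the age split). S_i = E_n β_i / J_i with the log-scale delta
method assuming β_i ⊥ J_i; escapement uncertainty is deliberately
excluded (the trap expansion dominates the error budget). Survival
percentages are reported rounded half-up to two decimals.

The delta method needs SEs while the upstream stages produce percentile
CIs; the mapping is SE(J) = J·(log hi − log lo)/(2·1.96) (the
multiplicative spread of the draws; a direct draw-SD is available via
`se_from_ci(..., log_scale=False)`). In the assembled pipeline SE(β)
combines the calibration-resampling SD with the adult-sample multinomial
component √(β(1−β)/n) in quadrature: a CI meant to cover the true
survival must account for the finite (~90-fish) otolith sample, which
residual resampling alone cannot see.

## Synthetic worlds

The generator emulates the study design rather than river physics:

* **Cohort** — daily totals are flow pulses (triangular kernels, default
  ~2.15 M outmigrants dominated by a mid-February fry pulse, composition
  ≈ 0.78/0.15/0.07 fry/parr/smolt) over a Jan 1 – Jun 30 season;
  integerization uses largest-remainder apportionment so requested totals
  are conserved exactly. The daily size mixture is a single Gaussian
  (floor 25 mm) whose mean drifts linearly from 30 to 95 mm, producing the
  fry→smolt seasonal shift; the daily size SD (default 5 mm) is exposed as
  a parameter since no empirical value is prescribed. Default true
  survivals are 0.07%/1.78%/0.77%.
* **Trap** — logistic efficiency in log-flow and phenotype (defaults give
  p ≈ 2–5%), beta-binomial catches with φ = 1.8, ≤ 50 measured fish per
  day allocated without replacement, and mark-release trials of 300 fish
  per phenotype every 7 days (release sizes typical of Central Valley RST
  programs; smaller or rarer trials inflate the ratio-expansion skew).
* **Otoliths** — three plateaus (natal, downstream, ocean 0.70918) joined
  by logistic ramps of half-width 8 μm, emulating the ~12 days of growth a
  laser spot integrates; spots every 10 μm (the sub-weekly resolution
  achieved around transition zones). Focal and downstream means/SDs use
  the measured values (0.70660 ± 0.00008, 0.70716 ± 0.00013); the hatchery
  stray sources are synthetic stand-ins with realistic spacing.
* **Adults** — per-phenotype binomial survival, stationary annual run
  sizes (so the age-distribution bookkeeping inverts exactly), hatchery
  strays at a configurable fraction (default 20%), and a 90-fish otolith
  sample.

What the generator does **not** emulate: hydrological realism (rating
curves, storm sequencing), growth between spots, age-dependent natal
signatures, inter-annual isoscape drift, and non-stationary run sizes.
Passing recovery tests therefore demonstrate that the inference chain is
consistent and correctly calibrated under the stated error structure, not
that field estimates carry these properties.

## Problem sizes and numerical choices

Simulation studies use reduced problem sizes chosen to keep many
replicates cheap while leaving Monte-Carlo error well below the margins
being tested: ~50k-fish seasons and 400 draws for passage-coverage
replicates, 800 draws / 1500 resamples / 90-fish adult samples for the
100-world survival-recovery study. Seeds are explicit everywhere;
generators accept either an integer seed or a numpy `Generator`, and the
pipeline derives per-stage seeds from one master seed via `SeedSequence`,
so identical configurations give byte-identical outputs.

Degenerate inputs are handled explicitly: zero-catch days give zero
passage; an all-missing interpolation window fills 0 with a warning; a
zero seasonal total makes phenology undefined (error); β = 0 or J = 0
strata are skipped in survival rather than producing infinite CIs.

## Known limitations

* The exit radius is the last natal spot on a discrete grid, so exit size
  is biased low by up to one spot spacing; fine default spacing (10 μm ≈
  1.7 mm FL) keeps this below the bin resolution.
* The β CI treats the calibration residuals as exchangeable across fish
  and ignores error in the exit radius itself.
* The delta-method CI is first-order and log-symmetric; it is verified
  against a parametric bootstrap only for coefficients of variation
  ≤ 10%, which the default study conditions satisfy.
* Escapement totals are treated as known; in applications their error
  budget should be revisited before comparing cohorts with very different
  escapement quality.
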