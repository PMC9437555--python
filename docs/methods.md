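# Methods

## Telemetry coding rules

Each device-day is reduced to one status with the precedence
`intake > heartbeat > none/absent`: any intake signal makes the day
*taken* (only the first opening is meaningful; repeats are ignored by
construction), a heartbeat without intake makes it *missed*, and a day
with only a malfunction signal — or no signal at all — is *missing*. A
day with both a heartbeat and a "none" signal counts as missed, since the
device was demonstrably alive and unopened at some point that day.
Treating signal-free days like malfunction days is a deliberate choice:
absence of even a heartbeat indicates failed transmission, not a missed
dose.

The first 7 days after device issue are excluded (novelty period with
repeated curiosity openings) and the remaining days renumbered, so
"month" means consecutive 30-day blocks starting the day after the
excluded week. Calendar months were rejected to keep windows equal
length. Only complete 30-day windows are classified. A month needs at
least `min_observed_days = 15` observed (non-missing) days to be
classifiable — half the window; the choice is conventional, and the knob
is exposed. Dose timing within a day is deliberately not modelled: the
daily binary is the unit of analysis regardless of once- or twice-daily
regimens, which matches how such telemetry is analysed and slightly
flatters multi-dose regimens.

Dichotomization: *poor* = more than 4 missed days per 30-day window (the
Ugandan consolidated-guidelines cut-off), applied identically to the
recall item ("days with at least one missed dose" — note the instruments
are asymmetric: the device counts opening-days, the recall counts
missed-dose days; the asymmetry is preserved, not harmonized). Viral
suppression uses strict `copies < cutoff` with cutoff 50 (primary) or
1000 (sensitivity); a value exactly at the cut-off is unsuppressed. On a
full 30-day window the >4-day rule coincides with a percent-adherence
threshold anywhere in (83.3%, 86.7%]; the sweep utilities use 95/90/85%.

## Agreement statistics

For two dichotomous measures, observed agreement `Pa`, Cohen's chance
term `Pe = pA·pB + (1−pA)(1−pB)` and Gwet's `Pe_γ = 2π(1−π)` with
`π = (pA+pB)/2` (the two-category case of
`Pe_γ = (1/(K−1)) Σ_k π_k(1−π_k)`). κ and AC1 are the respective
chance-corrected ratios. κ is reported signed; no absolute-value
formatting is applied. Pairwise comparisons use listwise deletion, so
each measure pair keeps its own complete-case `n` (device-based pairs are
smaller than recall-based pairs whenever some participants carry no
device data). `Pe_γ ≤ 1/2` for two categories, so AC1 is always defined;
κ is undefined when both marginals are fully concentrated (`Pe = 1`),
which raises a dedicated error rather than returning a number. No
confidence intervals are attached to agreement coefficients.

## Diagnostic accuracy

Poor adherence is the "positive" test, viral non-suppression the
outcome; the orientation is fixed and never flipped to push AUC above
0.5. Wilson score intervals are the default for sensitivity and
specificity — with 135/168 the Wilson bounds reproduce the kind of CIs
reported alongside such tables to within ~0.1 percentage point, while
exact (Clopper–Pearson) bounds do not. Two AUC variants are shipped
because a dichotomous test caps its AUC at `(Se+Sp)/2`: `auc_binary`
implements that identity (equal to the Mann–Whitney probability with
ties counted ½), and `auc_model` computes the empirical ROC of a
continuous score (e.g. monthly missed days) via trapezoid integration.
Published AUCs from regression-model ROCs on unstated predictors are not
reproducible from dichotomized tables; the model-based variant exists for
such analyses when the underlying score is available. A constant score
yields AUC 0.5 with a warning rather than an error.

The cluster bootstrap resamples *clinics* with replacement (the design's
randomization unit), keeping every row of each drawn clinic; participants
are not resampled within clinics. Defaults: 1000 replicates, percentile
2.5/97.5 bounds. Replicates on which the statistic is undefined (e.g. a
resample without cases) are redrawn and counted, with a hard cap of 10×
the requested replicates.

## Three-level logistic trend model

Monthly good-adherence `y_cim` follows
`logit P(y=1|u_c,v_i) = x'β + u_c + v_i` with independent normal random
intercepts for clinic and participant. Fixed effects: month as a
categorical factor (month 1 reference), arm, and month×arm. The marginal
likelihood factorizes over clinics, and within a clinic over
participants given `u`, so it is evaluated with nested Gauss–Hermite
quadrature: 25 nodes for the participant integral, 9 for the clinic
integral (the clinic variance is small; node counts are arguments).
Non-adaptive quadrature with these node counts was validated against R's
`lme4::glmer` (Laplace) on matched data and against plain logistic
regression in the zero-variance limit (deviance agreement to 1e-6).
Optimization is L-BFGS-B on `(β, log σ_c, log σ_p)` with an analytic
gradient computed from the posterior quadrature weights; the log-sd
parametrization keeps variances positive and gives usable Wald intervals
(squared back to the variance scale). Standard errors come from a
central-difference Hessian of the analytic gradient. Non-convergence is
flagged and warned, never silent; single-clinic data fall back to a
two-level model with the clinic variance pinned at zero.

Population-averaged predictions integrate `expit(η + u + v)` over both
random-effect distributions with 64 nodes per dimension. Their CIs map a
Wald interval on η through the (monotone) marginalization;
variance-component uncertainty is not propagated. Contrasts vs month 1
are Wald, evaluated at α = 0.05 with no multiplicity correction across
the 11 monthly contrasts (none is conventional for such trend
descriptions); the month×arm block gets a joint Wald χ² test.
Participant-months with unclassifiable adherence are dropped
(complete-case), treating malfunction as ignorable missingness.

## Synthetic cohort

The generator's defaults *are* the study conditions of the trial the
package targets: 39 clinics (19 control / 20 intervention, allocation
fixed, not re-randomized per seed), 18 adolescents per clinic, 12
months; fixed effects β₀ = 6.044, the published declining month effects
(−1.202 … −2.416), arm effect 0.339 and month×arm interactions; variance
components σ²_clinic = 0.089, σ²_participant = 10.610. Roster
demographics (sex, age, orphanhood, regimen, pill burden, dosing
frequency) follow the trial's baseline distribution. Each
participant-month draws `good ~ Bernoulli(expit(η + u + v))`; the latent
missed-day count is then drawn *consistent with the category*: uniform on
0..4 when good, and `5 + Geometric(0.2)` truncated at 30 (mean ≈ 8.9,
right-skewed) when poor. The within-category distribution and the
absence of month-to-month dependence beyond the shared intercepts are
assumptions — the source data constrain neither.

Self-report is binomial thinning: each truly missed day is admitted with
probability `sr_recall_prob`, so reports never exceed the truth — the
simplest mechanism for social-desirability under-reporting. The default
0.332 solves `1 − P(poor)·P(Binom(m, p) > 4) = 0.97` at the
model-implied month-12 poor prevalence, reproducing the ~97% self-report
"good" condition.

Viral load exists at the final month only (the comparison time point).
`P(unsuppressed) = expit(−0.7464 + 0.1943·poor)` — the logits of the
published conditional non-suppression rates among good (64/199) and poor
(19/52) adherers, i.e. deliberately weak coupling. Copies/ml are drawn
from a log10-scale mixture whose components sit strictly below/above 50,
so dichotomizing copies reproduces the binary draw exactly while the
1000-copies cut-off remains meaningful. These defaults give ~33%
non-suppression, device sensitivity ≈ 0.19 and specificity ≈ 0.84 for
non-suppression — the characteristic low-sensitivity/high-specificity
pattern.

One caveat the test suite documents rather than hides: the published
trend coefficients imply a marginal month-12 control-arm good-adherence
of 0.835 (by quadrature), while the same trial reports an observed 79.2%.
Both cannot hold in a correctly specified simulator; the defaults follow
the model coefficients, so the simulated month-12 EM-good sits at ≈0.83
and the calibration test pinned to the 79% band fails by design. The
likeliest cause of the original discrepancy is informative month-12
attrition, which this generator deliberately does not model (attrition
and intervention-mechanism simulation are out of scope).

Determinism: every stage derives its generator from `(seed, stage_id)`
via NumPy's SeedSequence, so identical configs give byte-identical CSVs
and the stages can be re-run independently.

## Problem sizes in the shipped tests

The acceptance suite fits the trend model once at the full published
design (39×18×12, ≈8400 observations; ~15 s with the analytic-gradient
fitter) and averages simulator calibration over 50 full-size cohort
draws. Power-style checks (null coverage of the arm effect and the
interaction test) use 10 replicates of a reduced 10-clinic, 4-month
design — enough to detect gross miscalibration while keeping the default
test run fast. AUC/chance-term oracle equivalences are exhaustive over
all 2×2 tables up to n = 50.

## Known limitations

- Quadrature is non-adaptive; for cluster sizes far beyond ~30
  observations per participant the participant integral would need more
  nodes (or adaptive centering).
- Marginal-prediction CIs ignore variance-component uncertainty.
- The simulator draws months independently given the random intercepts;
  real adherence shows additional serial correlation.
- Agreement statistics are limited to two raters and two categories by
  design (weighted/ordinal variants are out of scope).
- The event stream uses local-clock calendar days; dose windows, time
  zones and daylight-saving artefacts are not modelled.
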