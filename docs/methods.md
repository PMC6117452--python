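# Methods

This package implements the computational chain of a transdiagnostic
individual-differences study of perceptual decision making and
metacognition: a drift-diffusion model (DDM) of decision formation, a
type-2 signal-detection model of confidence (meta-d′), an item-level
exploratory factor analysis of a 209-item symptom-questionnaire battery,
and the regression/BIC battery linking the two levels — together with a
synthetic-cohort generator that plants known ground truth at every stage
so the whole chain can be validated end to end.

## Decision model

Two-choice decisions are modelled as a Wiener process with unit diffusion
coefficient, absorbing boundaries at 0 and `a`, and an unbiased starting
point `a/2`. Per-trial drift is

    v(δ) = v0 + v_δ · z(δ)

where `z(δ)` is the z-scored absolute stimulus difference (dots
difference). Observed RT is the first-passage time plus a nondecision
time `t_nd`. The model has exactly four free parameters — `a`, `t_nd`,
`v0`, `v_δ` — no starting-point bias and no across-trial variability
parameters. Data are accuracy-coded: the upper boundary is the correct
response. Useful closed forms under this scaling:
P(correct) = 1/(1+e^{−a·v}) and E[T_dec] = (a/2v)·tanh(av/2).

Software conventions for the DDM differ in the diffusion coefficient;
some fix σ = 0.1 rather than 1. Parameters here are on the σ = 1 scale;
divide drift and threshold by 10 to convert to the σ = 0.1 convention.

*Standardization of difficulty.* `z(δ)` uses the population SD (ddof = 0)
of the trial stream, which makes the likelihood exactly additive under
table replication. For staircase streams, whose difficulty distribution is
endogenous, the reference mean/SD of the fixed design grid is used during
generation so that `v_δ` means the same thing in both designs.

*Likelihood.* The first-passage density is evaluated with the standard
dual-series expansion, using whichever of the small-time or large-time
series needs fewer terms for a truncation error ≤ 1e−10. Both series are
cross-checked against each other (≤ 1e−6 disagreement) and against a
simulation oracle. Trials with `rt ≤ t_nd` contribute a large finite
penalty (1e4) rather than −∞ so optimizers can recover.

*Estimation.* Per-subject maximum likelihood with L-BFGS-B and 10 seeded
restarts inside bounds a∈(0.1, 5), t_nd∈(0, 0.99·min RT), v0∈(−5, 5),
v_δ∈(0, 10); ties break toward smaller `t_nd`. RTs outside [0.15, 10] s
are trimmed before fitting (configurable). This is a deterministic
desk-scale point estimator; the study tradition uses hierarchical Bayesian
means, but only point estimates enter the downstream regressions, and the
estimator choice is recorded in every output manifest.

*Simulation.* Euler–Maruyama with step ≤ 1e−3 s, augmented with the
Brownian-bridge within-step crossing probability exp(−2·d0·d1/Δt). The
bridge correction removes the O(√Δt) absorption bias of naive stepping:
at Δt = 1e−3 the simulated accuracy and first-passage histograms agree
with the series density to well under 2% (checked at 15 density points ×
10⁶ paths). Paths not absorbed within 10 s are resampled and counted;
at the tested parameter ranges timeouts are vanishingly rare, so the
induced truncation bias is negligible.

## Metacognition

*Confidence level* (metacognitive bias) is the mean confidence rating
min–max rescaled by the scale's declared endpoints — a number in [0, 1]
independent of accuracy.

*Metacognitive efficiency.* meta-d′ is the type-1 sensitivity an
equal-variance ideal observer would need to produce the observed
confidence data. It is fitted by maximum likelihood on the stimulus ×
response × confidence-bin counts, holding the type-1 operating point at
the empirical relative criterion c′ = c/d′; the 2(n_bins−1) type-2
criteria are parameterized as ordered cumulative log-offsets around it,
so monotonicity is guaranteed during optimization. Efficiency is
meta-d′/d′ (M-ratio) and log(meta-d′/d′); meta-d′ is floored at 1e−3
before the log (flagged). Confidence is binned into 4 bins by per-subject
quantiles by default (stable cell counts at 210 trials/subject); cells
are padded by 1/(2·n_bins) only when a zero cell appears.

*Which efficiency enters regressions.* The regression battery consumes
the plain M-ratio. At 210 trials the log form inherits extreme negative
outliers whenever a subject's meta-d′ estimate hits the floor, which
wrecks least squares; the ratio form is well behaved. Both are computed
and exported.

An analytic expected-counts generator for the same model serves as the
oracle: on expected counts the fitted meta-d′ matches the generating
value to < 1e−4 over a d′ × meta-d′ grid, and an ideal observer whose
rating bins are carved directly from the type-1 evidence axis yields
M-ratio = 1 within sampling error.

## Synthetic cohorts

Each subject is a genotype: four DDM parameters, a target M-ratio, a
confidence-bias offset (criterion-shift units), age, IQ, gender, and
scores on three correlated latent symptom factors (AD, CIT, SW;
factor correlation 0.36 between AD and CIT, 0.20 elsewhere).

Population defaults: a ~ U(1.2, 2.2), t_nd ~ U(0.25, 0.45) s,
v0 ~ U(0.5, 1.3), v_δ ~ U(0.3, 1.6), which give a mean fixed-design
accuracy of ≈ 0.72 with a between-subject SD of ≈ 0.09 (accuracy range
roughly 0.5–0.95), matching the broad spread a heterogeneous online
cohort shows on this task. An optional age effect lowers v_δ (and can
raise t_nd) linearly in standardized age — older, slower, less accurate —
with no planted age link to metacognition.

*Planted effects.* conf_bias = 0.5·(β_conf·f + ε) and
m_ratio = max(0.1, 0.85 + 0.3·(β_eff·f + ε)), with ε scaled so the
parenthesized variables have unit variance; β_conf and β_eff are then
standardized coefficients of the planted regressions. Defaults plant the
bidirectional pattern (−0.20, +0.23, 0) on confidence bias and
(+0.10, −0.12, 0) on efficiency.

*Confidence generator.* An SDT overlay on the simulated accuracy,
mirroring the analysis chain's own separation of decision formation (DDM)
and metacognition (type-2 SDT): effective sensitivity d′_gen is read off
the subject's realized accuracy; a metacognitive evidence sample is drawn
at meta-d′ = m_ratio_true·d′_gen conditioned on the trial's response (the
meta-d′ generative model); and the rating is read off criteria placed at
equal quantiles of the subject's own meta-evidence distribution, shifted
by the bias offset. Quantile-placed criteria decouple mean confidence
from task performance — deliberately, since confidence level and
performance are nearly orthogonal traits empirically — so planted bias
and efficiency effects can be recovered without leakage from accuracy.
A consequence worth knowing: unbiased synthetic subjects have near-uniform
rating distributions, which real raters do not; nothing downstream
depends on the rating histogram's shape.

*Staircase.* 2-down-1-up in log-difficulty, initial step log 2, step
halving after each of the first 3 reversals, difficulty clamped to
[1, 64]. Its asymptote is the p² = ½ point, accuracy ≈ 0.707. Feedback
makes session accuracy negatively autocorrelated, so clamped sessions
have *less* variance than a binomial of the same length — across a
4-fold sensitivity spread the staircase cuts the between-subject accuracy
SD to well under half the fixed-design value.

*Questionnaires.* 209 items in 9 questionnaires (apathy 18, alcohol use
10, eating 26, impulsivity 30, social anxiety 24, OCD 18, depression 20,
schizotypy 43, anxiety 20), each loading 0.45–0.75 on one factor with
N(0, 0.05) cross-loadings. Latent propensity Λf + unique noise is cut at
equal-probability normal thresholds into each item's 4–5 ordered
categories. Ordinal cutting attenuates Pearson inter-item correlations by
a near-uniform factor (≈ 0.86 at 4 categories); the generator's
convergence tests therefore compare the empirical matrix to the implied
matrix after rescaling by the median attenuation.

## Factor analysis

Pearson correlations on the ordinal items (polychoric would be ~40× more
expensive at 209 items and changes little at these category counts), ML
extraction, oblimin (γ = 0, i.e. quartimin) oblique rotation, Thurstone
regression scores Z R⁻¹(ΛΦ), and Tucker congruence with greedy column
matching and sign alignment for comparing solutions.

*Choosing the number of factors.* The scree elbow is operationalized on
the **log** eigenvalue spectrum: k maximizes
log λ_k − 2 log λ_{k+1} + log λ_{k+2} among k whose last retained
component has λ > 1. On the raw spectrum the largest second difference
almost always sits at the top of the scree (λ1 ≫ λ2 dominates any later
bend), so a raw-scale rule collapses to k = 1 on exactly the structures
of interest; the log scale makes "steep then flat" bends comparable
across magnitude, which is what the visual elbow criterion actually
detects. A spectrum with no admissible positive bend returns k = 1 with a
low-confidence flag.

At n = 2000 the planted 3-factor battery is recovered with per-factor
congruence ≥ 0.95, score recovery r ≥ 0.9, and the planted AD–CIT
correlation within ±0.05.

## Regression battery and model comparison

All continuous regressors *and outcomes* are z-scored (sample SD), so
coefficients are fully standardized; binary indicators (gender) stay 0/1.
Each traditional symptom score is tested in its own model with age, IQ
and gender as covariates; the three factor scores enter jointly.
p-values are Bonferroni-corrected over the declared number of dependent
variables. Coefficient differences (signed or absolute) are tested by
subject-level bootstrap (default B = 5000, seeded) — the field does not
agree on an analytic test for comparing standardized betas within a
model. BIC = −2·loglik + k·ln n with the Gaussian MLE log-likelihood and
k = number of mean parameters; Δ = BIC_full − BIC_simple compares
`outcome ~ age + IQ + gender` against the same plus AD + CIT + SW
(|Δ| > 10 read as very strong evidence).

## Exclusion rules

Applied independently per subject (hence order-invariant): (1) one-sided
binomial test of above-chance accuracy at α = 0.05; (2) a single rating
used on > 90% of trials; (3) > 20% of trials with RT outside
[0.15, 10] s; (4) an optional comprehension-check flag column. On a
cohort with 20% planted inattentive genotypes (zero drift, constant
confidence) the rules remove ≈ the planted fraction, plus the genuinely
near-chance tail of the wide population.

## Validation harness sizes

The acceptance checks run at: 10⁶ simulated paths × 15 density points
(2% tolerance); 10⁵ trials for the closed-form accuracy check (±0.005);
3×10⁴ trials for four-parameter recovery (±10%; the v0 sampling SE makes
this window ~2σ at 10⁴); 50 subjects × 210 trials for drift-slope rank
recovery (ρ ≥ 0.8); n = 2000 for factor recovery; and 20 replicate
cohorts of n = 500 for the double dissociation, judging betas on the
replicate mean (single-cohort beta SE is ≈ 0.045, comparable to the
±0.05 window) and BIC direction per cohort. With the planted effect
sizes, the noncentral-χ² power of the confidence BIC comparison at
n = 500 is ≈ 0.87–0.91 per cohort — the ≥ 90%-of-cohorts check operates
at the edge of its own power, which is worth remembering if a replicate
set lands at 17/20.

## Known limitations

- The generator's confidence scheme is an SDT overlay on realized
  accuracy, not a joint evidence/RT confidence model; RT–confidence
  couplings within subject are not emulated.
- No RT contaminant mixtures, no across-trial parameter variability, no
  start-point bias; real data violating these will bias fits in ways the
  synthetic tests cannot reveal.
- Factor scores are Thurstone estimates, not latent draws; their
  correlation slightly overestimates Φ for low-communality batteries.
- Per-subject MLE DDM estimates are noisier than hierarchical posterior
  means at 210 trials; group-level regressions inherit that attenuation.
- The exclusion thresholds are plausible operationalizations of standard
  online-study practice, configurable because the originals are not
  pinned down in the main text of the tradition this emulates.
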