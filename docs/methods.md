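# Methods

`elab` implements, end to end, the analysis of spontaneous approach-avoidance
decisions in a virtual-reality "elevator task" in which the predictability of
the action's outcome is manipulated: on each threat trial the participant
chooses between an elevator holding an angry avatar and one holding a neutral
avatar, and a central cue signals whether the chosen avatar will stay
(predictable condition) or be replaced by a new avatar that is angry with 50%
probability (unpredictable condition).  The package contains a synthetic
cohort generator and six analysis stages: trial filtering and hierarchical
Bayesian choice models, drift-diffusion modelling, finite-mixture latent
classes, ECG/EMG preprocessing, time-resolved GLM + cluster-permutation
inference, and pipeline orchestration.

## Synthetic cohorts (`taskgen`)

The generator's defaults are the task's design values: 4 blocks x 24 trials,
two-thirds threat trials, conditions split exactly 50/50 within each block,
a 1.5 s response deadline, and a jittered pre-stimulus interval of
0.9 +/- 0.3 s.  The jitter family is not dictated by the design, so we use a
normal distribution truncated to [0.3, 1.5] s; because truncation shrinks
dispersion, the pre-truncation scale is solved numerically so the *realized*
SD equals the configured 0.3 s (the bounds are symmetric about the mean, so
the mean is unaffected).

Participants belong to one of two latent behavioral classes:

* **GD (goal-directed)** — drift-rate toward avoidance is higher under
  predictability; avoidance cells calibrated to 0.575 (predictable) and
  0.515 (unpredictable).
* **SR (stimulus-response)** — one drift-rate in both conditions, higher
  overall; both cells calibrated to the 0.739/0.724 average (~0.73), since
  the class is defined by outcome-insensitivity the generator gives it
  exactly equal drift across conditions.

Drift-rates are derived from these avoidance targets through the closed-form
unbiased absorption probability P(avoid) = 1/(1+exp(-a v)).  Boundary
separations (GD 1.05, SR 1.16 — the SR class slightly more cautious) are
sized so that fewer than 2% of simulated first-passage times exceed the
1.5 s deadline; non-decision times are 0.37 s (GD) and 0.30 s (SR), giving
the GD class the longer t0.  Individual heterogeneity enters as a normal
perturbation of drift (SD 0.12) and of resting heart rate (70 +/- 6 bpm).
The SR mixing proportion defaults to 29/90, the observed class split.

ECG traces are trains of Gaussian R-wave templates on beat times from a
multiplicative log-normal IBI process; an event-locked deceleration kernel
(a squared-sine bump from 1 s before to 4 s after stimulus onset) lengthens
IBIs by a (condition x trial-type)-specific fraction.  Default kernel gains
give every cell a baseline deceleration, with the condition contrast present
only in GD threat trials (0.14 predictable vs 0.06 unpredictable) and absent
in SR profiles (0.07 both); gains were calibrated once so that the full
ECG-to-cluster pipeline detects the GD condition cluster essentially always
at cohort sizes of 15+.  Trials are spaced 16 s apart so the -4..10 s
epochs cannot overlap (a configuration error otherwise).

EMG traces are 20-480 Hz band-limited noise whose SD is modulated by a Hann
burst (~150 ms) centered at stimulus onset + RT on the responding hand,
with amplitude base 8 noise-SDs plus a threat bonus of 3 noise-SDs for SR
profiles only; a 50 Hz line component is mixed in so the spectral
interpolation step operates on realistic input.

Subjective evaluations draw per-dyad 0-100 values from clamped normals with
means 65.231 (avoid) and 27.704 (approach) and SD 20.5, and
SV = (value_avoid - value_approach)/100.

What the generator does **not** emulate: learning within or across blocks,
choice-RT dependence (with a fixed unbiased start the diffusion's choice is
independent of its RT, so RT-conditional avoidance effects are absent by
construction), P/T waves or ECG artifacts beyond IBI noise, EMG crosstalk,
and any questionnaire traits.  Passing tests therefore certify the
*machinery* — balance, calibration, recovery, error control — not that real
cohorts look like these.

## Behavioral models (`behavior`)

Responded threat trials with RT < 150 ms are anticipations and removed (the
percentage is reported against all threat trials, rounded to two decimals);
trials without a response are dropped separately.  Choices (avoid = 1) are
modelled by hierarchical Bayesian logistic regression with condition
treatment-coded (unpredictable = 0), RT grand-mean-centered, correlated
participant-level intercepts and slopes, and priors normal(0, 2.5) on
coefficients, exponential(2) on random-effect SDs and LKJ(2) on the
correlation matrix.  Model comparison uses WAIC from pointwise
log-likelihoods; effects are summarized by posterior medians, 95% credible
intervals, tail probabilities, and Savage-Dickey Bayes factors (posterior
kernel-density at zero against the coefficient prior) — chosen because it
matches per-parameter BF reporting without bridge sampling.

Sampling is an adaptive blocked random-walk Metropolis-within-Gibbs sampler
written in this package (no probabilistic-programming backend is required):
one block for the fixed effects, one per participant's random effects,
coordinate-wise updates for log-SDs and tanh-transformed canonical partial
correlations (under which the LKJ prior factorizes into independent shifted
Beta densities via the vine construction), plus an interweaving move that
rescales each SD jointly with its latent effects — the move that breaks the
funnel coupling and is what makes the variance parameters mix.  Proposal
scales adapt during warmup toward 30-44% acceptance.  Defaults are 3 chains
x 10,000 iterations with 2,000 warmup; tests and the pipeline run shorter
chains and verify split-R-hat/ESS through arviz.  With a zero-length trial
table the sampler returns exact prior draws (prior-predictive mode).

Classical checks: two-sided Wilcoxon signed-rank against chance (the
reported V is the positive-rank sum convention) and a paired t-test with
Shapiro-Wilk and Levene assumption checks; Cohen's d confidence intervals
come from a nonparametric bootstrap (10,000 resamples by default) since no
analytic form is assumed.

The value-integration model regresses avoidance on condition, RT, trial-wise
heart-rate change and subjective value with the complete four-way
interaction set (16 terms).  The random structure is reduced to a correlated
intercept + condition slope: a maximal structure over 16 terms is not
identifiable at 45 participants, and pruning highest-order slopes first is
the documented fallback.

The power procedure simulates artificial participants from seed fixed
effects and random-effect SDs and refits each dataset with a frequentist
population-averaged logistic model (GEE with exchangeable working
correlation and participant clusters), counting Wald p < .05 on the target
term; refit failures are counted separately.  A GEE stands in for a
random-effects ML refitter because the per-refit cost must stay compatible
with 1000 simulations per sample size.

## Drift-diffusion model (`ddm`)

The Wiener first-passage density uses the standard small-time/large-time
series expansions with per-element regime switching at truncation tolerance
1e-7; avoidance is the upper boundary, the start point is fixed at a/2, the
diffusion coefficient at 1, and no inter-trial variability parameters are
fitted.  The trial simulator is Euler-Maruyama at dt = 1 ms with
Brownian-bridge crossing corrections (probability exp(-2 d_old d_new/dt) of
an unobserved within-step crossing), which removes the first-order
absorption bias of naive Euler — verified against the closed-form absorption
probability 1/(1+exp(-a v)) and by Kolmogorov-Smirnov distance < 0.005
between the density and 2x10^5 simulated passages.

Designs: mod1..mod8 enumerate which of (v, a, t0) receive an additive
predictable-condition effect; a cell-means design estimates one parameter
per crossing of chosen factors (used for the class analysis).  ML mode runs
multistart (>= 10 starts by default) L-BFGS-B over v in [-5, 5],
a in (0.3, 4], t0 in [0, min RT), with rt <= t0 handled by a finite
log-density floor; AIC/BIC rank designs.  MCMC mode is hierarchical
Metropolis-within-Gibbs: participant-level baselines (v_i, log a_i, t0_i)
drawn from group normals, condition/cell effects estimated only at the
group level (trials per cell are few), priors mildly informative
(group v ~ N(0,2), log a ~ N(0.4, 0.8), t0 ~ N(0.3, 0.3) truncated, SDs
half-normal(0.5), effects N(0,1)).  DIC = D_bar + pD and BPIC = D_bar + 2pD
with pD = D_bar - D_hat, D_hat taken as the minimum sampled deviance (a
plug-in-at-mode proxy that avoids a refit).  Posterior contrasts (e.g. the
class difference-of-differences in drift) evaluate expressions draw-wise
over named parameters.

## Latent classes (`mixture`)

Participants are the mixture units: component k is a fixed-effects logistic
regression of choice on (intercept, condition, centered RT, condition x RT),
a participant's component likelihood is the product of their trial
likelihoods, and EM alternates participant-level responsibilities with
responsibility-weighted Newton/IRLS refits (a hand-written solver — the
4-coefficient refit runs thousands of times inside EM, where estimator
overhead would dominate).  Defaults: up to 1000 EM iterations, relative
tolerance 1e-6, 20 restarts from symmetric-Dirichlet responsibilities, best
restart by log-likelihood; a component collapsing below 1/(10 n) triggers a
restart and persistent collapse falls back to K-1 with a warning.
BIC = -2 logL + p log(N) with N = participants and
p = 4K + (K-1); K is selected over 1..5.  Components are reported in
descending avoidance-intercept order, so the SR-like class is always
component 1; hard labels take the maximum responsibility with ties broken
toward the lower index.

A note on attainable accuracy: with the calibrated class cells
(GD 0.575/0.515 vs SR ~0.73) and 64 trials per participant, the
per-participant log-likelihood ratio between the two class models has mean
~5.2 and SD ~3.3 nats, so even the Bayes-optimal assignment errs on ~5-6%
of participants and the expected adjusted Rand index sits near 0.8.  Label
recovery is therefore tested as a monotone function of class separation,
reaching ARI >= 0.9 once the SR-GD logit gap grows past roughly twice the
calibrated value.

## Physiology (`physio`)

ECG: 1-100 Hz zero-phase 4th-order Butterworth; R peaks are local maxima
above 60% of the 99th percentile of positive amplitudes (quantile-based, so
amplitude-scale invariant — the calibration the recording protocol leaves
to the analyst) with a 250 ms refractory period, and fewer than 10 beats
per minute of signal raises a quality error.  IBIs deviating more than 30%
from the last *accepted* IBI (left-to-right, so one ectopic beat does not
cascade) are replaced by cubic-spline interpolation over unflagged
neighbors.  iHR = 60000/IBI in bpm — note the inversion relative to a
"divide by 60,000" phrasing, the only reading that yields beats per minute.
Beat-wise iHR is assigned at the second R peak of each interval, linearly
interpolated to 10 Hz, band-passed 0.01-2 Hz (2nd-order zero-phase),
epoched -4..10 s around stimulus onset, and baseline-corrected by the mean
of -2..-1 s (a window placed before anticipatory deceleration begins).

EMG: 20-500 Hz zero-phase band-pass; line noise is removed by spectral
interpolation of the +/-0.5 Hz magnitude band around 50 Hz and harmonics up
to 250 Hz (phases preserved), gated on the band actually exceeding its
flanks by 1.5x so clean recordings pass through unchanged; envelopes are
full-wave rectified and low-passed at 10 Hz (4th-order).  Burst detection:
the baseline is the lowest-mean 500 ms moving-average window between 1 s
pre-stimulus and the response; the threshold is baseline mean + 3 SD;
supra-threshold runs closer than 20 ms merge and isolated runs shorter than
25 ms are dropped; the RT-generating burst is the one whose [onset, offset]
contains stimulus onset + RT.  Peak amplitudes outside Tukey 1.5-IQR fences
within a participant are rejected, epochs are +/-500 ms around the peak at
the native resolution (no decimation — the cluster rule needs millisecond
support), and all epochs are z-scored within participant over the
concatenated trial samples.  The analyzed channel is the responding hand
per trial (configurable).

## Cluster inference (`spm`)

Per participant and time point, z-scored epochs are regressed (OLS) on
effect-coded factors (all -0.5/+0.5: condition, threat, outcome, response;
interactions as products) plus one non-time-varying grand-mean-centered RT
regressor.  Three formulas cover the designs: condition x threat on all
trials, condition x outcome and condition x response on threat trials only
(neutral trials carry no approach/avoid semantics).  Rank-deficient
participant designs get missing betas for the affected regressors and drop
from that regressor's group test.

Group inference: one-sample t against zero across participants per time
point; candidate clusters are same-sign supra-threshold runs
(|t| > t_{.975, n-1}) strictly longer than 100 ms (iHR) or 20 ms (EMG).
The permutation null replaces the beta series of a uniformly drawn number
of participants (1..n) with zeros and recomputes |t_mass| within the
observed cluster windows; p_corr is the exceedance proportion floored at
1/n_perm, two-sided via absolute values, 10,000 permutations by default.
This window-fixed zero-subset construction is implemented literally and is
empirically conservative (familywise error ~0.5% at nominal 5% on 200
smooth-noise null cohorts).  A participant-level sign-flip scheme is
provided as the conventional reference; under sign flips the window-fixed
null is badly anticonservative (flipping destroys the effect that selected
the window), so that scheme automatically re-detects clusters per permuted
series and uses the max cluster |t_mass| over the series
(``null_statistic="max-over-time"``, FWER ~7.5% empirically).

The trial-wise cardiac covariate is the signed extreme baseline-referenced
iHR value within the significant negative intercept-cluster window, Tukey
1.5-IQR-filtered and z-scored within participant; when no qualifying
cluster exists the caller must supply a fallback window explicitly.

## Pipeline (`pipeline`, `cli`)

`run_pipeline` executes simulate -> filter -> behavioral fits -> DDM grid ->
mixture -> ECG chain -> cluster inference with per-stage seeds spawned from
a master `SeedSequence`, writes CSV/JSON artifacts plus a manifest (config
snapshot, stage seeds, output hashes, timings), and is bit-reproducible
from the same seed.  `make_report` renders avoidance cells, the mod1..mod8
table, the mixture BIC table, cluster tables, and defective RT densities
(each response type's RT density weighted by its relative frequency so the
two curves jointly integrate to one).  The `elab` command exposes thin
subcommands (`simulate`, `run`, `ddm-compare`, `mixture-select`, `power`,
`report`).

## Problem sizes and tolerances

Default analysis settings reproduce the study's values (150 ms filter, 30%
IBI rule, 3 SD burst threshold, 20/25 ms burst rules, 1.5 IQR fences,
p_thres = 0.05, >100 ms / >20 ms cluster durations, 10,000 permutations,
K = 1..5, 3 x 10,000 MCMC iterations).  The test and acceptance runs keep
the replicate counts that define the statistical checks (50 model-recovery
runs, 200 null cohorts at 1,000 permutations, >= 10,000 draws for
Monte-Carlo targets) while using reduced cohort sizes (8-24 participants
for end-to-end physiological runs, 90 for cohort-level recovery) and
shortened MCMC chains; these sizes are the package's verification design.
Numerical choices worth knowing: the wfpt series tolerance is 1e-7; ML fits
use a -745 log-density floor for rt <= t0 rather than infinities;
EM declares convergence at relative 1e-6; cluster durations are counted as
points x sampling period with a strict "more than" rule; empirical p-values
are floored at 1/n_perm.

## Known limitations

The behavioral sampler is a random-walk method: it needs the interweaving
move to mix variance parameters and longer chains than a gradient-based
sampler would; convergence should always be checked via the provided
diagnostics.  DIC's plug-in deviance uses the minimum sampled deviance
rather than a refit at the posterior mean.  The DDM MCMC mode estimates
condition effects without participant-level condition slopes, matching the
few-trials regime but understating between-participant effect
heterogeneity.  The generator's choice-RT independence means analyses that
depend on RT-conditional avoidance (e.g. condition x RT interactions) see
null effects on synthetic data by construction.
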