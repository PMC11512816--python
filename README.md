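# elab

Analysis pipeline for spontaneous approach-avoidance decisions under
manipulated action-outcome predictability — the virtual-reality "elevator
task" in which participants choose between an elevator holding an angry
avatar and one holding a neutral avatar, while a cue signals whether the
chosen avatar will stay (predictable outcome) or be replaced by a new
avatar that is angry with 50% probability (unpredictable outcome).  The
package is aimed at researchers in computational cognitive modelling and
psychophysiology who want the full analysis stack — and a synthetic cohort
generator that makes every stage testable without any data download.

## What it computes

* **Behavior** — anticipation filtering (RT < 150 ms), avoidance summaries,
  and hierarchical Bayesian logistic models of trial-wise choice
  (avoid = 1) with priors β ~ N(0, 2.5), σ ~ Exp(2), LKJ(2) correlations;
  WAIC model comparison; 95% CrI, p₍₀₎ tail probabilities and
  Savage-Dickey Bayes factors; Wilcoxon/paired-t classical checks; and a
  simulate-refit power procedure.
* **Diffusion model** — Wiener first-passage defective densities
  f(t | v, a, t₀) with fixed unbiased start z = a/2 (upper boundary =
  avoidance), a bias-corrected Euler simulator, maximum-likelihood and
  hierarchical-MCMC fitting of the mod1..mod8 condition-design grid
  (which of v, a, t₀ vary by condition) and class cell-means designs,
  ranked by BIC or DIC/BPIC, with draw-wise posterior contrasts.
* **Latent classes** — an EM-fitted finite mixture of logistic regressions
  with participants as mixture units, component count chosen over K = 1..5
  by BIC = −2 logL + p log(N participants).
* **Physiology** — ECG (1-100 Hz filter, calibrated R-peak detection, 30%
  IBI artifact rule with cubic-spline repair, iHR = 60000/IBI, 10 Hz
  stimulus-locked epochs −4..10 s baselined on −2..−1 s) and EMG
  (20-500 Hz filter, spectral line-noise interpolation, 10 Hz envelopes,
  single-threshold burst detection with 20 ms merge / 25 ms minimum rules,
  Tukey fences, ±500 ms peak-centered epochs).
* **Cluster inference** — per-time-point GLMs of z-scored epochs on
  ±0.5-coded factors, cluster formation (>100 ms iHR / >20 ms EMG) on
  one-sample t series, and cluster-mass permutation p-values (zeroed
  random participant subsets; a sign-flip max-over-time variant is
  available).

## Worked example

```python
import numpy as np
from elab import taskgen, behavior, ddm, mixture

cfg = taskgen.StudyConfig(n_participants=30, rng_seed=7)
cohort = taskgen.generate_cohort(cfg)
threat = cohort["trials"].query("trial_type == 'threat'")
kept, n_removed, pct, n_missing = behavior.filter_anticipations(threat)
print(f"threat trials kept {len(kept)}, anticipations {n_removed} ({pct}%)")

summary = behavior.avoidance_summary(kept)
print(summary.groupby("condition")["p_avoid"].mean().round(3))

fit = ddm.fit(ddm.CONDITION_DESIGNS["mod2"], kept, mode="ml", seed=1)
print({k: round(float(v), 3) for k, v in fit.estimates.items()})

best_k, bic_table, fits = mixture.select_K(kept, rng=1, n_restarts=8)
print("best K =", best_k)
```

Output from this exact snippet:

```
threat trials kept 1901, anticipations 0 (0.0%)
condition
predictable      0.629
unpredictable    0.612
Name: p_avoid, dtype: float64
{'v_intercept': 0.429, 'v_condition': 0.049, 'a_intercept': 1.129, 't0_intercept': 0.315}
best K = 2
```

Reading the numbers: the cohort avoids the angry avatar above chance in
both conditions and slightly more when the outcome is predictable (0.629
vs 0.612; this draw is SR-heavy, which lifts the baseline and dilutes the
condition contrast), the pooled fit shows a clearly positive baseline
drift toward avoidance (0.43 evidence-units/s) with a small extra drift
under predictability (+0.05, carried by the goal-directed participants),
and the mixture model recovers the two latent behavioral classes (K = 2)
the cohort was built from.

The same stages run from the shell:

```bash
elab simulate --seed 7 --n-participants 30 --out run/
elab ddm-compare --trials run/trials.csv --mode ml
elab mixture-select --trials run/trials.csv --kmax 5 --seed 7
elab run --seed 7 --out run_full/   # full pipeline incl. ECG + clusters
elab report --run-dir run_full/
```

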