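# Methods

This note documents the models, estimators and numerical choices behind
`motorlearn`, and what its synthetic data can and cannot say about real
behavior.

## The optimal learner

The learner is a linear-Gaussian state-space model with two hidden states —
a slow process (retention 0.998 per trial) and a fast process (retention
0.75) — summed into a single observable output (`H = [1, 1]`).  Feedback is
generated open-loop by the same dynamical system (`x_k = A x_{k-1} + w_k`,
`Z_k = H x_k + v_k`) and then filtered closed-loop by the standard Kalman
recursion; the innovation `y_k = Z_k − H x̂_{k|k−1}` is identified with the
movement error on trial *k*.  Assumptions worth keeping in mind: noise is
Gaussian and trial-indexed (no within-movement dynamics), retention and
noise are stationary, and the perturbation enters purely as an additive
offset on the observed feedback, not on the generative states.

Default parameters (dimensionless, per trial):

| parameter | default | meaning |
|---|---|---|
| `A` | diag(0.998, 0.75) | retention of the slow / fast state |
| `Q` | diag(1.46e-7, 1.46e-7) | process-noise covariance (a.u.²) |
| `R` | 3.0e-4 | observation-noise variance (a.u.²) |
| `x0`, `P0` | 0, Q | initial state and estimate covariance |

These values place the model in the regime of human adaptation: baseline
variability ≈ 6% of a typical amplitude, ≈ 92% asymptotic compensation of a
constant offset, half-life ≈ 35 trials.  `P0` is not separately
identifiable; we set `P0 = Q` and verified that quantities computed after
the 1000-trial burn-in are unchanged when `P0` is set to the steady-state
covariance instead.  The state ordering puts the slow process first; the
fast process is the one with the smaller retention.

**Protocol.**  All learning-rate measurements use one continuous run: a
10000-trial unperturbed baseline (first 1000 trials discarded from
variability estimates to exclude transients), then 3000 trials with a
constant −0.3 added to the feedback.  The filter state is *not* reset at
perturbation onset; an onset-at-201 variant is available through
`PerturbationSchedule` for short illustrative runs.  3000 post-onset trials
are ample for asymptote at the default rate (~0.02/trial).

**Amplitude reference.**  The simulation is unitless, so "percent of
movement amplitude" needs a reference; we use the perturbation magnitude
0.3.  The baseline innovation SD (~0.018) is then ~6% of amplitude.

**Suboptimal learning.**  A gain-scale factor multiplies the Kalman gain in
both the state update and the covariance update, applied identically to
both components.  At scale 1 the filter is exactly the optimal Kalman
filter, which is also where baseline variability is minimised — verified
by a paired sign test over common feedback sequences.

**Steady state.**  The Riccati fixed point is found by iterating the
covariance recursion from `P0` until successive prior covariances change by
less than `tol` (default 1e-14, max-abs).  Asymptotic compensation solves
the deterministic fixed point `x* = A x* + K∞(c − H A x*)` and reports
`H x*/c`, which is independent of the sign and size of `c` by linearity; it
agrees with the mean residual of a long perturbed simulation to < 0.02.

## Learning-rate estimators

`fit_exponential` fits `y(t) = a + b e^{−ct}` by bounded least squares
(`c ∈ [1e-6, 10]`), restarted from five deterministic rate guesses
geometrically spaced over `c ∈ [1e-3, 1]` (local minima are a real risk for
slow rates); the best-SSE solution wins.  Inputs with zero variance return
`converged=False` with `b = 0` rather than an arbitrary rate.  Fit
significance is the F-test of the three-parameter curve against a constant
model.  The simulation's learning curve is fit on the signed innovation
with the sign of `b` free — for a monotone decay this is equivalent to
fitting the absolute error, and it avoids the rectification bias of
absolute values near the noise floor.

`fit_learning_slope` regresses test-trial deviations on preceding
perturbation magnitudes (OLS) and reports the slope with the adaptive sign
positive: a subject correcting a fraction η of each perturbation has raw
slope −η, reported as +η (11% means "11% of a perturbation is corrected in
the next movement").

`baseline_sd` is the sample SD (n−1) after a leading discard window.

## Parameter sweeps

Observation noise and process noise are swept by multiplying `R` or `Q` by
integer factors 1–10; the gain manipulation uses scales
{1/16, 1/8, 1/4, 1, 4, 8, 16} with model parameters unchanged; the
fast-state manipulation multiplies only `Q[fast]`.  Each cell runs the full
protocol over a common set of 20 seeds (common random numbers make the
factor contrasts paired) and averages baseline SD and fitted `c`.  Averaged
curves are used because single-run curves are visibly noisy; the four
directional patterns (opposite for observation noise and fast-state noise,
same-direction for process noise, U-shaped variability around the optimal
gain) are asserted as rank correlations across factor means.

## Synthetic block experiments

The four designs share one grammar: familiarization and baseline phases,
then adaptation blocks of `n` trials — `n−2` veridical null trials, one
perturbation trial, one no-feedback test trial — with each perturbation
magnitude used in 10 blocks per condition and block order shuffled by the
session seed.  Phase lengths, magnitude sets and block-size compositions
give totals of 520 (Exp1/Exp2, two sessions), 500 (Exp3, one interleaved
session) and 700 trials (Exp4, two sessions).  In Exp3 the two perturbation
directions are simulated as independent one-dimensional channels;
familiarization/baseline trials are alternately labelled so each channel
receives half of the baseline endpoints.

The generative subject is deliberately minimal: a single intended aim point
per condition, updated on feedback trials by `−η · (endpoint + perturbation)`
and frozen on test trials, with endpoint = aim + N(0, motor_noise_sd²).
The correction gain follows cue combination, `η = g·σ_P²/(σ_P²+σ_V²)`:
greater visual uncertainty σ_V lowers the weight of a visual error and
slows learning.  Defaults (`motor_noise_sd = 3 mm`, `σ_V = 1.5 mm`,
`σ_P = 0.5 mm`, `g = 1`) give η = 0.1 and baseline SDs of 2–4 mm, the range
observed in planar reaching.  This makes η the ground truth that
`estimate_subject_metrics` must recover, which is the module's main test
surface.  What the model does *not* emulate: kinematic trajectories,
reaction/movement times, use-dependent drift, savings, or any anticipatory
strategy; passing recovery tests says the analysis pipeline is unbiased for
this generative class, not that humans are one-state learners.

A small caveat discovered by the noiseless tests: because the aim point
carries over between blocks, a finite session induces slight correlations
between a block's perturbation and the aim inherited from previous blocks,
so slope estimates scatter around η rather than hitting it exactly even
without motor noise.  Tolerances in recovery tests are therefore stated in
standard errors.

## Psychometrics

2AFC responses are modelled as Bernoulli with `P(d) = Φ((d − μ)/σ)` at
offsets [0, ±0.7, ±1.4, ±2.1] mm, 20 repetitions each.  `fit_probit`
maximises the Bernoulli likelihood with Nelder–Mead over (μ, log σ) — the
log parameterisation enforces σ > 0 — from a moment start (μ₀ at the
interpolated 50% crossing, σ₀ at half the stimulus range), clamping fitted
probabilities to [1e-6, 1−1e-6].  Maximum likelihood on binary trials was
chosen over least squares on proportions; the two coincide on noiseless
proportions, which is tested.  No lapse-rate parameter is fitted.

## Meta-analysis and power

Synthetic studies mirror the shape of published adaptation datasets: five
studies of 16/37/36/30/13 subjects (132 total), learning curves of 240, 30,
150, 150 and 200 trials, and last-N baseline-window rules of 15, 50, 50, 20
and 50 trials.  Per subject, the curve is `b e^{−ct}` plus execution noise
with `b = 10 × SD` (adaptation starts well above the noise floor), rates
uniform on [0.05, 0.2] per trial and SDs uniform on [1, 4]; a copula
parameter `rho` can couple SD and rate (0 = null cohort).  Variability and
rate are z-scored within study before pooling, making units irrelevant;
Pearson and Spearman correlations are both reported because outliers are
expected in rate estimates.

Permutation machinery: the null of a paired mean difference is generated by
sign flips, of a two-sample difference by label reshuffles, and of a
correlation by permuting one margin; the two-sided critical value is the
(1−α) quantile of the |statistic| null.  The minimal detectable effect is
found by bisection against that fixed critical value, with power evaluated
by Monte-Carlo under a normal alternative (a mean shift, or a
bivariate-normal correlation at the observed n) — shifting the mean /
injecting a correlation is the simplest alternative consistent with the
null resampling scheme.  Correlation sample sizes use the Fisher-z power
`Φ(atanh(r)·√(n−3) − z_{1−α/2})` with two-tailed α throughout; for
r = 0.76 this gives n = 11, and for r = 0.45 it gives n = 37 (power
approximations differing in the tail treatment give values as low as 34;
the Fisher-z answer is what the function returns).

## Problem sizes and determinism

Seed-averaged quantities use 20 seeds; permutation defaults are 10000
reshuffles; recovery studies use 100–200 simulated observers.  Test-suite
variants of expensive computations use reduced but structurally identical
protocols (e.g. 3000-trial baselines) — chosen so the whole suite and the
analysis scripts run comfortably on a laptop.  Every stochastic function
takes an explicit integer seed (NumPy `default_rng`), child seeds are
derived via `SeedSequence`, and repeated runs are bit-identical; the
pipeline writes a provenance block (config hash, seed, version) next to its
outputs.

## Known limitations

- Two timescales only; no non-Gaussian or nonlinear filtering.
- The unitless simulation needs an amplitude convention for percentage
  claims (see above); other conventions rescale the 6% figure.
- The subject model omits exploration, so it cannot by construction produce
  a facilitatory effect of variability on learning — it is the null model
  against which such claims are tested.
- Real-data ingestion is schema-level (long-format CSVs of per-subject
  sequences); no public-dataset downloader is included.
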