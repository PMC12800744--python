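# Methods

This package is a complete synthetic re-implementation of a model-based
EEG analysis of social learning: a binary-lottery advice-taking task, a
hierarchical Gaussian filter (HGF) account of how participants track an
adviser's changing intentions, MAP fitting and random-effects model
selection across a cohort, and a mass-univariate single-trial GLM stage
that recovers planted computational signatures — and their temporal
hierarchy — from synthetic EEG. Everything runs from seeds; no recorded
data is required at any point.

## Task model

The task is a 170-trial binary lottery split into a stable phase (34
trials, consistently helpful advice), a volatile phase (102 trials, the
adviser's policy alternates between helpful and misleading in blocks of
10–20 trials), and a second stable phase (34 trials). The adviser holds
privileged information that is accurate on 80% of trials; a helpful
policy transmits it faithfully, a misleading policy inverts it. The
generator assigns advice accuracy with exact stratified counts per policy
block and then flips single volatile-phase trials so that the number of
privileged-correct trials is exactly `round(0.8 * 170) = 136` on every
seed — the design constant is deterministic, not an expectation.

Each trial also shows a pie-chart cue. We model the cue as the
probability `c` that the advised option wins, drawn independently and
uniformly from `{0.25, 0.35, 0.45, 0.55, 0.65, 0.75}` — a symmetric,
moderately informative set. Two consequences of this independence
assumption are documented below (regressor collinearity; see
*Limitations*).

## Perceptual model

The three-level binary HGF represents advice accuracy (level 1, Bernoulli),
adviser fidelity `x2` (Gaussian random walk whose step size is
`exp(kappa2 * x3 + omega2)`), and the log-volatility of the adviser's
intentions `x3` (random walk with variance `theta`). The mean-reverting
variant adds a drift `phi3 * (m3 - x3)` at the third level — a
discrete-time Ornstein–Uhlenbeck pull toward a subject-specific
equilibrium `m3`, modelling a baseline expectation about how changeable
the adviser is.

Trial-wise inversion follows the canonical variational update scheme of
the binary HGF: each level's posterior mean moves by a precision-weighted
prediction error,

    mu2 = muhat2 + delta1 / pi2,
    mu3 = muhat3 + (kappa2 / 2) * (w2 / pi3) * delta2,

with `w2 = v2 * pihat2`, `v2 = exp(kappa2 * muhat3 + omega2)`,
`pi2 = pihat2 + muhat1 (1 - muhat1)`,
`delta2 = (1/pi2 + (mu2 - muhat2)^2) * pihat2 - 1`, and
`pi3 = pihat3 + (kappa2^2 / 2) * w2 * (w2 + (2 w2 - 1) delta2)`.
The level-1 prediction is `muhat1 = s(muhat2)` using the prediction
available at outcome onset, which is also the alignment used for the EEG
regressors. For some parameter settings (strong coupling with confident
beliefs) `pi3` can become non-positive; the filter then raises an error
naming the trial and quantity, and the fitting objective treats the
region as excluded.

Two derived quantities close the set of six single-trial regressors: the
cue PE `delta_c = u - c` and the outcome PE `delta_b = u - mu_b` with the
integrated prediction `mu_b = zeta * muhat1 + (1 - zeta) * c`.
Algebraically `delta_b = (1 - zeta) * delta_c + zeta * delta1`.

The per-trial loop is JIT-compiled with numba; a pure-NumPy fallback with
identical semantics exists, and the test suite holds the production path
to a literal per-trial transliteration of the update equations at 1e-10.

## Response model

Choices integrate advice- and cue-based probabilities,
`b = zeta * muhat1 + (1 - zeta) * c`, and follow the advice with
probability `b^beta / (b^beta + (1-b)^beta)` where
`beta = exp(-muhat3 + nu)`: the more volatile the adviser currently
seems, the flatter (more exploratory) the choice function. `b` is guarded
into `[1e-8, 1 - 1e-8]` and the sigmoid is evaluated in log space so
large `beta` cannot overflow.

## Fitting, evidence, and model selection

Seven parameters are free in the mean-reverting variant (`kappa2` via
log, `zeta` via logit, `omega2`, `m3`, `mu2_0`, `mu3_0`, `nu` via
identity); the standard variant drops `m3`; the two ideal-observer null
models first optimise the perceptual parameters against the inputs alone
(minimum total Bernoulli surprise) and then fit only `zeta` and `nu` to
behaviour. Priors are weakly informative, transformed-space Gaussians:
`kappa2 ~ N(log 1, 0.25)`, `omega2 ~ N(-3, 16)`, `m3 ~ N(1, 1)`,
`mu2_0 ~ N(0, 1)`, `mu3_0 ~ N(1, 1)`, `zeta ~ N(0, 1)` (logit),
`nu ~ N(2, 4)`; `theta = 0.5` and `phi3 = 0.1` are fixed. MAP estimation
uses derivative-free simplex search (objective tolerance 1e-6, at most
2000 evaluations) from the prior means plus jittered restarts, all
seeded.

Log model evidence is a Laplace approximation at the MAP with a central
finite-difference Hessian. Because the MAP can sit near the filter's
divergence boundary, the Hessian computation shrinks steps that hit the
boundary, falls back to the prior curvature for coordinates that remain
unusable, and clamps eigenvalues into `[1e-3, 1e7]` before taking the log
determinant (results record `laplace_clamped` when this happens). On
simulated subjects this approximation tracks a brute-force Monte-Carlo
evidence (40k prior draws) to within one or two log units.

Group-level comparison uses random-effects Bayesian model selection: a
variational Dirichlet posterior over model frequencies, exceedance
probabilities by Monte-Carlo sampling of that Dirichlet (default 1e6
seeded samples), the Bayes omnibus risk (BOR) from the free-energy
comparison against the fixed equal-frequency null, and protected
exceedance probabilities `PEP = (1 - BOR) * EP + BOR / K`.

### What the recovery simulations show — and what they cannot

Parameter recovery draws true parameters from the priors, simulates
choices on the default schedule, and refits. Under these generating
conditions the response parameters (`zeta`, `nu`) recover well, the drift
equilibrium `m3` moderately, and `kappa2`/`mu3_0` poorly — the
qualitative ranking expected for this task length. The recovered-estimate
correlation structure shows a positive `kappa2`–`omega2` coupling (the
two parameters jointly set the effective level-2 learning rate, so the
likelihood constrains mainly their combination) of roughly 0.4, and an
`m3`–`mu3_0` trade-off of roughly −0.65 (both place the level-3
trajectory; 170 trials cannot separate the starting point from the
equilibrium). With a prior as wide as `omega2 ~ N(-3, 16)`, many
simulated subjects are behaviourally near-degenerate (no learning, or
noise-dominated choices), which caps all recovery correlations.

Model recovery is intrinsically hard under these conditions: with
`phi3 = 0.1` and `m3` drawn near `mu3_0`, the mean-reverting drift is
behaviourally almost invisible for typical subjects. An exact Monte-Carlo
evidence oracle shows a mean per-subject log Bayes factor of only ~0.3
for the generating mean-reverting model over the standard one, with only
~60% of subjects favouring it. Group BMS therefore selects the
mean-reverting model as the winner (highest frequency and PEP), but the
protected exceedance probability saturates well below certainty — a
property of the generating distribution, not of the selection machinery,
which passes its analytic limit cases exactly.

## Synthetic EEG

Epochs are outcome-locked, −100 to 650 ms at 256 Hz (192 samples), on 64
channels arranged in concentric rings on a unit disc with BioSemi-style
A/B labels. Each epoch is a shared background ERP (fronto-central
negativity ~150 ms, parietal positivity ~320 ms) plus planted linear
effects of the z-scored computational trajectories — per quantity a
Gaussian temporal kernel times a Gaussian spatial patch — plus Gaussian
noise that is smoothed over time (20 ms SD) and mixed across channels
(spatial SD 0.2 disc units) to mimic the smoothness of real scalp data,
then baseline-corrected over −100…0 ms. Per-subject effect amplitudes
combine a group mean, a between-subject SD (0.25 µV/z), and an optional
slope on a standardized psychosocial-functioning covariate. Covariates
(`GF: Social`, `GF: Role`) are integers on a 1–10 scale drawn so that the
cohort median is 9 with interquartile range [8, 9].

Default plant latencies encode the temporal hierarchy the analysis is
meant to recover: volatility precision `pi3` early (326 ms, narrow), cue
and advice PEs mid-latency (441/445 ms), outcome and volatility PEs late
(535 ms). Advice precision `pi2` is planted with zero group amplitude but
a negative covariate slope (−0.8 µV per SD of GF:Social), so the
covariate stage has a group-null effect to find. Amplitudes sit on a
common ~1 µV/z scale chosen for high group-level detection power at 43
subjects where the design allows it; signs follow an FRN-like convention
(cue and outcome PEs negative, the rest positive) so that correlated
quantities reinforce rather than artifactually cancel in the summed scalp
signal. Epochs are stored float32; the baseline-zero property therefore
holds to ~1e-4 µV rather than machine double precision.

The generator emulates clean, artifact-free epochs. Real preprocessing
(filtering, eyeblink projection) is out of scope; an optional
artifact-injection path plants ±100 µV-exceeding blink-like bursts purely
to exercise rejection bookkeeping.

## Single-trial GLMs and inference

First level: per subject, channel and time sample, OLS of amplitude on an
intercept plus a z-scored regressor pair — (delta_c, delta_b),
(|delta1|, pi2), (delta2, pi3) — with an error raised for collinear pairs
(|r| > 0.999) naming the offending regressors. Second level: one-sample
F (squared t) across subjects per channel × time, restricted to 100–550
ms. Family-wise error control replaces Gaussian-random-field theory with
permutation: max-statistic sign-flip permutation for peak-level
inference, and cluster-mass permutation at a primary threshold of
p < 0.001 with clusters defined on the Delaunay channel graph × adjacent
time samples. Phase ERPs are trial means per phase; phase effects are
paired contrasts (S1−V, S1−S2, V−S2) through the same sign-flip
machinery. Covariate maps regress subject-level betas on the
standardized covariate with max-|t| FWE by covariate permutation.

Latency ordering reports each regressor's earliest peak-level-significant
time (falling back to the earliest significant cluster onset) and, as a
robustness check, the peak-F time.

## Limitations

* **Cue–outcome independence.** Because the cue is drawn independently
  of the advice stream, `delta_c` and `delta_b` correlate at ~0.97 across
  trials (real cohorts show substantially lower values): the cue never
  predicts advice accuracy here, so both PEs are dominated by the shared
  outcome term. This makes the cue/outcome design strongly collinear,
  inflating its first-level standard errors ~4×, and is the main reason
  the cue/outcome plants are the hardest to detect.
* **Cross-design leakage.** `delta2` correlates with `|delta1|` at ~0.88
  (the volatility PE is driven by the squared level-2 update). Since the
  two sit in different GLMs, the advice-PE plant projects almost fully
  onto the volatility-PE map; the earliest significant time for `delta2`
  is therefore dragged to within a sample or two of the advice-PE onset.
  Peak-time ordering is robust to this; earliest-onset ordering is not,
  and the latency-ordering recovery rate across simulated cohorts
  reflects it.
* **Desk-scale problem sizes.** The GLM calibration studies use reduced
  cohorts (12 subjects × 48 trials) for type-I-error calibration and the
  full 43 × 170 geometry for power/ordering runs; permutation counts are
  150–500 in the simulation studies and 1000 by default in the pipeline.
* Passing tests demonstrate internal consistency of the generative and
  analysis machinery under these synthetic conditions; they do not
  certify behaviour on recorded EEG, where noise is non-Gaussian,
  non-stationary, and spatially structured by real head geometry.
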