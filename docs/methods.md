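# Methods

## The scientific question

When two moving stimuli fall inside the receptive field of a
direction-selective visual neuron (area MT), its trial-averaged firing
rate is a weighted average of the rates evoked by each stimulus alone.
Two very different single-trial mechanisms produce that same average:

* **response averaging** — on every trial the neuron fires at the
  weighted-average rate;
* **probability mixing** — on each trial the neuron responds to exactly
  one of the stimuli (stimulus 1 with probability `p_c`), so single
  trials look like single-stimulus trials and only the average is a
  blend.

The package fits both models to per-trial spike trains by maximum
likelihood and compares them with information criteria, predictive
accuracy, time-rescaling residuals, and interspike-interval (ISI)
unimodality tests.

## Experimental design emulated by the generator

Four conditions: `fix1` and `fix2` (one pattern alone in aperture 1 or
2, attention at fixation), `attend-fix` (both patterns, attention at
fixation) and `attend-in` (both patterns, attention on the aperture-1
pattern).  Twelve direction configurations step the aperture-1 direction
in 30° increments; the aperture-2 direction is always 120° clockwise
(encoded as −2π/3; the sign is configurable since screen handedness is a
convention).  The analysis window is the 200–700 ms epoch after stimulus
onset re-anchored to 0 (≤ 500 ms, 1 ms resolution), excluding the onset
burst; windows up to 2000 ms are accepted for the boundary-effect study.
Default trials per condition × direction are the experiment's medians:
4, 4, 4 and 12.  Trains are sampled bin-by-bin as Bernoulli events with
probability `clamp(λΔt, 0, 1−1e−12)` with emitted spikes fed back into
the history term, so the generator and the fitted likelihood describe
exactly the same discrete process.  Randomness comes from one root seed
with substreams keyed by (neuron, condition, direction, trial), making
any subset reproducible under reordering.  History before the window
start is taken as spike-free.

## Model

Conditional intensity for a neuron responding to stimulus *l*:

    λ(t|H_t) = r_l · exp( γ0·t + Σ_{i=1..m} γ_i · ΔN_{t−iΔt} ),   m = 10

with rates in spikes/s, `t` in ms, and Δt converted to seconds in every
`λΔt` product (the axis scale of typical MT tuning plots fixes the Hz
convention).  `γ0` is a linear trend (expected slightly negative), and
`γ_1..γ_m` are spike-response weights; a strongly negative `γ_1` is
relative refractoriness.  Tuning is a periodic Gaussian

    r_l = A_l · exp( −‖d−D‖²_{2π} / 2σ_l² ) + r0,

with the preferred direction fixed at D = 0 (directions are measured as
deviations from it; an optional free-D fit is deliberately not exposed so
the parameter count stays 20/19).  Under `attend-in` the amplitudes are
scaled by gains `a_l`.  The mixing model draws stimulus 1 with
probability `p_attend_fix` / `p_attend_in`; the averaging model uses the
rate `p·r1 + (1−p)·r2`, in which only `b1 = p_attend_in·a1` and
`b2 = (1−p_attend_in)·a2` are identifiable — hence 20 free parameters
for mixing and 19 for averaging.  `r0` is shared across apertures and
conditions; because the averaging weights sum to one its baseline stays
`r0`.

The log-likelihood is the discrete sum
`Σ_spikes log λ − Σ_bins λΔt`, evaluated at bin start times with history
up to but excluding the current bin; it agrees with the
conditional-Bernoulli mass function up to a known first-order term (the
test suite asserts the exact relationship).  Mixture trials use
log-sum-exp.  Likelihoods factorize over trials, so estimation is per
neuron.  A rate floor of 1e−10 spikes/s inside logarithms keeps the
objective finite during optimization.

## Fitting

All parameters are estimated simultaneously on an unconstrained scale
(log for positive parameters, logistic clipped at ±30 for
probabilities).  A DIRECT (dividing-rectangles) global stage searches a
physiological box (A ∈ [0.1, 200] sp/s, σ ∈ [0.1, 3] rad,
r0 ∈ [0.1, 100] sp/s, gains ∈ [0.05, 20], γ0 ∈ ±0.02/ms,
γ_i ∈ [−25, 5]; 2000 evaluations by default — no published values exist
for these, so they are engineering choices surfaced in `FitOptions`).
Its best point, together with a moment-based initial guess, seeds an
adaptive Nelder–Mead refinement (fatol 1e−8) that is restarted from its
own optimum until the improvement falls below 0.01, because a single
simplex run in ~20 dimensions routinely stalls short of the optimum.
The mixture likelihood is maximized directly (no EM).  Fits are
deterministic given data and options.

A per-neuron likelihood cache makes one objective evaluation cost one
pass over the bins within 10 ms of a spike plus a closed-form geometric
series for the trend — about 1 ms for ~900 trials — which is what makes
the two-stage search affordable.

## Model selection

AIC `= −2ℓ + 2k` and BIC `= −2ℓ + k·log(n_obs)` are reported with the
neuron's null deviance subtracted (the single-rate model's −2ℓ at the
closed-form MLE `spikes/time`); differences between models are
unaffected.  `n_obs` is the total number of 1 ms bins, the natural
discrete-observation count.  The weight in favor of the lower-criterion
model is `1/(1+exp(−Δ/2))`.  Cohort-level evidence sums per-neuron
log-likelihoods, i.e. sums AIC differences.

Decoding classifies each bidirectional trial to the posterior-maximizing
stimulus (ties → stimulus 1, deterministic).  Predictive accuracy is the
10-fold cross-validated RMSD between each held-out trial's empirical rate
`N/T` and the model rate `(1/T)∫λ` computed with that trial's own spike
history; held-out mixing trials use their decoded component (hard
decoding, not posterior-weighted — the posterior-weighted variant is
available for sensitivity analysis).  CV folds are stratified by
condition × direction and seeded; refits warm-start from the full-data
estimates with a reduced simplex budget.  A neuron is *diagnostic* when
both models' attend-fix weights lie in [0.2, 0.8] or the mixing
attend-in probability does; outside that region the two models mimic
each other and carry little selection information.

## Goodness of fit: time rescaling on a discrete, finite window

If λ is correct, rescaled ISIs `Z_i = ∫ λ` are unit-exponential and the
window total `Z` is a unit-rate Poisson duration with `N` events.  Two
properties of real (and simulated) data break naive uniformity of the
mapped residuals, and the package treats both explicitly:

1. **Discreteness.** At 1 ms bins a rescaled ISI has probability atoms
   of a few percent at physiological rates.  Options: `none` (the
   continuous formula applied verbatim), `midpoint` (exact per-bin
   hazard `−log(1−λΔt)` and the midpoint of each atom — the same
   de-discretization the count level applies by averaging the Poisson
   CDF at N and N−1), `randomized` (a uniform draw within the atom;
   exactly uniform when the model is true).
2. **Window-end censoring.** An ISI is observed only if the next spike
   arrives before the window ends, so long intervals are under-sampled;
   with 500 ms windows and off-preferred rates near r0 = 5 sp/s this
   alone produces KS distances of ~0.05 under the *true* model.
   `truncated` conditions on observability (an observed rescaled ISI is
   truncated-Exp(1) on (0, Z_max]), which removes the effect at any
   window length.  The uncorrected variants deliberately retain it: the
   shrinking of the miscalibration from 500 ms to 2000 ms windows is
   itself a result the pipeline reproduces.

The first interval (window start to first spike) is not an ISI and is
excluded.  Count-level residuals use the Poisson CDF midpoint (or
randomized) transform.  For the mixing model, residuals default to the
decoded component's intensity.

## Dip tests of ISI unimodality

Probability mixing with well-separated component rates makes per-trial
spike counts bimodal; ISI distributions can also turn multimodal when
trials at different rates are pooled, provided the component ISI
densities peak at distinct values.  The dip statistic (maximum distance
between the empirical CDF and the closest unimodal CDF) is computed with
the classical greatest-convex-minorant / least-concave-majorant
algorithm (numba kernel, validated against an independent
linear-programming oracle that minimizes the band width by definition).
P-values are calibrated by bootstrap from the uniform null (default
2000 replicates, seeded) — reproducible and table-free.

Two honest caveats, both verified by the test suite:

* The uniform distribution is the *least favorable* unimodal null, so
  the test is conservative for peaked (exponential-like) ISI samples:
  its realized level on constant-rate spike trains is well below the
  nominal 5% (fractions of a percent at n ≈ 150).  On uniform samples
  the bootstrap level is exact.  The acceptance script reports the
  realized level of this experiment.
* A mixture of two exponential-like ISI densities is itself decreasing,
  hence unimodal: with a short (10 ms) history filter, rate mixing alone
  does not move the component ISI modes apart.  ISI-level dip power
  therefore requires genuinely separated ISI populations (e.g. regular
  firing at two rates), and the power tests use such samples; the
  mixing/averaging contrast is demonstrated on per-trial spike counts,
  which are bimodal under mixing.  Exact ties (integer counts) must be
  dithered first, since the dip test reads discreteness as multimodality.

The grid analysis pools, per neuron × direction configuration, the
fix1+fix2 ISIs after multiplying each condition's ISIs by that cell's
mean rate (preventing artificial bimodality from unequal aperture
responses — normalization is per neuron, condition and direction
configuration, the finest grid that matches the lattice of tests);
bidirectional cells are tested raw.  Cells with fewer than 4 ISIs or a
single distinct value are marked untestable, not failed.  Firing-rate
dip tests are deliberately not offered at the grid level (short windows
make empirical rates too discrete).

## Auxiliary analyses

* **Pair correlations.** For simultaneously recorded pairs, Spearman
  rank correlation of per-trial rates per direction configuration, with
  the two attention conditions pooled; under coupled mixing (both
  neurons select the same stimulus) pairs with shared direction
  preference correlate positively, pairs with opposed rate orderings
  negatively.  Cells with fewer than 5 aligned trials are untestable.
* **Split-half stationarity.** The full fit+selection pipeline is rerun
  on the 0–250 ms and 250–500 ms half-windows; a paired two-sided
  Wilcoxon signed-rank test (exact null below n = 26) compares the
  AIC/BIC differences between halves.  Neurons with a spikeless half are
  dropped and logged.

## Generator defaults and test-harness problem sizes

The canonical simulated neuron uses A1 = 40, A2 = 10 sp/s, σ = 1.2 rad,
r0 = 5 sp/s, p_attend_fix = 0.5, p_attend_in = 0.7, a1 = 1.5, a2 = 0.8,
γ1 = −3, γ0 = −5e−4/ms — a strong, refractory neuron in the regime where
the two models are clearly distinguishable.  The heterogeneous-cohort
prior draws around typical MT values (documented in
`design.sample_ground_truth`).

The package's own validation harness runs at sizes chosen as its
defaults: recovery/selection cohorts of 10 mixing- and 8
averaging-generated neurons at three times the median trial counts
(12/12/12/36 per direction), dip-level calibration with 1000 simulated
neurons, residual calibration on ~1e4 ISIs, and the boundary-effect
study on single neurons at 500 vs 2000 ms.  Medians across a cohort of
10 are what the recovery criteria assess; the estimator itself is
per-neuron and independent of cohort size.

## What passing tests do and do not show

The generator reproduces the design's structure (conditions, direction
grid, trial counts, windowing, refractoriness, attentional gain, latent
stimulus identity fixed within a trial) but deliberately omits features
of real recordings: onset transients (the modeled window starts after
them), overdispersion from trial-to-trial parameter drift, within-trial
attentional switching (a 500 ms trial keeps one latent stimulus; a
switching variant is out of scope), eye-movement artifacts, and
recording noise.  Passing recovery and calibration tests therefore show
the estimator and diagnostics are correct *under the model class*, not
that cortical data satisfy the model.  ISI-level dip results on real
data may also reflect burst structure at timescales longer than the
10 ms history filter, which this model cannot produce.

## Known limitations

* No standard errors or Hessian-based confidence intervals are reported.
* The averaging model's `(p, a1, a2)` cannot be separated (only b1, b2);
  this is intrinsic, not numerical.
* Nelder–Mead with restarts is robust but slow near 20 dimensions;
  budgets trade precision for time and are exposed in `FitOptions`.
* The dip test's conservativeness for peaked nulls is a property of the
  uniform calibration, not a bug; interpret grid fractions relative to
  matched simulations rather than the nominal level.
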