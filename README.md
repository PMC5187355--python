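# spikemix

**Do visual neurons average multiple stimuli in their receptive field, or
do they respond to one stimulus at a time?**

When two moving random-dot patterns share the receptive field of an MT
(middle temporal area) neuron, the trial-averaged firing rate is a
weighted average of the single-stimulus rates.  That average is equally
consistent with two opposite single-trial mechanisms:

* **response averaging** — every trial fires at the blended rate
  `r = p·r1 + (1−p)·r2`;
* **probability mixing** — each trial the neuron commits to *one*
  stimulus (stimulus 1 with probability `p`), so single trials look like
  single-stimulus responses and only the across-trial mean is a blend.

`spikemix` is a library for telling these apart from per-trial spike
trains.  It models trains as discrete-time point processes with
conditional intensity

```
λ(t|H_t) = r_l · exp( γ0·t + Σ_{i=1..10} γ_i · ΔN_{t−i} ),
r_l = A_l · exp( −‖d−D‖²_2π / 2σ_l² ) + r0,
```

(periodic Gaussian direction tuning, attentional amplitude gains `a_l`
under attention, linear trend, 10 ms spike-history filter), fits both
competing models per neuron by maximum likelihood (DIRECT global search +
Nelder–Mead refinement over all ~20 parameters simultaneously), and
compares them with null-referenced AIC/BIC and Akaike-type weights,
10-fold cross-validated rate prediction (RMSD), time-rescaling
goodness-of-fit with explicit discreteness and finite-window corrections,
posterior decoding of the per-trial stimulus, dip tests of ISI
multimodality, trial-by-trial pair correlations, and a split-half
stationarity check.  A synthetic-data generator emulates the underlying
two-aperture attention experiment (4 conditions × 12 direction
configurations × ≤500 ms windows at 1 ms resolution) and samples from
either model, providing ground truth for every stage.

Intended users: systems/computational neuroscientists analysing
single-unit responses to multiple stimuli, and statisticians interested
in trial-level mixture point-process modelling.

## Worked example

`examples/01_simulate_and_fit.py` simulates one strongly-tuned,
refractory neuron from the probability-mixing model (576 trials, ~5200
spikes) and refits it:

```
parameter          true  estimate
A1 (sp/s)        40.000    41.912
A2 (sp/s)        10.000     9.654
sigma1 (rad)      1.200     1.232
r0 (sp/s)         5.000     4.979
p_attend_fix      0.500     0.493
p_attend_in       0.700     0.674
a1                1.500     1.431
a2                0.800     0.864
gamma1           -3.000    -2.987
```

All parameters are recovered within a few percent; `p_attend_in >
p_attend_fix` and `a1 > 1` are the attentional shift toward the cued
stimulus, and `gamma1 ≈ −3` is the refractory suppression in the
millisecond after a spike.  `examples/03_goodness_of_fit.py` shows the
single-trial discrimination the package exists for — on the same data:

```
count residuals under mixing (true)     : KS D = 0.024, p = 0.89
count residuals under averaging (wrong) : KS D = 0.116, p = 3.2e-07
```

the response-averaging model is rejected from spike-count residuals even
though both models predict identical trial-averaged rates.  The other
examples cover model selection on a cohort (`02`) and single-trial
decoding plus dip tests (`04`).

A thin CLI mirrors the pipeline stages
(`spikemix simulate|validate|fit|dip|run-all`), writing CSV/JSON bundles.

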