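"""Single-trial stimulus decoding and dip tests of multimodality.

Simulates a mixing neuron, decodes which stimulus each bidirectional
trial responded to from the fitted model, scores the decoding against the
stored latent labels, and runs a dip test on the per-trial firing rates
(dithered) to show the bimodality that probability mixing induces.
"""

import numpy as np

import spikemix as sm
from spikemix.fitting import FitOptions

design = sm.build_design(
    trials_per_cell={"fix1": 6, "fix2": 6, "attend-fix": 6, "attend-in": 18}
)
truth = sm.default_ground_truth("mixing")
records, labels = sm.simulate_dataset(design, truth, 1, seed=5)

fit = sm.fit_neuron(records, "mixing",
                    FitOptions(direct_maxfun=1000, nm_maxfev=3000))
decoded = sm.decode_trials(records, fit.params)
hits = total = 0
for d in decoded:
    key = ("n000", d.condition, d.direction_index, d.trial_index)
    if key in labels:
        total += 1
        hits += d.label == labels[key]
print(f"decoded {total} bidirectional trials; "
      f"label recovery {100 * hits / total:.1f}%")

# dip test on per-trial rates at the preferred-direction configuration
rng = np.random.default_rng(0)
rates = np.array([
    r.train.n_spikes / (r.train.T / 1000) for r in records
    if r.condition == "attend-in" and r.direction_index == 1
])
sample = rates + rng.uniform(-1, 1, rates.size)  # dither tied counts
res = sm.dip_test(sample, n_boot=2000, seed=1)
print(f"dip test of attend-in firing rates at the preferred direction: "
      f"dip = {res.statistic:.3f}, p = {res.p_value:.3f}")
print("High decoding accuracy and a small dip p-value are the two "
      "single-trial signatures of probability mixing: trials split into "
      "stimulus-1-like and stimulus-2-like responses.")
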