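"""Time-rescaling goodness of fit: right model vs wrong model.

Simulates one strongly-mixing neuron, then computes count-level uniform
residuals twice -- under the generating (mixing) parameters and under the
matched response-averaging parameters -- and compares their KS distances
from the uniform distribution.  Also demonstrates the finite-window
correction at the ISI level.
"""

import numpy as np
from scipy import stats

import spikemix as sm
from spikemix.gof import residuals_for_neuron

design = sm.build_design(
    trials_per_cell={"fix1": 8, "fix2": 8, "attend-fix": 8, "attend-in": 24}
)
truth = sm.default_ground_truth("mixing")
records, _ = sm.simulate_dataset(design, truth, 1, seed=3)

avg_params = sm.ModelParams(
    "averaging", truth.params.tuning, truth.params.attn.as_averaging(),
    truth.params.history,
)

for label, params in (("mixing (true)", truth.params),
                      ("averaging (wrong)", avg_params)):
    rs = residuals_for_neuron(records, params, level="count",
                              correction="randomized")
    d, p = rs.ks_uniform()
    print(f"count residuals under {label:18s}: KS D = {d:.3f}, p = {p:.2g}")

rs = residuals_for_neuron(records, truth.params, level="isi",
                          correction="truncated")
d, p = rs.ks_uniform()
print(f"ISI residuals (finite-window corrected, true model): "
      f"KS D = {d:.3f}, p = {p:.2g}")

print("\nThe wrong model's count residuals pile up away from uniform "
      "(small p): single trials carry enough information to reject "
      "response averaging even though both models share the same "
      "trial-averaged rates.")
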