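"""Deterministic-learning identification of the slow adaptation dynamics.

Identifies f3(x) = r (s0 (x1 - q0) - x3) of the fast-spiking neuron
(I = 4, order 0.98) along its orbit, freezes the converged weights, and
reports the along-orbit approximation error — without ever handing the
estimator the model constants.
"""

import numpy as np

from fohrlearn import HRParameters, hr_vector_field
from fohrlearn.experiments import identify_pattern
from fohrlearn.learning import orbit_settling_ratio

pattern, results, orbit = identify_pattern(I=4.0, pattern_id="chi4", dims=(2,))
res = results[2]

t_end = orbit.times[-1]
window = orbit.window(t_end - 300.0, t_end)
approx = np.asarray(pattern.evaluate(2, window.states))
truth = np.array([hr_vector_field(s, HRParameters(I=4.0))[2] for s in window.states])
rel = np.abs(approx - truth).mean() / np.sqrt((truth**2).mean())
settle = orbit_settling_ratio(res, pattern.network(2), orbit)

print(f"adaptation run: {orbit.times[-1]:g} time units, "
      f"{res.snap_weights.shape[1]} lattice nodes")
print(f"along-orbit |W̄ᵀφ - f3| = {100 * rel:.2f}% of RMS f3")
print(f"weight secular trend over the averaging window: {100 * settle:.2f}%")
print("The frozen weights reproduce the unknown slow dynamics along the")
print("orbit; away from it the Gaussian lattice decays to zero (learning")
print("is local, which is exactly what the recognition stage exploits).")
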