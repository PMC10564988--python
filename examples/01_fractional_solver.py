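"""Grünwald-Letnikov differintegration and the fractional solver.

Differentiates a monomial at half order against the analytic power rule,
then integrates the fractional relaxation equation and compares it with
the Mittag-Leffler function it should follow.
"""

import math

import numpy as np

from fohrlearn import MemoryPolicy, TimeGrid, gl_derivative, solve_fode

# D^{1/2} of t^2 on [0, 1]: the power rule gives Gamma(3)/Gamma(2.5) t^{3/2}
h = 1e-3
t = np.arange(0.0, 1.0 + h / 2, h)
deriv = gl_derivative(t**2, q=0.5, h=h)
exact = math.gamma(3) / math.gamma(2.5) * t[-1] ** 1.5
print(f"D^0.5 t^2 at t=1: computed {deriv[-1]:.6f}, power rule {exact:.6f}")

# fractional relaxation D^{1/2} x = -x, x(0) = 1
grid = TimeGrid.from_duration(1.0, 1e-3)
traj = solve_fode(lambda x, t: -x, q=0.5, x0=[1.0], grid=grid,
                  policy=MemoryPolicy(mode="full"))
ml = sum((-1.0) ** k / math.gamma(0.5 * k + 1) for k in range(200))
print(f"x(1): solver {traj.states[-1, 0]:.6f}, Mittag-Leffler E_0.5(-1) {ml:.6f}")
print("The solver tracks the fractional relaxation law, not the exponential",
      f"exp(-1) = {math.exp(-1):.6f} of the integer-order equation.")
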