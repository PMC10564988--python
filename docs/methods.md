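# Methods

## Model

The package simulates the three-variable Hindmarsh-Rose (HR) neuron and
its fractional-order generalization (FOHR),

    D^q x1 = x2 - a x1^3 + b x1^2 - x3 + I
    D^q x2 = c - d x1^2 - x2
    D^q x3 = r (s0 (x1 - q0) - x3)

with `x1` the membrane potential, `x2` the fast K+ recovery variable and
`x3` the slow Ca2+ adaptation current. `D^q` is the Grünwald-Letnikov
(GL) differintegral of order `0 < q <= 1`; at `q = 1` the classical model
is recovered. Defaults are the classic bursting constants `a=1, b=3,
c=1, d=5, r=0.006, s0=4, q0=-1.6` (the package constant `hr_c` names the
HR `c` to avoid colliding with the sliding-surface gain). Under these
constants the stimulation current drives the canonical regime staircase
— slow period-1 spiking near `I=1.5`, period-2/3/4 bursting at
`I=1.8/2.3/2.8`, chaotic discharge around `I=3.2`, fast spiking beyond
`I=3.5` — which the acceptance suite reproduces end to end. All times
are the model's dimensionless units (read as milliseconds in the control
scenarios).

## Fractional solver

`gl_derivative` implements the GL operator literally: binomial weights
`c_r = (-1)^r C(q, r)` by the O(n) recursion, applied to the raw signal
history (FFT convolution). `solve_fode` advances `D^q x = f(x, t)` by
the fixed-step explicit scheme

    x_k = f(x_{k-1}, t_k) h^q - sum_{r=1..min(k, L)} c_r x_{k-r},

which is explicit Euler at `q = 1`. By default the history sum acts on
the deviation `x - x(0)` ("deviation" mode): for constant initial data
this makes the scheme Caputo-consistent, so the linear relaxation test
`D^q x = -x, x(0) = 1` converges to the Mittag-Leffler law `E_q(-t^q)`
at O(h). Summing raw states ("raw" mode) is available; it collapses a
nonzero initial state in Riemann-Liouville fashion and is only
equivalent for `x(0) = 0`.

The short-memory policy truncates the history at the smallest lag `L`
whose dropped coefficient tail satisfies `|sum_{r>L} c_r| < 1e-6` (the
weights of order `q > 0` sum to zero, so the tail equals the leading
partial sum). For `q = 0.98` and `h = 0.01` this gives `L ≈ 25,000`
lags, i.e. a 250-time-unit moving window; regime classification is
verified stable under doubling `L` and halving `h`. The sliding-surface
differintegral of order `1-q = 0.02` decays far too slowly to truncate
and always runs with full memory. A high-accuracy classical reference
(`solve_ivp`/LSODA on the same grid) backs all `q = 1` work and the
solver cross-checks.

Caveat surfaced by the cross-validation work: discharge regimes at
orders just below 1 are sensitive to the FO discretization itself.
Burst counts at `q = 0.98` from a converged GL/Euler scheme differ by
one spike per burst from counts produced by slightly "more integer"
schemes (equivalent to `q ≈ 0.99`, or to aggressive memory truncation).
The package reports its own converged classifications and treats them
as the ground truth of this implementation.

## Spike and regime analysis

Spikes are local maxima of `x1` above a 0.0 threshold separated by at
least 1.0 time units (HR spikes rise well above zero; sub-threshold
ripple stays below). Burst segmentation places the cut inside the
widest multiplicative gap of the sorted inter-spike intervals and splits
where an ISI exceeds the geometric midpoint of that gap, provided the
gap ratio exceeds `gap_factor = 2`; a fixed multiple of the median ISI
is *not* used because for two-spike bursts the median straddles the two
ISI scales and misses the inter-burst gap. A trajectory is labelled

* `spiking` — every burst holds one spike;
* `period-n bursting` — a modal burst size `n` holds a >= 90% share and
  the ISI multiset rounds (bin 0.5) to at most 20 distinct values;
* `chaotic` — otherwise (many distinct ISIs, no repeating burst size).

The chaos call is a reproducible proxy for the visual label, not a
Lyapunov computation. The first half of every run is discarded as
transient; classification is checked invariant to doubling the run and
halving the step. Bifurcation scans restart each grid point from the
same initial state (independent-run diagrams, no continuation) and
record per-point failures without aborting the scan.

## Deterministic-learning identification

Each right-hand-side component `f_i` is identified along one measured
orbit by the estimator / weight-law pair

    D^q x̂_i = -a_i (x̂_i - x_i) + Ŵᵀ φ(z_i),
    Ŵ̇      = -Γ φ(z_i) x̃_i - σ Γ Ŵ,      x̃_i = x̂_i - x_i,

with Gaussian regressors `φ_j = exp(-Σ_d (z_d - c_jd)² / η_d²)` on an
even lattice. The squared-exponent form is used throughout (required by
the Schoenberg kernel properties that underpin the persistent-excitation
argument). The estimator runs at the plant's order `q` so the converged
`W̄ᵀφ` approximates the *fractional* right-hand side; an integer-order
estimator is a config option. The weight law is an ordinary ODE,
stepped with explicit Euler at the plant step.

Inputs per component follow the HR dependency structure: `f1(x1,x2,x3)`,
`f2(x1,x2)`, `f3(x1,x3)`. The `f3` lattice is the canonical 15x15 grid
on `[-2.1, 2.1] x [0.9, 5.1]` (spacing and width 0.3) — the box the
training orbits fill in the `(x1, x3)` plane. The `f1`/`f2` lattices
are derived per orbit: 15 nodes per axis over the post-transient
bounding box padded 10%, with per-axis widths equal to the spacing (a
neighbour sits at `exp(-1)`).

Gains are `a_i = 10`, `Γ = 2`, `σ = 1e-4`, zero initial weights,
estimator states deliberately started off the plant. With these gains
convergence is pass-limited, so the adaptation horizon scales with the
orbit's recurrence period: 9,000 / 10,000 / 6,000 / 2,000 time units for
the slow-spiking (`I=1.5`), bursting (`I=2.5`), chaotic-side (`I=3.6`)
and fast-spiking (`I=4`) training orbits respectively (recurrence
periods roughly 150 / 110 / 30 / 21 units; the third orbit gets extra
margin). Constant weights `W̄` are the arithmetic mean of the weight
history over the trailing 25% of the run.

Two diagnostics qualify a run as converged, both computed by the tests
and the acceptance script:

* along-orbit accuracy — mean `|W̄ᵀφ - f_i|` over a trailing stretch of
  the training orbit, relative to the RMS of `f_i` there (the guarantee
  is local: off-orbit accuracy is never asserted);
* weight settling — the secular trend (difference of half-window means)
  of the weight subvector actually excited by the trailing orbit (mean
  regressor above 5% of the maximum), reported relative to the excited
  subvector's excursion scale. Converged weights keep oscillating with
  the orbit's recurrence, nodes touched only during the approach
  transient drain under the σ-modification on a `1/(σΓ) = 5000`-unit
  timescale, and near-zero weakly-excited nodes never stop creeping at
  their own noise floor; none of these is a failure of convergence, so
  none enters the statistic.

Patterns freeze `W̄`, the lattice, the widths and the run metadata per
state dimension; a pattern base is a JSON container of patterns with
stable ids (`chi1..chi4` for the canonical training set at currents
1.5, 2.5, 3.6, 4.0 and order 0.98).

## Rapid recognition

Each stored pattern `k` drives one scalar estimator along the observed
orbit, `D^q x̄_k = -b (x̄_k - x_i) + W̄_kᵀ φ(z_i)`, starting on the
observation so the tracking error starts at zero. The similarity of a
pattern is the trailing average-L1 norm of its error over a window `T`;
the winner is the argmin, ties breaking to the earliest pattern. `b`
defaults to 10 (matching the identification leak gain); `T` defaults to
one recurrence period estimated from the observed ISI structure (the
longest inter-event gap), falling back to 50 time units for sparse or
degenerate records. The no-match threshold `τ` is disabled by default
(`None` = always match) and config-exposed; a practical setting is a
few times the largest training self-similarity. The bank runs at the
patterns' stored order; because every pattern shares the same `f3`, the
third-dimension measure discriminates purely through orbit locality —
the winning pattern is the one *trained where the observation lives*.
Summed all-dimension similarity is available but is a worse default
here: the large-magnitude `f1`/`f2` mismatches swamp the locality
signal.

## Sliding-mode synchronization

Errors `e = x_s - x_m` feed the fractional proportional-integral surface
`s_i = c_i D^{1-q} e_i + e_i` (identity at `q = 1`), computed from the
stored error history with full memory. The model-based law is

    u_i = -η_i sgn(s_i) - c_i e_i + f_{m,i}(x_m) - f̂_{s,i}(x_s),

zero-order-held over each solver step, with pure `sgn` by default and an
optional boundary layer `s/(|s| + ε)`. Compensation `f̂_s` is the
recognized pattern (default), a forced pattern, the true slave field
(ablation upper bound) or zero (pure robust SMC). Relearning mode
switches selected dimensions (default: the third) to live weights
initialized from the recalled pattern and adapted by
`Ŵ̇ = Γ φ s - σ Γ |s| Ŵ` (explicit Euler); the update vanishes exactly
on the surface. The canonical scenario: master `I=1.5`, slave `I=3.8`,
disturbances `d1 = 0.6 + 0.2 cos t`, `d2 = 0`, `d3 = 0.01 + 0.05 sin t`
(declared bounds 0.8 / 0 / 0.06, verified by sampling), both neurons
from `(0.3, 1, 3)`, gains `η = 1`, `c = 1`, `Γ = 2`, `σ = 0.01`,
control on at `t = 300` of 600, relearning switch at `t = 500`.

The reaching condition is empirical, not symbolic: with `η` above the
measured disturbance-plus-residual bound the sliding variables settle
into a chatter band of width about `η h^q`; far below it they never
converge. The acceptance suite exercises both sides with true-dynamics
compensation, which isolates the disturbance as the only residual.

## What the synthetic conditions do and do not show

Every input is generated by the model itself; there is no randomness
anywhere in the pipeline (identical configs are bit-reproducible), and
no measurement noise, parameter drift or unmodelled channel dynamics.
Passing tests therefore demonstrate the *mechanisms* — GL convergence,
PE-driven weight convergence, locality-based recognition, sliding-mode
reaching — under clean conditions, not robustness to real
electrophysiological data.

The clean conditions also expose a structural limitation honestly: a
pattern learned on one attractor compensates poorly on another. In the
canonical scenario the recognized fast-spiking pattern is accurate on
the slave's own orbit (`x3 ≈ 4`) but the controller drives the slave
onto the master's orbit (`x3 ≈ 1.5`), where the pattern's Gaussian
lattice was never excited and its output decays to zero. The residual
then exceeds a unit reaching gain, leaving a moderate steady error where
true-dynamics compensation reaches the chatter floor — the ablation
trio (true / recognized / deliberately-wrong pattern) quantifies exactly
this gap, and the relearning mode exists to close it by adapting the
recalled weights along the synchronized trajectory.

## Numerical bookkeeping

* Lattice axes are generated inclusive of both endpoints with a 1e-9
  guard on the point count; tensor-grid regressors factorize per axis,
  so evaluation costs per-axis exponentials plus an outer product.
* Weight snapshots are thinned to about 1,200 rows per run regardless of
  length; the averaging window always contains hundreds of samples.
* Divergence anywhere (non-finite state, weight norm beyond bound)
  raises a typed error naming the step or time; bifurcation scans record
  the error and continue.
* Trajectory CSV files are written at full float precision and re-read
  with round-trip parsing, so file round trips are bit-exact.
* Empty spike trains, single-spike ISI sequences and degenerate lattice
  axes are legal inputs with defined results (empty arrays, widened
  bands); too-few post-transient spikes raise an insufficient-data
  error rather than guessing a regime.
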