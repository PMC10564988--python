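# fohrlearn

Learning-based synchronization of fractional-order Hindmarsh-Rose
neurons: simulate, identify, recognize, control.

Abnormal synchronization between neurons is implicated in disorders from
Parkinson's disease to epilepsy, and the Hindmarsh-Rose (HR) model is
the workhorse for studying it in silico. This package implements the
full computational stack for a *learning-based* approach to the
master-slave synchronization problem when the slave neuron's dynamics
are unknown: instead of a high-gain robust controller, the unknown
dynamics are first learned along recurrent orbits, stored as constant
neural-network weights, recalled by a rapid recognition step, and
plugged into a sliding-mode controller. It is written for computational
neuroscientists and control researchers who want a reproducible,
inspectable reference implementation of each stage.

## What is inside

The fractional-order HR neuron

    D^q x1 = x2 - a x1^3 + b x1^2 - x3 + I
    D^q x2 = c - d x1^2 - x2
    D^q x3 = r (s0 (x1 - q0) - x3)

is integrated with a Grünwald-Letnikov fixed-step scheme
(`x_k = f(x_{k-1}) h^q - Σ_r c_r x_{k-r}`, explicit Euler at `q = 1`)
with a short-memory policy and a classical adaptive reference for
cross-checks. On top of it:

* **Discharge analysis** — spike detection, inter-spike-interval (ISI)
  and peak-amplitude sequences, period-n bursting / chaos
  classification, bifurcation scans over `q`, `I` and `r`.
* **Deterministic learning** — dynamical RBF estimators
  `D^q x̂ = -a(x̂ - x) + Ŵᵀφ(x)` with the σ-modified gradient weight
  law; along a recurrent orbit the excited weights converge and are
  frozen into a constant-weight *dynamic pattern* (`W̄ᵀφ`), locally
  accurate along that orbit.
* **Rapid recognition** — a bank of estimators, one per stored pattern,
  driven by an observed trajectory; the trailing average-L1 tracking
  error is the similarity measure, and the argmin pattern is recalled
  with no re-training.
* **Sliding-mode synchronization** — fractional PI surface
  `s = c D^{1-q} e + e`, reaching law `-η sgn(s)`, feedforward from the
  recalled pattern (`u = -η sgn(s) - c e + f_m - W̄ᵀφ`), plus a
  relearning mode that adapts the recalled weights online through
  `Ŵ̇ = Γ φ s - σ Γ |s| Ŵ`.

## A two-minute tour

```bash
python examples/02_discharge_regimes.py
```

prints the classic regime staircase of the integer-order neuron:

```
I      regime
1.5    period-1 spiking
1.8    period-2 bursting
2.3    period-3 bursting
2.8    period-4 bursting
3.2    chaotic
3.58   period-1 spiking
```

— one line per stimulation current: the neuron adds one spike per burst
at each step of the staircase, passes through a chaotic window, and
returns to (fast) regular spiking. And

```bash
python examples/01_fractional_solver.py
```

checks the fractional machinery against closed forms:

```
D^0.5 t^2 at t=1: computed 1.503941, power rule 1.504506
x(1): solver 0.427502, Mittag-Leffler E_0.5(-1) 0.427584
```

the half-order derivative of `t²` lands on the fractional power rule,
and the relaxation equation `D^0.5 x = -x` follows the Mittag-Leffler
decay (0.4276), not the exponential (0.3679) — the memory of the
fractional operator slows the decay exactly as theory says.

The remaining examples walk the full pipeline: `03` bifurcation scans,
`04` identification of unknown dynamics (prints the along-orbit
approximation error), `05` recognition of an unseen neuron against the
stored base, `06` master-slave synchronization with recalled vs true
dynamics, `07` the relearning controller. A thin CLI mirrors them
(`fohr simulate`, `fohr bifurcate`, `fohr build-base`, `fohr recognize`,
`fohr synchronize`, `fohr run <experiment>`); every run logs its
resolved configuration next to its outputs.

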