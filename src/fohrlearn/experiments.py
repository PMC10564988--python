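"""Canonical fixtures and end-to-end experiment drivers.

Everything here is generated from the model itself — no external data.
The catalog pins the study conditions used throughout the package:

* training patterns ``chi1..chi4`` (stimulation currents 1.5, 2.5, 3.6,
  4.0 at order q = 0.98): slow spiking, bursting, chaotic bursting and
  fast spiking exemplars whose dynamics are identified and frozen into
  the pattern base;
* testing patterns ``chi5..chi8`` (currents 1.43, 2.3, 3.4, 4.2) used
  only for recognition;
* the master-slave synchronization scenario ``sync_mismatch`` (master at
  I = 1.5, disturbed slave at I = 3.8, control from t = 300) and its
  relearning variant ``relearn_mismatch`` (switch to live weights at
  t = 500).

Identification runs long enough for the weights to settle; since the
adaptation gain is fixed, the run length scales with the orbit's
recurrence period (slow-spiking and bursting orbits revisit each lattice
region far less often than fast-spiking ones, and chaotic orbits need
extra passes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .control import ControllerConfig, SyncResult, synchronize
from .fractional import MemoryPolicy, TimeGrid
from .hindmarsh_rose import (
    DisturbanceSpec,
    HRParameters,
    MasterSlaveSystem,
    simulate_hr,
)
from .learning import (
    DynamicPattern,
    IdentificationResult,
    LatticeSpec,
    LearningConfig,
    PatternBase,
    PatternDimension,
    build_lattice,
    identify_dynamics,
    DEFAULT_INPUT_DIMS,
)
from .recognition import RecognitionConfig, SimilarityReport, recognize
from .spikes import AnalysisConfig, RegimeLabel, classify_simulated
from .trajectory import Trajectory

__all__ = [
    "TRAINING_CURRENTS",
    "TESTING_CURRENTS",
    "Q_CANONICAL",
    "X0_LEARNING",
    "X0_BIFURCATION",
    "H_CANONICAL",
    "CANONICAL_F3_LATTICE",
    "identification_duration",
    "simulate_orbit",
    "identify_pattern",
    "build_training_base",
    "recognize_current",
    "sync_system",
    "run_sync",
    "regime_table",
    "EXPERIMENTS",
    "run_experiment",
]

# -- canonical study conditions ---------------------------------------------

Q_CANONICAL = 0.98
H_CANONICAL = 0.01
X0_LEARNING = (0.3, 1.0, 3.0)  # identification / recognition / control runs
X0_BIFURCATION = (0.1, 1.0, 0.2)  # regime and bifurcation work

TRAINING_CURRENTS: dict[str, float] = {
    "chi1": 1.5,  # slow spiking
    "chi2": 2.5,  # bursting
    "chi3": 3.6,  # chaotic-side exemplar
    "chi4": 4.0,  # fast spiking
}
TESTING_CURRENTS: dict[str, float] = {
    "chi5": 1.43,
    "chi6": 2.3,
    "chi7": 3.4,
    "chi8": 4.2,
}

# the f3 lattice: evenly spaced centers on [-2.1, 2.1] x [0.9, 5.1],
# spacing and width 0.3 — the box the training orbits fill in (x1, x3)
CANONICAL_F3_LATTICE = LatticeSpec(((-2.1, 2.1, 0.3), (0.9, 5.1, 0.3)))
F3_WIDTH = 0.3

# Adaptation horizons per training pattern.  The adaptation gain is fixed
# (Γ = 2), so weight convergence needs a fixed number of orbit passes;
# the horizon scales with the recurrence period (about 150 time units for
# the slow-spiking orbit, 110 for the bursting one, 30 and 21 for the
# chaotic and fast-spiking ones, the chaotic case getting extra margin).
IDENTIFICATION_DURATIONS: dict[str, float] = {
    "chi1": 9000.0,
    "chi2": 10000.0,
    "chi3": 6000.0,
    "chi4": 2000.0,
}
DEFAULT_IDENTIFICATION_DURATION = 4000.0


def identification_duration(pattern_id: str | None) -> float:
    if pattern_id is None:
        return DEFAULT_IDENTIFICATION_DURATION
    return IDENTIFICATION_DURATIONS.get(pattern_id, DEFAULT_IDENTIFICATION_DURATION)


def sync_disturbances() -> DisturbanceSpec:
    """The canonical bounded slave disturbances of the control scenario."""
    return DisturbanceSpec(
        d1=lambda t: 0.6 + 0.2 * math.cos(t),
        d2=lambda t: 0.0,
        d3=lambda t: 0.01 + 0.05 * math.sin(t),
        bounds=(0.8, 0.0, 0.06),
    )


# -- orbits and identification ----------------------------------------------


def simulate_orbit(
    I: float,
    q: float = Q_CANONICAL,
    duration: float = 1000.0,
    h: float = H_CANONICAL,
    x0: Sequence[float] = X0_LEARNING,
    policy: MemoryPolicy = MemoryPolicy(),
) -> Trajectory:
    """One autonomous FOHR orbit at stimulation current I."""
    return simulate_hr(
        HRParameters(I=I), q, x0, TimeGrid.from_duration(duration, h), policy
    )


def _auto_lattice(orbit: Trajectory, input_dims: tuple[int, ...]) -> LatticeSpec:
    """15-points-per-axis lattice over the post-transient orbit box, padded 10%."""
    span = orbit.times[-1] - orbit.times[0]
    post = orbit.window(orbit.times[0] + 0.5 * span, orbit.times[-1])
    sub = post.states[:, list(input_dims)]
    return LatticeSpec.from_box(sub.min(axis=0), sub.max(axis=0))


def identify_pattern(
    I: float,
    pattern_id: str,
    q: float = Q_CANONICAL,
    duration: float | None = None,
    h: float = H_CANONICAL,
    dims: tuple[int, ...] = (0, 1, 2),
    config: LearningConfig = LearningConfig(),
    orbit: Trajectory | None = None,
) -> tuple[DynamicPattern, dict[int, IdentificationResult], Trajectory]:
    """Identify the FOHR right-hand side along one orbit and freeze it.

    The f3 regressor lattice is the canonical box; the f1 / f2 lattices
    are derived from the orbit's own bounding box.  Estimator states
    start at 0 (deliberately off the plant) and weights at zero.
    """
    if duration is None:
        duration = identification_duration(pattern_id)
    if orbit is None:
        orbit = simulate_orbit(I, q, duration, h)
    results: dict[int, IdentificationResult] = {}
    pattern_dims: dict[int, PatternDimension] = {}
    for dim in dims:
        input_dims = DEFAULT_INPUT_DIMS[dim]
        if dim == 2:
            spec, widths = CANONICAL_F3_LATTICE, np.full(2, F3_WIDTH)
        else:
            spec = _auto_lattice(orbit, input_dims)
            widths = spec.spacings
        net = build_lattice(spec, widths)
        res = identify_dynamics(
            orbit, dim, net, config, q=q, input_dims=input_dims, xhat0=0.0
        )
        results[dim] = res
        pattern_dims[dim] = PatternDimension(
            input_dims=input_dims,
            lattice=spec,
            widths=widths,
            weights=res.constant_weights,
        )
    pattern = DynamicPattern(
        id=pattern_id,
        dims=pattern_dims,
        metadata={
            "I": I,
            "q": q,
            "h": h,
            "duration": duration,
            "x0": list(X0_LEARNING),
            "params": {
                k: getattr(HRParameters(I=I), k)
                for k in ("a", "b", "hr_c", "d", "r", "s0", "q0")
            },
        },
    )
    return pattern, results, orbit


def build_training_base(
    path: str | Path | None = None,
    q: float = Q_CANONICAL,
    durations: Mapping[str, float] | None = None,
    dims: tuple[int, ...] = (0, 1, 2),
    config: LearningConfig = LearningConfig(),
    keep_results: bool = False,
) -> PatternBase | tuple[PatternBase, dict]:
    """Identify chi1..chi4 and assemble (optionally write) the pattern base."""
    base = PatternBase()
    all_results: dict[str, dict] = {}
    for pid, I in TRAINING_CURRENTS.items():
        dur = None if durations is None else durations.get(pid)
        pattern, results, orbit = identify_pattern(
            I, pid, q=q, duration=dur, dims=dims, config=config
        )
        base.add(pattern)
        if keep_results:
            all_results[pid] = {"results": results, "orbit": orbit}
    if path is not None:
        base.to_json(path)
    return (base, all_results) if keep_results else base


def recognize_current(
    base: PatternBase,
    I: float,
    q: float = Q_CANONICAL,
    duration: float = 400.0,
    h: float = H_CANONICAL,
    settle: float = 100.0,
    config: RecognitionConfig = RecognitionConfig(),
) -> SimilarityReport:
    """Simulate an unknown neuron at current I and match it to the base.

    The leading ``settle`` time units are dropped so the bank sees the
    asymptotic orbit rather than the approach transient.
    """
    orbit = simulate_orbit(I, q, duration, h)
    observed = orbit.window(settle, duration)
    return recognize(base, observed, config, q=q)


# -- synchronization scenarios ----------------------------------------------


def sync_system(
    I_master: float = 1.5,
    I_slave: float = 3.8,
    q: float = Q_CANONICAL,
    disturbed: bool = True,
) -> MasterSlaveSystem:
    return MasterSlaveSystem(
        master=HRParameters(I=I_master),
        slave=HRParameters(I=I_slave),
        q=q,
        disturbances=sync_disturbances() if disturbed else DisturbanceSpec(),
    )


def run_sync(
    base: PatternBase | None,
    compensation: str = "recognized",
    mode: str = "model_based",
    duration: float = 600.0,
    t_on: float = 300.0,
    t_switch: float | None = None,
    reach_gain: float | tuple[float, float, float] = 1.0,
    surface_gain: float = 1.0,
    h: float = H_CANONICAL,
    system: MasterSlaveSystem | None = None,
    x0: Sequence[float] = X0_LEARNING,
) -> SyncResult:
    """The canonical master-slave run (both neurons start at the same state)."""
    if system is None:
        system = sync_system()
    config = ControllerConfig(
        reach_gain=reach_gain,
        surface_gain=surface_gain,
        mode=mode,
        t_on=t_on,
        t_switch=t_switch,
        adapt_gain=2.0,
        adapt_leakage=0.01,
        disturbance_bound=system.disturbances.bounds,
    )
    grid = TimeGrid.from_duration(duration, h)
    return synchronize(
        system,
        base,
        config,
        grid,
        x0_master=x0,
        x0_slave=x0,
        compensation=compensation,
    )


# -- regime tables -----------------------------------------------------------


def regime_table(
    points: Sequence[float],
    q: float,
    duration: float = 2000.0,
    h: float = H_CANONICAL,
    x0: Sequence[float] = X0_BIFURCATION,
    config: AnalysisConfig = AnalysisConfig(),
    method: str = "auto",
) -> dict[float, RegimeLabel]:
    """Classified discharge regime per stimulation current."""
    out = {}
    for I in points:
        label, _, _ = classify_simulated(
            HRParameters(I=I), q, x0, duration, h, config=config, method=method
        )
        out[float(I)] = label
    return out


# -- named experiments (CLI surface) ----------------------------------------


@dataclass
class ExperimentSpec:
    """A named, reproducible end-to-end run."""

    name: str
    description: str
    runner: Callable[[Path], dict] = field(repr=False)

    def run(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        return self.runner(outdir)


def _exp_build_base(outdir: Path) -> dict:
    base = build_training_base(outdir / "pattern_base.json")
    return {"patterns": base.ids(), "file": str(outdir / "pattern_base.json")}


def _exp_regimes_integer(outdir: Path) -> dict:
    table = regime_table([1.5, 1.8, 2.3, 2.8, 3.2, 3.58], q=1.0, duration=4000.0)
    payload = {str(k): str(v) for k, v in table.items()}
    (outdir / "regimes_q1.json").write_text(__import__("json").dumps(payload, indent=2))
    return payload


def _exp_regimes_fractional(outdir: Path) -> dict:
    table = regime_table([2.5, 3.0, 3.3], q=Q_CANONICAL, duration=2000.0, x0=X0_LEARNING)
    payload = {str(k): str(v) for k, v in table.items()}
    (outdir / "regimes_q098.json").write_text(
        __import__("json").dumps(payload, indent=2)
    )
    return payload


def _exp_sync(outdir: Path) -> dict:
    base = build_training_base()
    result = run_sync(base)
    result.write(outdir / "sync_mismatch.csv", outdir / "sync_mismatch.json")
    return {
        "recognized": result.recognition.winner if result.recognition else None,
        "pre_mean_abs_e1": result.mean_abs_error(0, 200.0, 300.0),
        "post_mean_abs_e1": result.mean_abs_error(0, 400.0, 500.0),
    }


def _exp_relearn(outdir: Path) -> dict:
    base = build_training_base()
    result = run_sync(base, mode="relearning", t_switch=500.0)
    result.write(outdir / "relearn_mismatch.csv", outdir / "relearn_mismatch.json")
    return {
        "model_based_mean_abs_e3": result.mean_abs_error(2, 400.0, 450.0),
        "relearning_mean_abs_e3": result.mean_abs_error(2, 550.0, 600.0),
    }


EXPERIMENTS: dict[str, ExperimentSpec] = {
    spec.name: spec
    for spec in [
        ExperimentSpec(
            "build-base",
            "identify chi1..chi4 and write the pattern base JSON",
            _exp_build_base,
        ),
        ExperimentSpec(
            "regimes-integer",
            "classify the q=1 discharge regimes over the canonical currents",
            _exp_regimes_integer,
        ),
        ExperimentSpec(
            "regimes-fractional",
            "classify q=0.98 regimes at I=2.5, 3.0, 3.3",
            _exp_regimes_fractional,
        ),
        ExperimentSpec(
            "sync_mismatch",
            "master I=1.5 vs disturbed slave I=3.8, model-based control at t=300",
            _exp_sync,
        ),
        ExperimentSpec(
            "relearn_mismatch",
            "same scenario, switching to relearning control at t=500",
            _exp_relearn,
        ),
    ]
}


def run_experiment(name: str, outdir: str | Path) -> dict:
    """Dispatch one named experiment; unknown names list the catalog."""
    if name not in EXPERIMENTS:
        known = ", ".join(sorted(EXPERIMENTS))
        raise KeyError(f"unknown experiment {name!r}; known: {known}")
    return EXPERIMENTS[name].run(outdir)
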