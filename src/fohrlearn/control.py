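"""Sliding-mode synchronization of the master-slave FOHR pair.

The slave is driven onto the master's orbit through a fractional
proportional-integral sliding surface

    s_i = c_i D^{1-q} e_i + e_i,        e_i = x_{s,i} - x_{m,i},

(at q = 1 the differintegral is the identity and s = (c+1) e) and a
reaching law ``D^q s = -eta sgn(s)``.  Solving the error dynamics for the
control gives

    u_i = -eta_i sgn(s_i) - c_i e_i + f_{m,i}(x_m) - f̂_{s,i}(x_s),

where the unknown slave dynamics f̂_s are compensated either by the
*recognized* constant-weight pattern (model-based mode), by live RBF
weights initialized from that pattern and adapted online through

    Ŵ̇_i = Γ φ(x_s) s_i - σ Γ |s_i| Ŵ_i

(relearning mode), by the true slave field (ablation upper bound), or not
at all (pure robust sliding mode).  The reaching gain eta then only has
to dominate the disturbance plus the *residual* compensation error,
which is the point of learning before controlling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import json
import numpy as np

from .errors import DivergenceError, FohrlearnError, WeightDivergenceError
from .fractional import GLHistorySum, MemoryPolicy, TimeGrid, check_order, gl_coefficients
from .hindmarsh_rose import STATE_LABELS, MasterSlaveSystem, hr_vector_field
from .learning import DynamicPattern, PatternBase, RBFNetwork
from .recognition import RecognitionConfig, SimilarityReport, recognize
from .trajectory import Trajectory

__all__ = [
    "ControllerConfig",
    "SyncResult",
    "compute_sliding_surface",
    "smooth_sign",
    "model_based_control_law",
    "relearning_step",
    "synchronize",
]


def compute_sliding_surface(
    errors: np.ndarray,
    surface_gain: float,
    q: float,
    h: float,
    policy: MemoryPolicy | None = None,
) -> np.ndarray:
    """s = c D^{1-q} e + e for a full error history (n,) or (n, dims).

    Uses the raw GL differintegral of order 1-q with full memory by
    default (the order-(1-q) weights decay too slowly for a meaningful
    truncation when q is close to 1).
    """
    from .fractional import FULL_MEMORY, gl_derivative

    q = check_order(q)
    policy = FULL_MEMORY if policy is None else policy
    errors = np.asarray(errors, dtype=float)
    one_d = errors.ndim == 1
    E = errors[:, None] if one_d else errors
    if q == 1.0:
        s = (surface_gain + 1.0) * E
    else:
        s = np.stack(
            [
                surface_gain * gl_derivative(E[:, j], 1.0 - q, h, policy) + E[:, j]
                for j in range(E.shape[1])
            ],
            axis=1,
        )
    return s[:, 0] if one_d else s


def smooth_sign(s: np.ndarray, epsilon: float) -> np.ndarray:
    """sgn(s), or the boundary-layer surrogate s/(|s|+epsilon) for epsilon>0."""
    s = np.asarray(s, dtype=float)
    if epsilon > 0:
        return s / (np.abs(s) + epsilon)
    return np.sign(s)


def model_based_control_law(
    e: np.ndarray,
    s: np.ndarray,
    f_m: np.ndarray,
    compensation: np.ndarray,
    reach_gain: float | np.ndarray,
    surface_gain: float | np.ndarray,
    epsilon: float = 0.0,
) -> np.ndarray:
    """u = -eta sgn(s) - c e + f_m - f̂_s, elementwise over dimensions."""
    e = np.asarray(e, dtype=float)
    return (
        -np.asarray(reach_gain) * smooth_sign(s, epsilon)
        - np.asarray(surface_gain) * e
        + np.asarray(f_m, dtype=float)
        - np.asarray(compensation, dtype=float)
    )


def relearning_step(
    s_i: float,
    phi: np.ndarray,
    weights: np.ndarray,
    adapt_gain: float,
    leakage: float,
    h: float,
) -> np.ndarray:
    """One explicit-Euler step of the relearning weight law.

    ΔŴ = h (Γ φ s - σ Γ |s| Ŵ); both terms vanish with s, so the update
    is exactly zero on the sliding surface.
    """
    return weights + h * (
        adapt_gain * phi * s_i - leakage * adapt_gain * abs(s_i) * weights
    )


@dataclass(frozen=True)
class ControllerConfig:
    """Gains, smoothing, mode schedule and documentation bounds.

    reach_gain is the sliding-mode gain eta (per dimension or scalar);
    surface_gain the surface coefficient c; epsilon > 0 replaces sgn by
    a boundary-layer surrogate.  mode "model_based" uses the frozen
    recognized pattern throughout; "relearning" switches the dimensions
    in ``relearn_dims`` to live adapted weights at ``t_switch``.
    ``disturbance_bound`` and ``residual_bound`` are documentation fields
    for the reaching-gain condition eta > D + epsilon-bar; they do not
    enter the control law.
    """

    reach_gain: float | tuple[float, float, float] = 1.0
    surface_gain: float | tuple[float, float, float] = 1.0
    epsilon: float = 0.0
    mode: str = "model_based"
    adapt_gain: float = 2.0
    adapt_leakage: float = 0.01
    t_on: float = 300.0
    t_switch: float | None = None
    relearn_dims: tuple[int, ...] = (2,)
    weight_bound: float = 1e3
    weight_snapshot_every: int = 100
    disturbance_bound: tuple[float, float, float] | None = None
    residual_bound: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.reach_gain) <= 0):
            raise ValueError("reach gain must be positive")
        if self.mode not in ("model_based", "relearning"):
            raise ValueError("mode must be 'model_based' or 'relearning'")
        if self.mode == "relearning":
            t_sw = self.t_on if self.t_switch is None else self.t_switch
            if t_sw < self.t_on:
                raise ValueError("t_switch must not precede t_on")


MODE_CODES = {"off": 0, "model_based": 1, "relearning": 2}


@dataclass
class SyncResult:
    """Closed-loop traces from one synchronization run."""

    times: np.ndarray
    master: Trajectory
    slave: Trajectory
    errors: np.ndarray  # (n, 3)
    sliding: np.ndarray  # (n, 3), as used by the controller
    control: np.ndarray  # (n, 3)
    mode_trace: np.ndarray  # (n,), MODE_CODES values
    recognition: SimilarityReport | None = None
    weight_snaps: tuple[np.ndarray, np.ndarray] | None = None  # (times, (S, N))
    config: ControllerConfig | None = None

    def mean_abs_error(self, dim: int, t_lo: float, t_hi: float) -> float:
        mask = (self.times >= t_lo) & (self.times <= t_hi)
        return float(np.abs(self.errors[mask, dim]).mean())

    def mean_abs_sliding(self, dim: int, t_lo: float, t_hi: float) -> float:
        mask = (self.times >= t_lo) & (self.times <= t_hi)
        return float(np.abs(self.sliding[mask, dim]).mean())

    def to_frame(self):
        import pandas as pd

        cols = {"t": self.times}
        for j in range(3):
            cols[f"e{j + 1}"] = self.errors[:, j]
        for j in range(3):
            cols[f"s{j + 1}"] = self.sliding[:, j]
        for j in range(3):
            cols[f"u{j + 1}"] = self.control[:, j]
        cols["mode"] = self.mode_trace
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def sidecar(self) -> dict:
        out = {
            "t_end": float(self.times[-1]),
            "recognized": None if self.recognition is None else self.recognition.winner,
        }
        if self.config is not None:
            out["config"] = {
                "reach_gain": np.asarray(self.config.reach_gain).tolist(),
                "surface_gain": np.asarray(self.config.surface_gain).tolist(),
                "epsilon": self.config.epsilon,
                "mode": self.config.mode,
                "t_on": self.config.t_on,
                "t_switch": self.config.t_switch,
            }
        return out

    def write(self, csv_path, json_path) -> None:
        self.to_csv(csv_path)
        with open(json_path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=2)


def _compensator(
    compensation: str,
    base: PatternBase | None,
    system: MasterSlaveSystem,
    report: SimilarityReport | None,
) -> tuple[DynamicPattern | None, Callable[[np.ndarray], np.ndarray]]:
    """Resolve the f̂_s evaluator for the model-based law."""
    if compensation == "none":
        return None, lambda xs: np.zeros(3)
    if compensation == "true":
        return None, lambda xs: hr_vector_field(xs, system.slave)
    if compensation == "recognized":
        if report is None or base is None:
            raise FohrlearnError("recognition did not run; no pattern to recall")
        pattern = base.get(report.winner)
    elif compensation.startswith("pattern:"):
        if base is None:
            raise FohrlearnError("a pattern base is required")
        pattern = base.get(compensation.split(":", 1)[1])
    else:
        raise ValueError(f"unknown compensation {compensation!r}")

    def comp(xs: np.ndarray) -> np.ndarray:
        return np.array([pattern.evaluate(d, xs) for d in range(3)])

    return pattern, comp


def synchronize(
    system: MasterSlaveSystem,
    base: PatternBase | None,
    config: ControllerConfig,
    grid: TimeGrid,
    x0_master: Sequence[float],
    x0_slave: Sequence[float],
    recognition: RecognitionConfig = RecognitionConfig(),
    policy: MemoryPolicy = MemoryPolicy(),
    compensation: str = "recognized",
    surface_policy: MemoryPolicy | None = None,
) -> SyncResult:
    """Closed-loop run: free flight, recognition at t_on, then control.

    Phases: the pair runs uncontrolled until ``config.t_on``; the slave's
    pre-control trajectory is matched against the base (compensation
    "recognized"); the model-based law engages at t_on; in relearning
    mode the dimensions in ``relearn_dims`` switch to live weights at
    ``t_switch``, initialized from the recognized pattern's weights.
    Control is zero-order-held over each solver step.  ``compensation``
    may force "true" (ablation upper bound), "pattern:<id>" (deliberate
    choice), or "none" (pure robust SMC, allowed with an empty base).
    """
    q = system.q
    if compensation == "recognized" and (base is None or len(base) == 0):
        raise FohrlearnError(
            "compensation='recognized' needs a non-empty pattern base"
        )
    times = grid.times
    h = grid.h
    n = grid.n_steps
    hq = h**q
    qp = 1.0 - q  # surface differintegral order
    x0_m = np.asarray(x0_master, dtype=float)
    x0_s = np.asarray(x0_slave, dtype=float)

    L = policy.resolve(q, n)
    acc_m = GLHistorySum(q, L, n, 3, base=x0_m)
    acc_s = GLHistorySum(q, L, n, 3, base=x0_s)
    acc_m.push(x0_m)
    acc_s.push(x0_s)

    # order-(1-q) weights for the incremental surface evaluation
    if qp > 0:
        cp_rev = gl_coefficients(qp, n)[::-1].copy()
        hqp = h ** (-qp)
    E = np.empty((n + 1, 3))
    S = np.empty((n + 1, 3))
    U = np.zeros((n + 1, 3))
    modes = np.zeros(n + 1, dtype=int)
    E[0] = x0_s - x0_m

    eta = np.broadcast_to(np.asarray(config.reach_gain, dtype=float), (3,))
    cs = np.broadcast_to(np.asarray(config.surface_gain, dtype=float), (3,))

    report: SimilarityReport | None = None
    pattern: DynamicPattern | None = None
    comp: Callable[[np.ndarray], np.ndarray] = lambda xs: np.zeros(3)
    comp_ready = False
    live_nets: dict[int, RBFNetwork] = {}
    snaps: list[np.ndarray] = []
    snap_times: list[float] = []
    relearning_on = False
    t_switch = config.t_switch if config.t_switch is not None else config.t_on

    def surface_at(k: int) -> np.ndarray:
        """s(t_k) from the error history up to and including row k."""
        e_k = E[k]
        if qp == 0.0:
            return (cs + 1.0) * e_k
        frac = hqp * (cp_rev[n - k :] @ E[: k + 1])
        return cs * frac + e_k

    for k in range(1, n + 1):
        t_prev = times[k - 1]
        xm = acc_m.last()
        xs = acc_s.last()
        s_prev = surface_at(k - 1)
        S[k - 1] = s_prev

        u = np.zeros(3)
        mode = "off"
        if t_prev >= config.t_on:
            if not comp_ready:
                if compensation == "recognized":
                    pre = Trajectory(times[:k], acc_s.states(), STATE_LABELS)
                    report = recognize(base, pre, recognition, q=q)
                pattern, comp = _compensator(compensation, base, system, report)
                comp_ready = True
            mode = "model_based"
            f_m = system.master_field(xm)
            f_hat = comp(xs)
            if config.mode == "relearning" and t_prev >= t_switch:
                mode = "relearning"
                if not relearning_on:
                    if pattern is None:
                        raise FohrlearnError(
                            "relearning needs a recalled pattern to start from"
                        )
                    for d in config.relearn_dims:
                        live_nets[d] = pattern.network(d)
                        live_nets[d].weights = live_nets[d].weights.copy()
                    relearning_on = True
                for d, net in live_nets.items():
                    idx = list(pattern.dims[d].input_dims)
                    phi = net.regressors(xs[idx])
                    f_hat[d] = phi @ net.weights
                    net.weights = relearning_step(
                        float(s_prev[d]),
                        phi,
                        net.weights,
                        config.adapt_gain,
                        config.adapt_leakage,
                        h,
                    )
                    wmax = np.abs(net.weights).max()
                    if not np.isfinite(wmax) or wmax > config.weight_bound:
                        raise WeightDivergenceError(
                            float(wmax), config.weight_bound, float(t_prev)
                        )
                if (k - 1) % config.weight_snapshot_every == 0:
                    snaps.append(
                        np.concatenate(
                            [live_nets[d].weights for d in sorted(live_nets)]
                        )
                    )
                    snap_times.append(float(t_prev))
            u = model_based_control_law(
                E[k - 1], s_prev, f_m, f_hat, eta, cs, config.epsilon
            )
        U[k - 1] = u
        modes[k - 1] = MODE_CODES[mode]

        d = system.disturbances(t_prev)
        new_m = system.master_field(xm) * hq + acc_m.memory_term()
        new_s = (system.slave_field(xs) + d + u) * hq + acc_s.memory_term()
        if not (np.isfinite(new_m).all() and np.isfinite(new_s).all()):
            raise DivergenceError(k, float(times[k]))
        acc_m.push(new_m)
        acc_s.push(new_s)
        E[k] = new_s - new_m

    S[n] = surface_at(n)
    U[n] = U[n - 1]
    modes[n] = modes[n - 1]

    master = Trajectory(times, acc_m.states(), STATE_LABELS)
    slave = Trajectory(times, acc_s.states(), STATE_LABELS)
    weight_snaps = None
    if snaps:
        weight_snaps = (np.asarray(snap_times), np.asarray(snaps))
    return SyncResult(
        times=times,
        master=master,
        slave=slave,
        errors=E,
        sliding=S,
        control=U,
        mode_trace=modes,
        recognition=report,
        weight_snaps=weight_snaps,
        config=config,
    )
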