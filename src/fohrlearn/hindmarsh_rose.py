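"""Hindmarsh-Rose neuron vector fields and the master-slave pair.

The three-state HR model describes a bursting neuron: ``x1`` the membrane
potential, ``x2`` the fast K+ gating (recovery) variable, ``x3`` the slow
Ca2+ adaptation current.  Its fractional-order generalization replaces the
time derivative with the GL operator of order ``q``; at ``q = 1`` the
classical model is recovered.

    D^q x1 = x2 - a x1^3 + b x1^2 - x3 + I
    D^q x2 = hr_c - d x1^2 - x2
    D^q x3 = r (s0 (x1 - q0) - x3)

``hr_c`` is the HR model constant named ``c`` in the literature; the field
name avoids collision with the sliding-surface gain and the RBF centers
used elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .fractional import MemoryPolicy, TimeGrid, check_order, solve_classical, solve_fode
from .trajectory import Trajectory

__all__ = [
    "HRParameters",
    "hr_vector_field",
    "simulate_hr",
    "DisturbanceSpec",
    "MasterSlaveSystem",
    "simulate_master_slave",
    "STATE_LABELS",
]

STATE_LABELS = ("x1", "x2", "x3")


@dataclass(frozen=True)
class HRParameters:
    """HR model constants.  All of a, b, hr_c, d, r, s0 are positive.

    Defaults are the classic bursting set (a=1, b=3, hr_c=1, d=5, r=0.006,
    s0=4, q0=-1.6), under which the stimulation current I drives the
    canonical regime staircase: slow period-1 spiking near I=1.5,
    period-2/3/4 bursting at I=1.8/2.3/2.8, chaotic discharge around
    I=3.2, and fast period-1 spiking past I=3.5.
    """

    I: float
    a: float = 1.0
    b: float = 3.0
    hr_c: float = 1.0
    d: float = 5.0
    r: float = 0.006
    s0: float = 4.0
    q0: float = -1.6

    def __post_init__(self) -> None:
        for name in ("a", "b", "hr_c", "d", "r", "s0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HR parameter {name} must be positive")

    def with_current(self, I: float) -> "HRParameters":
        return replace(self, I=I)


def hr_vector_field(state: Sequence[float], params: HRParameters) -> np.ndarray:
    """Right-hand side of the (FO)HR model at one state point."""
    x1, x2, x3 = state
    p = params
    return np.array(
        [
            x2 - p.a * x1**3 + p.b * x1**2 - x3 + p.I,
            p.hr_c - p.d * x1**2 - x2,
            p.r * (p.s0 * (x1 - p.q0) - x3),
        ]
    )


def simulate_hr(
    params: HRParameters,
    q: float,
    x0: Sequence[float],
    grid: TimeGrid,
    policy: MemoryPolicy = MemoryPolicy(),
    method: str = "auto",
) -> Trajectory:
    """Integrate one autonomous (FO)HR neuron.

    method="auto" uses the adaptive classical integrator at q = 1 and the
    GL scheme otherwise; "gl" and "classical" force one path (the latter
    only at q = 1), which the cross-check tests rely on.
    """
    q = check_order(q)
    if method == "auto":
        method = "classical" if q == 1.0 else "gl"
    field_ = lambda x, t: hr_vector_field(x, params)  # noqa: E731
    if method == "classical":
        if q != 1.0:
            raise ValueError("classical integration requires q = 1")
        return solve_classical(field_, x0, grid, labels=STATE_LABELS)
    if method != "gl":
        raise ValueError(f"unknown method {method!r}")
    return solve_fode(field_, q, x0, grid, policy, labels=STATE_LABELS)


ZERO = staticmethod(lambda t: 0.0)


@dataclass(frozen=True)
class DisturbanceSpec:
    """Bounded additive disturbances entering the slave's three equations."""

    d1: Callable[[float], float] = lambda t: 0.0
    d2: Callable[[float], float] = lambda t: 0.0
    d3: Callable[[float], float] = lambda t: 0.0
    bounds: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __call__(self, t: float) -> np.ndarray:
        return np.array([self.d1(t), self.d2(t), self.d3(t)])

    def check_bounds(self, times: np.ndarray, slack: float = 1e-9) -> bool:
        """Sampled |d_i(t)| <= declared bound, for every channel."""
        vals = np.array([self(t) for t in times])
        return bool((np.abs(vals) <= np.asarray(self.bounds) + slack).all())


@dataclass(frozen=True)
class MasterSlaveSystem:
    """Coupled pair: autonomous master, disturbed and controllable slave.

    The master runs undisturbed and uncontrolled; disturbances and control
    are added to each slave state equation.  Both neurons share the
    fractional order q.
    """

    master: HRParameters
    slave: HRParameters
    q: float
    disturbances: DisturbanceSpec = field(default_factory=DisturbanceSpec)

    def __post_init__(self) -> None:
        check_order(self.q)

    def master_field(self, x: np.ndarray) -> np.ndarray:
        return hr_vector_field(x, self.master)

    def slave_field(self, x: np.ndarray) -> np.ndarray:
        """Slave intrinsic dynamics f_s (without disturbance or control)."""
        return hr_vector_field(x, self.slave)


@dataclass
class PairedRun:
    """Output of a master-slave co-simulation."""

    times: np.ndarray
    master: Trajectory
    slave: Trajectory
    control: np.ndarray  # (n, 3), zeros when uncontrolled

    @property
    def error(self) -> np.ndarray:
        """Synchronization error e = x_s - x_m, shape (n, 3)."""
        return self.slave.states - self.master.states

    def to_frame(self):
        import pandas as pd

        cols = {"t": self.times}
        for j, lab in enumerate(STATE_LABELS):
            cols[f"xm{j + 1}"] = self.master.states[:, j]
        for j, lab in enumerate(STATE_LABELS):
            cols[f"xs{j + 1}"] = self.slave.states[:, j]
        for j in range(3):
            cols[f"u{j + 1}"] = self.control[:, j]
        err = self.error
        for j in range(3):
            cols[f"e{j + 1}"] = err[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def simulate_master_slave(
    system: MasterSlaveSystem,
    x0_master: Sequence[float],
    x0_slave: Sequence[float],
    grid: TimeGrid,
    policy: MemoryPolicy = MemoryPolicy(),
    controller=None,
    t_on: float | None = None,
) -> PairedRun:
    """Co-integrate the pair under the GL scheme.

    ``controller``, when given, is called as ``controller(t, x_m, x_s, k)``
    and must return the 3-vector u; control is forced to zero before
    ``t_on``.  Disturbances always act on the slave.  The uncontrolled
    case (controller=None) leaves u identically zero.  The closed-loop
    sliding-mode drivers in :mod:`fohrlearn.control` build on this via
    their own loop because they also need the error history; this routine
    covers open-loop and simple state-feedback hooks.
    """
    from .fractional import GLHistorySum

    q = system.q
    times = grid.times
    h = grid.h
    n = grid.n_steps
    L = policy.resolve(q, n)
    x0_m = np.asarray(x0_master, dtype=float)
    x0_s = np.asarray(x0_slave, dtype=float)
    acc_m = GLHistorySum(q, L, n, 3, base=x0_m)
    acc_s = GLHistorySum(q, L, n, 3, base=x0_s)
    acc_m.push(x0_m)
    acc_s.push(x0_s)
    u_trace = np.zeros((n + 1, 3))
    hq = h**q
    for k in range(1, n + 1):
        t_prev = times[k - 1]
        xm = acc_m.last()
        xs = acc_s.last()
        u = np.zeros(3)
        if controller is not None and (t_on is None or t_prev >= t_on):
            u = np.asarray(controller(t_prev, xm, xs, k - 1), dtype=float)
        u_trace[k - 1] = u
        d = system.disturbances(t_prev)
        new_m = system.master_field(xm) * hq + acc_m.memory_term()
        new_s = (system.slave_field(xs) + d + u) * hq + acc_s.memory_term()
        if not (np.isfinite(new_m).all() and np.isfinite(new_s).all()):
            from .errors import DivergenceError

            raise DivergenceError(k, float(times[k]))
        acc_m.push(new_m)
        acc_s.push(new_s)
    master = Trajectory(times, acc_m.states(), STATE_LABELS)
    slave = Trajectory(times, acc_s.states(), STATE_LABELS)
    return PairedRun(times, master, slave, u_trace)
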