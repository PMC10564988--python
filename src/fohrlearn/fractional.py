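"""Grünwald-Letnikov differintegration and a fixed-step fractional solver.

The GL derivative of order ``q`` on a uniform grid with step ``h`` is the
weighted backward difference

    D^q x(t_k)  ≈  h^{-q} * sum_{r=0..k} c_r x(t_k - r h),
    c_0 = 1,    c_r = (1 - (1+q)/r) c_{r-1}  =  (-1)^r binom(q, r).

For ``q = 0`` the operator is the identity; for ``q = 1`` it is the first
backward difference, so the companion initial-value scheme

    x_k = f(x_{k-1}, t_k) h^q - sum_{r=1..min(k,L)} c_r x_{k-r}

degenerates to explicit Euler.  The binomial weights decay like
``r^{-1-q}``, which justifies the short-memory truncation at lag ``L``
(:class:`MemoryPolicy`); with ``L = n_steps`` the truncated scheme is the
full-memory scheme, term for term.

The lower terminal sits at the first grid sample.  For the *operator*
(:func:`gl_derivative`) the sum uses the raw signal history, exactly as
the definition reads.  For the *initial-value scheme* (:func:`solve_fode`)
the history sum is applied by default to the deviation ``x(t) - x(0)``
("deviation" mode): for a constant initial state this makes the discrete
operator agree with the Caputo reading, so that e.g. ``D^q x = -x, x(0)=1``
converges to the Mittag-Leffler relaxation.  Summing the raw state history
("raw" mode) is also available; the two coincide when ``x(0) = 0`` and
both reduce to explicit Euler at ``q = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import fftconvolve

from .errors import DivergenceError, FohrlearnError
from .trajectory import Trajectory

__all__ = [
    "TimeGrid",
    "MemoryPolicy",
    "check_order",
    "gl_coefficients",
    "gl_derivative",
    "solve_fode",
    "solve_classical",
]


def check_order(q: float, *, allow_zero: bool = False) -> float:
    """Validate a fractional order for this package's operators.

    Solvers require ``0 < q <= 1``; the derivative operator additionally
    admits ``q = 0`` (the identity).
    """
    q = float(q)
    lo_ok = q > 0.0 or (allow_zero and q == 0.0)
    if not (lo_ok and q <= 1.0):
        rng = "[0, 1]" if allow_zero else "(0, 1]"
        raise ValueError(f"fractional order q={q} outside {rng}")
    return q


@dataclass(frozen=True)
class TimeGrid:
    """Uniform integration grid: samples ``t0 + k h`` for ``k = 0..n_steps``."""

    t0: float
    h: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("step h must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.h * np.arange(self.n_steps + 1)

    @property
    def t_end(self) -> float:
        return self.t0 + self.h * self.n_steps

    @classmethod
    def from_duration(cls, duration: float, h: float, t0: float = 0.0) -> "TimeGrid":
        return cls(t0=t0, h=h, n_steps=int(round(duration / h)))


@dataclass(frozen=True)
class MemoryPolicy:
    """Truncation policy for the GL history sum.

    mode="full" keeps every past sample.  mode="short" keeps the most
    recent ``length`` lags; when ``length`` is None it is chosen as the
    smallest L whose dropped tail satisfies ``|sum_{r>L} c_r| < tail_tol``
    (the weights sum to zero for q > 0, so the tail equals minus the
    leading partial sum).
    """

    mode: Literal["full", "short"] = "short"
    length: int | None = None
    tail_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.mode not in ("full", "short"):
            raise ValueError(f"unknown memory mode {self.mode!r}")
        if self.length is not None and self.length < 1:
            raise ValueError("memory length must be >= 1")

    def resolve(self, q: float, n_steps: int) -> int:
        """Number of history lags to keep for a run of ``n_steps`` steps."""
        if self.mode == "full":
            return n_steps
        if self.length is not None:
            return min(self.length, n_steps)
        if q >= 1.0:
            return 1  # Euler: single-lag memory is exact
        c = gl_coefficients(q, n_steps)
        tail = np.abs(np.cumsum(c))  # |sum_{r>L} c_r| = |sum_{r<=L} c_r|
        below = np.nonzero(tail < self.tail_tol)[0]
        return int(below[0]) if below.size else n_steps


FULL_MEMORY = MemoryPolicy(mode="full")


def gl_coefficients(q: float, n: int) -> np.ndarray:
    """GL binomial weights c_0..c_n of order ``q``, via the O(n) recursion."""
    if n < 0:
        raise ValueError("n must be >= 0")
    q = float(q)
    c = np.empty(n + 1)
    c[0] = 1.0
    for r in range(1, n + 1):
        c[r] = c[r - 1] * (1.0 - (1.0 + q) / r)
    return c


def _signal_array(signal: Trajectory | Sequence[float]) -> np.ndarray:
    if isinstance(signal, Trajectory):
        arr = signal.states
        if arr.shape[1] != 1:
            raise ValueError("gl_derivative expects a 1-dimensional signal")
        return arr[:, 0]
    arr = np.asarray(signal, dtype=float)
    if arr.ndim != 1:
        raise ValueError("gl_derivative expects a 1-dimensional signal")
    return arr


def gl_derivative(
    signal: Trajectory | Sequence[float],
    q: float,
    h: float | None = None,
    policy: MemoryPolicy = FULL_MEMORY,
) -> Trajectory | np.ndarray:
    """Discrete GL differintegral of a uniformly sampled signal.

    ``out[k] = h^{-q} sum_{r=0..min(k,L)} c_r signal[k-r]`` on the input
    grid.  Accepts either a 1-dim :class:`Trajectory` (returns one, with
    the step read off the grid) or a plain array plus explicit ``h``.
    """
    q = check_order(q, allow_zero=True)
    x = _signal_array(signal)
    if x.size == 0:
        raise ValueError("empty signal")
    if isinstance(signal, Trajectory):
        h = signal.h
    elif h is None:
        raise ValueError("h is required when the signal is a plain array")

    L = policy.resolve(q, x.size - 1) if x.size > 1 else 0
    kernel = gl_coefficients(q, min(L, x.size - 1))
    if kernel.size >= 64 and x.size >= 64:
        y = fftconvolve(x, kernel)[: x.size]
    else:
        y = np.convolve(x, kernel)[: x.size]
    y *= h ** (-q)
    if isinstance(signal, Trajectory):
        label = signal.labels[0]
        return Trajectory(signal.times, y[:, None], (f"D{q:g}_{label}",))
    return y


class GLHistorySum:
    """Incremental evaluator of the lagged GL memory term.

    Maintains ``-sum_{r=1..min(k,L)} c_r x_{k-r}`` for a growing state
    history; used by the solver here and by the closed-loop integrators,
    which must interleave control computation with stepping.

    The sum runs over the deviation from a reference state ``base`` (the
    initial state in the default Caputo-consistent scheme; zero for the
    raw reading).  Deviations are stored internally so the hot loop stays
    allocation-free; absolute states are recovered via :meth:`last` /
    :meth:`states`.
    """

    def __init__(
        self,
        q: float,
        L: int,
        n_steps: int,
        dim: int,
        base: np.ndarray | None = None,
    ):
        self.L = max(1, min(L, n_steps))
        c = gl_coefficients(q, self.L)
        # ascending-time weights: position L-1 holds lag 1
        self.w = (-c[1:])[::-1].copy()
        self.hist = np.empty((n_steps + 1, dim))  # deviations x - base
        self.base = np.zeros(dim) if base is None else np.asarray(base, float)
        self.k = 0

    def push(self, x: np.ndarray) -> None:
        self.hist[self.k] = x - self.base
        self.k += 1

    def last(self) -> np.ndarray:
        """Most recently pushed absolute state."""
        return self.hist[self.k - 1] + self.base

    def states(self) -> np.ndarray:
        """Absolute state history pushed so far, shape (k, dim)."""
        return self.hist[: self.k] + self.base

    def memory_term(self) -> np.ndarray:
        """Memory contribution for the step about to be taken (step k)."""
        k, L = self.k, self.L
        m = min(k, L)
        return self.w[L - m :] @ self.hist[k - m : k] + self.base


def solve_fode(
    vector_field: Callable[[np.ndarray, float], np.ndarray],
    q: float,
    x0: Sequence[float],
    grid: TimeGrid,
    policy: MemoryPolicy = MemoryPolicy(),
    labels: tuple[str, ...] = (),
    ic_mode: Literal["deviation", "raw"] = "deviation",
) -> Trajectory:
    """Fixed-step explicit GL scheme for ``D^q x = f(x, t)``.

    The field is evaluated at the previous state (explicit, Petráš-style);
    at ``q = 1`` the scheme is exactly explicit Euler.  ``ic_mode``
    selects whether the history sum acts on the deviation from the
    initial state (Caputo-consistent, default) or on the raw states.
    Raises :class:`DivergenceError` naming the step at which a state went
    non-finite.
    """
    q = check_order(q)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    times = grid.times
    h = grid.h
    L = policy.resolve(q, grid.n_steps)
    base = x0 if ic_mode == "deviation" else None
    if ic_mode not in ("deviation", "raw"):
        raise ValueError(f"unknown ic_mode {ic_mode!r}")
    acc = GLHistorySum(q, L, grid.n_steps, x0.size, base=base)
    acc.push(x0)
    hq = h**q
    for k in range(1, grid.n_steps + 1):
        t_k = times[k]
        rate = np.asarray(vector_field(acc.last(), t_k), dtype=float)
        x_new = rate * hq + acc.memory_term()
        if not np.isfinite(x_new).all():
            raise DivergenceError(k, float(t_k))
        acc.push(x_new)
    return Trajectory(times, acc.states(), labels)


def solve_classical(
    vector_field: Callable[[np.ndarray, float], np.ndarray],
    x0: Sequence[float],
    grid: TimeGrid,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    method: str = "LSODA",
    labels: tuple[str, ...] = (),
) -> Trajectory:
    """High-accuracy classical (q = 1) reference via adaptive integration.

    Samples the adaptive solution on the same uniform grid, so its output
    is directly comparable with :func:`solve_fode` at q = 1.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    times = grid.times
    sol = solve_ivp(
        lambda t, y: np.asarray(vector_field(y, t), dtype=float),
        (times[0], times[-1]),
        x0,
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
        dense_output=False,
    )
    if not sol.success:
        raise FohrlearnError(f"classical reference integration failed: {sol.message}")
    return Trajectory(sol.t, sol.y.T, labels)
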