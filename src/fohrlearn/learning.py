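"""Deterministic-learning identification with Gaussian RBF lattices.

An unknown component ``f_i(x)`` of a recurrent system is identified by
co-integrating a dynamical estimator and an adaptive weight law along a
measured orbit:

    D^q x̂_i = -a_i (x̂_i - x_i) + Ŵ_iᵀ φ(z_i(t)),
    Ŵ̇_i    = -Γ φ(z_i) x̃_i - σ Γ Ŵ_i,          x̃_i = x̂_i - x_i,

where ``φ`` is a lattice of Gaussian radial basis functions over the
inputs ``z_i`` that ``f_i`` actually depends on.  Along a periodic or
chaotic-recurrent orbit the regressor subvector excited by the orbit is
persistently exciting, so the weights converge; time-averaging the tail
of the weight history freezes them into constants ``W̄`` that store the
dynamics as a *dynamic pattern* — locally accurate along the orbit,
decaying to zero away from it.

The estimator's derivative operator defaults to the plant's fractional
order ``q`` so that the converged ``W̄ᵀφ`` approximates the fractional
right-hand side; an integer-order estimator is available as an option.
The weight law itself is an ordinary ODE and is stepped with explicit
Euler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import FohrlearnError, WeightDivergenceError
from .fractional import GLHistorySum, MemoryPolicy, check_order
from .trajectory import Trajectory

__all__ = [
    "RBFNetwork",
    "LatticeSpec",
    "LearningConfig",
    "IdentificationResult",
    "DynamicPattern",
    "PatternBase",
    "build_lattice",
    "rbf_eval",
    "identify_dynamics",
    "extract_constant_weights",
    "eval_learned_dynamics",
    "along_orbit_residual",
    "DEFAULT_INPUT_DIMS",
]

# Which state variables each HR right-hand side actually depends on:
# f1(x1,x2,x3), f2(x1,x2), f3(x1,x3).
DEFAULT_INPUT_DIMS: dict[int, tuple[int, ...]] = {0: (0, 1, 2), 1: (0, 1), 2: (0, 2)}


@dataclass(frozen=True)
class LatticeSpec:
    """Per-input-dimension (min, max, spacing) of an even RBF center grid."""

    dims: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for lo, hi, sp in self.dims:
            if hi <= lo:
                raise ValueError(f"lattice range [{lo}, {hi}] is empty")
            if sp <= 0:
                raise ValueError("lattice spacing must be positive")
            if sp > hi - lo:
                raise ValueError("lattice spacing exceeds the range")

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    def axes(self) -> list[np.ndarray]:
        """Center coordinates per axis, inclusive of both endpoints."""
        out = []
        for lo, hi, sp in self.dims:
            n = int(np.floor((hi - lo) / sp + 1e-9)) + 1
            out.append(lo + sp * np.arange(n))
        return out

    @property
    def spacings(self) -> np.ndarray:
        return np.array([sp for _, _, sp in self.dims])

    @classmethod
    def from_box(
        cls,
        lo: Sequence[float],
        hi: Sequence[float],
        n_points: int = 15,
        pad: float = 0.1,
    ) -> "LatticeSpec":
        """Even lattice over a (padded) bounding box, n_points per axis."""
        dims = []
        for a, b in zip(lo, hi):
            width = b - a
            if width <= 0:
                width = max(abs(a), 1.0) * 0.2  # degenerate axis: open a band
            a_p, b_p = a - pad * width, b + pad * width
            dims.append((a_p, b_p, (b_p - a_p) / (n_points - 1)))
        return cls(tuple(dims))


@dataclass
class RBFNetwork:
    """Gaussian RBF lattice with per-dimension widths and one weight per node.

    Regressor components are ``exp(-sum_d (x_d - c_d)^2 / eta_d^2)`` so
    that each component equals 1 at its own center and decays to zero
    away from the lattice (localization).
    """

    centers: np.ndarray  # (N, d)
    widths: np.ndarray  # (d,)
    weights: np.ndarray  # (N,)
    axes: tuple[np.ndarray, ...] | None = None  # tensor-grid axes, if lattice

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if self.widths.size == 1 and self.centers.shape[1] > 1:
            self.widths = np.full(self.centers.shape[1], self.widths[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.widths <= 0).any():
            raise ValueError("RBF widths must be positive")
        if self.widths.size != self.centers.shape[1]:
            raise ValueError("one width per input dimension required")
        if self.weights.size != self.centers.shape[0]:
            raise ValueError("one weight per center required")

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[1]

    def regressors(self, x: np.ndarray) -> np.ndarray:
        """φ(x) for a single point (d,) -> (N,) or a batch (n, d) -> (n, N)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        pts = x[None, :] if single else x
        if pts.shape[1] != self.n_inputs:
            raise ValueError(
                f"input dimension {pts.shape[1]} != lattice dimension {self.n_inputs}"
            )
        if self.axes is not None:
            # tensor-product grid: the Gaussian factorizes per axis, so an
            # outer product of short per-axis profiles replaces N full exps
            factors = [
                np.exp(-(((pts[:, d, None] - ax[None, :]) / self.widths[d]) ** 2))
                for d, ax in enumerate(self.axes)
            ]
            phi = factors[0]
            for fac in factors[1:]:
                phi = phi[:, :, None] * fac[:, None, :]
                phi = phi.reshape(pts.shape[0], -1)
        else:
            scaled = (pts[:, None, :] - self.centers[None, :, :]) / self.widths
            phi = np.exp(-np.einsum("nkd,nkd->nk", scaled, scaled))
        return phi[0] if single else phi

    def output(self, x: np.ndarray) -> float | np.ndarray:
        phi = self.regressors(x)
        return phi @ self.weights


def build_lattice(
    spec: LatticeSpec, width: float | Sequence[float]
) -> RBFNetwork:
    """Cartesian-grid RBF network with zero initial weights."""
    axes = spec.axes()
    grids = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([g.ravel() for g in grids], axis=1)
    width = np.atleast_1d(np.asarray(width, dtype=float))
    if width.size == 1:
        width = np.full(spec.n_dims, width[0])
    return RBFNetwork(centers, width, np.zeros(centers.shape[0]), axes=tuple(axes))


def rbf_eval(net: RBFNetwork, x: Sequence[float]) -> tuple[np.ndarray, float]:
    """Regressor vector φ(x) and network output Ŵᵀφ(x) at one point."""
    phi = net.regressors(np.asarray(x, dtype=float))
    return phi, float(phi @ net.weights)


@dataclass(frozen=True)
class LearningConfig:
    """Gains and bookkeeping of the identification run.

    estimator_gain is the state-tracking leak a_i; adapt_gain the (scalar
    diagonal) adaptation gain Γ; leakage the σ-modification that keeps
    unexcited weights bounded.  averaging_frac sets the default constant-
    weight window (trailing fraction of the run).  estimator_order
    "plant" runs the estimator at the plant's fractional order q so the
    learned map approximates the fractional right-hand side; "integer"
    uses a first-order estimator regardless of q.
    """

    estimator_gain: float = 10.0
    adapt_gain: float = 2.0
    leakage: float = 1e-4
    averaging_frac: float = 0.25
    snapshot_every: int = 100
    weight_bound: float = 100.0
    estimator_order: str = "plant"
    chunk: int = 4096

    def __post_init__(self) -> None:
        if self.estimator_gain <= 0 or self.adapt_gain <= 0:
            raise ValueError("estimator and adaptation gains must be positive")
        if self.leakage < 0:
            raise ValueError("leakage must be nonnegative")
        if self.estimator_order not in ("plant", "integer"):
            raise ValueError("estimator_order must be 'plant' or 'integer'")


@dataclass
class IdentificationResult:
    """Histories and frozen weights from one identification run."""

    dim: int
    input_dims: tuple[int, ...]
    snap_times: np.ndarray  # (S,)
    snap_weights: np.ndarray  # (S, N)
    estimator_states: np.ndarray  # (n,) full x̂ history
    times: np.ndarray  # (n,) plant grid
    window: tuple[float, float]  # averaging window actually used
    constant_weights: np.ndarray  # (N,) W̄ over the window

    def tracking_error(self, traj: Trajectory) -> np.ndarray:
        return self.estimator_states - traj.channel(self.dim)

    def weight_drift(self) -> np.ndarray:
        """Per-component secular weight trend inside the averaging window.

        Converged weights keep oscillating with the orbit's recurrence but
        stop trending, so the drift is measured as the difference between
        the mean over the second half of the window and the mean over the
        first half — insensitive to the oscillation phase at the window
        edges, sensitive to any remaining systematic motion.
        """
        ta, tb = self.window
        keep = (self.snap_times >= ta) & (self.snap_times <= tb)
        w = self.snap_weights[keep]
        half = w.shape[0] // 2
        return np.abs(w[half:].mean(axis=0) - w[:half].mean(axis=0))

    def weight_range(self) -> np.ndarray:
        """Per-component excursion over the whole history (settling scale)."""
        return self.snap_weights.max(axis=0) - self.snap_weights.min(axis=0)

    def settling_ratio(self, active_frac: float = 0.05) -> float:
        """Worst secular trend relative to each component's excursion.

        Restricted to components whose excursion exceeds ``active_frac``
        of the largest (never-excited lattice nodes carry no signal).
        """
        rng = self.weight_range()
        act = rng > active_frac * rng.max()
        return float((self.weight_drift()[act] / rng[act]).max())


def orbit_settling_ratio(
    result: "IdentificationResult",
    net: RBFNetwork,
    traj: Trajectory,
    span: float = 300.0,
    stride: int = 10,
    phi_cut: float = 0.05,
) -> float:
    """Settling of the weight subvector excited along the trailing orbit.

    Persistent excitation — and hence weight convergence — holds only for
    the regressor components the asymptotic orbit actually visits; nodes
    charged during the approach transient merely leak back toward zero
    under the σ-modification and are excluded here.  A component counts
    as excited when its mean regressor over the trailing ``span`` of the
    orbit exceeds ``phi_cut`` of the largest mean.

    The worst secular trend is reported relative to the excursion scale
    of the excited subvector (its largest component range), not each
    component's own range: near-zero weights would otherwise contribute
    pure noise-over-noise ratios while carrying no signal.
    """
    t_end = traj.times[-1]
    win = traj.window(t_end - span, t_end)
    z = win.states[::stride, list(result.input_dims)]
    phi_mean = net.regressors(z).mean(axis=0)
    excited = phi_mean > phi_cut * phi_mean.max()
    rng = result.weight_range()[excited]
    drift = result.weight_drift()[excited]
    return float(drift.max() / max(rng.max(), 1e-12))


def extract_constant_weights(
    snap_times: np.ndarray,
    snap_weights: np.ndarray,
    ta: float,
    tb: float,
) -> np.ndarray:
    """Component-wise arithmetic mean of the weight history over [ta, tb]."""
    if not tb > ta:
        raise ValueError("averaging window must satisfy tb > ta")
    snap_times = np.asarray(snap_times, dtype=float)
    keep = (snap_times >= ta - 1e-12) & (snap_times <= tb + 1e-12)
    if not keep.any():
        raise ValueError(f"averaging window [{ta}, {tb}] contains no samples")
    return np.asarray(snap_weights, dtype=float)[keep].mean(axis=0)


def identify_dynamics(
    traj: Trajectory,
    dim: int,
    net: RBFNetwork,
    config: LearningConfig = LearningConfig(),
    q: float = 1.0,
    input_dims: tuple[int, ...] | None = None,
    policy: MemoryPolicy = MemoryPolicy(),
    xhat0: float | None = None,
    known_term: Callable[[float, np.ndarray], float] | None = None,
    window: tuple[float, float] | None = None,
) -> IdentificationResult:
    """Identify one right-hand-side component along a measured orbit.

    ``traj`` is the plant orbit (all state channels), ``dim`` the state
    equation being identified, ``input_dims`` the channels feeding the
    regressor (defaults to the HR dependency map when the trajectory has
    three channels, else all channels).  ``known_term`` adds a known
    forcing v(t, x) to the estimator, for plants of the form
    D^q x = f(x) + v.  Returns histories plus the frozen constant
    weights over ``window`` (default: trailing ``averaging_frac`` of the
    run).
    """
    q = check_order(q)
    if input_dims is None:
        input_dims = (
            DEFAULT_INPUT_DIMS.get(dim, tuple(range(traj.dim)))
            if traj.dim == 3
            else tuple(range(traj.dim))
        )
    if dim < 0 or dim >= traj.dim:
        raise ValueError(f"dimension index {dim} outside trajectory")
    h = traj.h
    times = traj.times
    n = times.size
    x_target = traj.channel(dim)
    z = traj.states[:, list(input_dims)]

    q_est = 1.0 if config.estimator_order == "integer" else q
    L = policy.resolve(q_est, n - 1)
    x0_hat = float(x_target[0]) if xhat0 is None else float(xhat0)
    acc = GLHistorySum(q_est, L, n - 1, 1, base=np.array([x0_hat]))
    acc.push(np.array([x0_hat]))

    W = net.weights.copy()
    a = config.estimator_gain
    gam = config.adapt_gain
    sig_gam = config.leakage * gam
    hq = h**q_est

    xhat = np.empty(n)
    xhat[0] = x0_hat
    # snapshot stride grows with run length so the stored weight history
    # stays bounded (~1200 rows) even for very long adaptation runs
    stride = max(config.snapshot_every, (n - 1) // 1200)
    snap_idx = list(range(0, n, stride))
    if snap_idx[-1] != n - 1:
        snap_idx.append(n - 1)
    snaps = np.empty((len(snap_idx), W.size))
    snap_ptr = 0
    if snap_idx[0] == 0:
        snaps[0] = W
        snap_ptr = 1

    # divergence is detected per chunk via the weight bound; transient
    # overflow inside a diverging chunk is expected, not a warning
    with np.errstate(over="ignore", invalid="ignore"):
        for start in range(0, n - 1, config.chunk):
            stop = min(start + config.chunk, n - 1)
            phi_block = net.regressors(z[start:stop])
            for k in range(start, stop):
                phi = phi_block[k - start]
                x_prev = x_target[k]
                xh_prev = xhat[k]
                xt = xh_prev - x_prev
                rate = -a * xt + phi @ W
                if known_term is not None:
                    rate += known_term(times[k], traj.states[k])
                new = rate * hq + acc.memory_term()[0]
                xhat[k + 1] = new
                acc.push(np.array([new]))
                # adaptive law, explicit Euler at the plant step
                W += h * (-gam * xt * phi - sig_gam * W)
                if snap_ptr < len(snap_idx) and snap_idx[snap_ptr] == k + 1:
                    snaps[snap_ptr] = W
                    snap_ptr += 1
            wmax = np.abs(W).max()
            if not np.isfinite(wmax) or wmax > config.weight_bound:
                raise WeightDivergenceError(
                    float(wmax), config.weight_bound, times[stop]
                )

    snap_times = times[np.asarray(snap_idx)]
    if window is None:
        t_end = times[-1]
        window = (t_end - config.averaging_frac * (t_end - times[0]), t_end)
    w_bar = extract_constant_weights(snap_times, snaps, *window)
    return IdentificationResult(
        dim=dim,
        input_dims=tuple(input_dims),
        snap_times=snap_times,
        snap_weights=snaps,
        estimator_states=xhat,
        times=times,
        window=window,
        constant_weights=w_bar,
    )


# ---------------------------------------------------------------------------
# Frozen patterns and the pattern base
# ---------------------------------------------------------------------------


@dataclass
class PatternDimension:
    """Frozen constant-weight representation of one identified f_i."""

    input_dims: tuple[int, ...]
    lattice: LatticeSpec
    widths: np.ndarray
    weights: np.ndarray

    def network(self) -> RBFNetwork:
        net = build_lattice(self.lattice, self.widths)
        net.weights = np.asarray(self.weights, dtype=float).copy()
        return net


@dataclass
class DynamicPattern:
    """One stored dynamics regime: constant weights per state dimension."""

    id: str
    dims: dict[int, PatternDimension]
    metadata: dict = field(default_factory=dict)
    _nets: dict[int, RBFNetwork] = field(default_factory=dict, repr=False)

    def network(self, dim: int) -> RBFNetwork:
        if dim not in self.dims:
            raise KeyError(f"pattern {self.id!r} holds no weights for dim {dim}")
        if dim not in self._nets:
            self._nets[dim] = self.dims[dim].network()
        return self._nets[dim]

    def evaluate(self, dim: int, x: np.ndarray) -> float | np.ndarray:
        """W̄ᵀφ at full-state point(s) ``x`` (the pattern selects its inputs)."""
        net = self.network(dim)
        x = np.asarray(x, dtype=float)
        idx = list(self.dims[dim].input_dims)
        z = x[idx] if x.ndim == 1 else x[:, idx]
        return net.output(z)


def eval_learned_dynamics(
    pattern: DynamicPattern, dim: int, x: Sequence[float]
) -> float:
    """Learned approximation of f_dim at one full-state point."""
    return float(pattern.evaluate(dim, np.asarray(x, dtype=float)))


@dataclass
class PatternBase:
    """Ordered collection of dynamic patterns with unique ids."""

    patterns: list[DynamicPattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patterns]
        if len(set(ids)) != len(ids):
            raise ValueError("pattern ids must be unique")

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def ids(self) -> list[str]:
        return [p.id for p in self.patterns]

    def get(self, pattern_id: str) -> DynamicPattern:
        for p in self.patterns:
            if p.id == pattern_id:
                return p
        raise KeyError(f"no pattern {pattern_id!r} in the base")

    def add(self, pattern: DynamicPattern) -> None:
        if pattern.id in self.ids():
            raise ValueError(f"duplicate pattern id {pattern.id!r}")
        self.patterns.append(pattern)

    # -- JSON container -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": 1,
            "patterns": [
                {
                    "id": p.id,
                    "metadata": p.metadata,
                    "dims": {
                        str(d): {
                            "input_dims": list(pd.input_dims),
                            "lattice": [list(t) for t in pd.lattice.dims],
                            "widths": np.asarray(pd.widths).tolist(),
                            "weights": np.asarray(pd.weights).tolist(),
                        }
                        for d, pd in p.dims.items()
                    },
                }
                for p in self.patterns
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PatternBase":
        if payload.get("version") != 1:
            raise FohrlearnError("unsupported pattern-base version")
        patterns = []
        for rec in payload["patterns"]:
            dims = {
                int(d): PatternDimension(
                    input_dims=tuple(spec["input_dims"]),
                    lattice=LatticeSpec(tuple(tuple(t) for t in spec["lattice"])),
                    widths=np.asarray(spec["widths"], dtype=float),
                    weights=np.asarray(spec["weights"], dtype=float),
                )
                for d, spec in rec["dims"].items()
            }
            patterns.append(
                DynamicPattern(id=rec["id"], dims=dims, metadata=dict(rec["metadata"]))
            )
        return cls(patterns)

    @classmethod
    def from_json(cls, path) -> "PatternBase":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def along_orbit_residual(
    pattern: DynamicPattern,
    dim: int,
    traj: Trajectory,
    truth: Callable[[np.ndarray], float],
    t_lo: float,
    t_hi: float,
) -> tuple[float, float]:
    """(mean |W̄ᵀφ - f|, RMS of f) along one stretch of the orbit.

    The deterministic-learning guarantee is local: accuracy is asserted
    along the training orbit only, so callers pass a post-convergence
    window of that orbit.
    """
    win = traj.window(t_lo, t_hi)
    approx = np.asarray(pattern.evaluate(dim, win.states))
    exact = np.array([truth(s) for s in win.states])
    return float(np.abs(approx - exact).mean()), float(np.sqrt((exact**2).mean()))
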