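"""Rapid recognition of an observed neuron against a pattern base.

Each stored pattern ``k`` drives one first-order estimator along the
observed orbit:

    D^q x̄_k = -b (x̄_k - x_i(t)) + W̄_kᵀ φ(z(t)),    x̄_k(0) = x_i(0),

so the tracking error obeys ``D^q x̃_k = -b x̃_k + (W̄_kᵀφ - f_i)``: it
stays near zero exactly when the pattern's stored dynamics match the
observed ones along the orbit, and settles near ``mismatch / b``
otherwise.  The similarity of each pattern is the trailing average-L1
norm of its error; the winner is the argmin.  No re-identification is
performed — recognition costs one linear filter per stored pattern.

Because the stored weights approximate the *fractional* right-hand side
of the plant, the bank runs at the patterns' order ``q`` by default; an
integer-order bank is available for classical plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import json
import numpy as np

from .errors import FohrlearnError
from .fractional import GLHistorySum, MemoryPolicy, check_order
from .learning import PatternBase
from .spikes import compute_isi, detect_spikes
from .trajectory import Trajectory

__all__ = [
    "RecognitionConfig",
    "SimilarityReport",
    "run_estimator_bank",
    "l1_similarity",
    "estimate_recurrence_period",
    "recognize",
]


@dataclass(frozen=True)
class RecognitionConfig:
    """Estimator gain, similarity window and no-match threshold.

    ``window`` is the trailing averaging span T of the L1 similarity;
    None asks :func:`recognize` to estimate one recurrence period from
    the observed spike train (falling back to ``fallback_window``).
    ``threshold`` is the no-match cutoff tau: a winning similarity above
    it yields decision "no_match"; None disables the cutoff (always
    matched).  ``dimension`` is the state equation the bank listens to.
    """

    gain: float = 10.0
    window: float | None = None
    fallback_window: float = 50.0
    threshold: float | None = None
    dimension: int = 2
    order: str = "pattern"  # "pattern": run at the base's q; "integer": q=1

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("estimator gain must be positive")
        if self.window is not None and self.window <= 0:
            raise ValueError("similarity window must be positive")
        if self.order not in ("pattern", "integer"):
            raise ValueError("order must be 'pattern' or 'integer'")


def run_estimator_bank(
    base: PatternBase,
    observed: Trajectory,
    dimension: int,
    config: RecognitionConfig = RecognitionConfig(),
    q: float | None = None,
    policy: MemoryPolicy = MemoryPolicy(),
) -> dict[str, np.ndarray]:
    """Per-pattern tracking-error trajectories x̃_k(t) on the observed grid.

    Estimators start at the observed initial state, so x̃_k(0) = 0 and
    early errors reflect dynamics mismatch only.  ``q`` defaults to the
    fractional order recorded in the patterns' metadata (1.0 when absent
    or when config.order == "integer").
    """
    if len(base) == 0:
        raise ValueError("empty pattern base")
    if q is None:
        q = base.patterns[0].metadata.get("q", 1.0)
    q = 1.0 if config.order == "integer" else check_order(q)
    h = observed.h
    n = observed.n_samples
    x_i = observed.channel(dimension)
    b = config.gain
    hq = h**q
    L = policy.resolve(q, n - 1)

    # stored dynamics along the observed orbit, one batch evaluation each
    drive = {
        p.id: np.asarray(p.evaluate(dimension, observed.states)) for p in base
    }
    ids = list(drive)
    m = len(ids)
    acc = GLHistorySum(q, L, n - 1, m, base=np.full(m, x_i[0]))
    acc.push(np.full(m, x_i[0]))
    xbar = np.empty((n, m))
    xbar[0] = x_i[0]
    W = np.stack([drive[i] for i in ids], axis=1)  # (n, m)
    for k in range(1, n):
        prev = xbar[k - 1]
        rate = -b * (prev - x_i[k - 1]) + W[k - 1]
        new = rate * hq + acc.memory_term()
        xbar[k] = new
        acc.push(new)
    if not np.isfinite(xbar).all():
        raise FohrlearnError("estimator bank diverged")
    err = xbar - x_i[:, None]
    return {pid: err[:, j] for j, pid in enumerate(ids)}


def l1_similarity(error: np.ndarray, T: float, h: float) -> float:
    """Trailing average-L1 norm: mean of |x̃| over the last window of width T.

    Trapezoidal quadrature over the final ``T`` time units, normalized
    by T, evaluated at the end of the record.
    """
    if T <= 0:
        raise ValueError("window T must be positive")
    error = np.asarray(error, dtype=float)
    n_win = int(round(T / h))
    if n_win + 1 > error.size:
        raise ValueError("window T longer than the error record")
    tail = np.abs(error[error.size - (n_win + 1) :])
    return float(np.trapezoid(tail, dx=h) / T)


def estimate_recurrence_period(
    observed: Trajectory,
    fallback: float = 50.0,
    threshold: float = 0.0,
    min_separation: float = 1.0,
) -> float:
    """Recurrence-period estimate from the observed ISI structure.

    For spiking orbits this is the inter-spike interval; for bursting
    orbits the burst repeat (the long inter-burst gap dominates the ISI
    maximum).  Chaotic or sparse records fall back to ``fallback``.
    """
    spikes = detect_spikes(observed, threshold, min_separation)
    isi = compute_isi(spikes)
    if isi.size < 3:
        return fallback
    longest = float(isi.max())
    span = observed.times[-1] - observed.times[0]
    if longest > span / 2:
        return fallback
    return longest


@dataclass
class SimilarityReport:
    """Per-pattern similarities, the winner, and the match decision."""

    similarities: dict[str, float]
    winner: str
    winner_value: float
    decision: str  # "matched" | "no_match"
    config: RecognitionConfig
    errors: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "similarities": self.similarities,
            "winner": self.winner,
            "winner_value": self.winner_value,
            "decision": self.decision,
            "config": {
                "gain": self.config.gain,
                "window": self.config.window,
                "fallback_window": self.config.fallback_window,
                "threshold": self.config.threshold,
                "dimension": self.config.dimension,
                "order": self.config.order,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def recognize(
    base: PatternBase,
    observed: Trajectory,
    config: RecognitionConfig = RecognitionConfig(),
    q: float | None = None,
    policy: MemoryPolicy = MemoryPolicy(),
    keep_errors: bool = False,
) -> SimilarityReport:
    """Select the stored pattern whose dynamics best track the observation.

    Runs the estimator bank on the configured dimension, applies the
    trailing L1 similarity, and picks the argmin; ties break to the
    earliest pattern in the base.  The decision is "no_match" when the
    winning similarity exceeds the configured threshold.
    """
    errors = run_estimator_bank(base, observed, config.dimension, config, q, policy)
    T = config.window
    if T is None:
        T = estimate_recurrence_period(observed, config.fallback_window)
    h = observed.h
    span = observed.times[-1] - observed.times[0]
    T = min(T, span)
    sims = {pid: l1_similarity(err, T, h) for pid, err in errors.items()}
    winner = min(sims, key=lambda pid: (sims[pid], base.ids().index(pid)))
    value = sims[winner]
    decision = "matched"
    if config.threshold is not None and value > config.threshold:
        decision = "no_match"
    return SimilarityReport(
        similarities=sims,
        winner=winner,
        winner_value=value,
        decision=decision,
        config=config,
        errors=errors if keep_errors else {},
    )
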