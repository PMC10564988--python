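"""Uniformly sampled multivariate time series.

A :class:`Trajectory` is the common currency between the solver, the spike
analysis, the learning stages and the controllers: a uniform time grid plus
one column of samples per state variable.  Files are plain delimited text
with a ``t,<label>,...`` header so that any external tool can read them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FohrlearnError

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (n_samples, dim)
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim == 1:
            self.states = self.states[:, None]
        if self.times.ndim != 1 or self.times.size != self.states.shape[0]:
            raise ValueError("times and states must have matching lengths")
        if self.times.size == 0:
            raise ValueError("empty trajectory")
        if not self.labels:
            self.labels = tuple(f"x{i + 1}" for i in range(self.states.shape[1]))
        if len(self.labels) != self.states.shape[1]:
            raise ValueError("one label per state column required")

    # -- basic geometry -------------------------------------------------
    @property
    def dim(self) -> int:
        return self.states.shape[1]

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def h(self) -> float:
        """Sampling step, asserting uniform spacing."""
        if self.times.size < 2:
            raise FohrlearnError("step undefined for a single-sample trajectory")
        dt = np.diff(self.times)
        h = float(dt[0])
        if not np.allclose(dt, h, rtol=1e-9, atol=1e-12 * max(1.0, abs(h))):
            raise FohrlearnError("trajectory is not uniformly sampled")
        return h

    def channel(self, which: int | str) -> np.ndarray:
        """Return one state column, by index or by label."""
        if isinstance(which, str):
            try:
                which = self.labels.index(which)
            except ValueError:
                raise KeyError(f"no channel labelled {which!r}") from None
        return self.states[:, which]

    def window(self, t_lo: float, t_hi: float) -> "Trajectory":
        """Sub-trajectory with t_lo <= t <= t_hi (inclusive, half-open safe)."""
        mask = (self.times >= t_lo - 1e-12) & (self.times <= t_hi + 1e-12)
        if not mask.any():
            raise FohrlearnError(f"window [{t_lo}, {t_hi}] contains no samples")
        return Trajectory(self.times[mask], self.states[mask], self.labels)

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.states).all())

    # -- file round trip -------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.states, columns=list(self.labels))
        df.insert(0, "t", self.times)
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.columns[0] != "t":
            raise FohrlearnError("trajectory file must start with a 't' column")
        return cls(
            df["t"].to_numpy(),
            df.iloc[:, 1:].to_numpy(),
            tuple(df.columns[1:]),
        )
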