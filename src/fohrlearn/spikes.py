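"""Spike detection, ISI extraction, regime classification, bifurcation scans.

The membrane potential of a Hindmarsh-Rose neuron alternates between
sub-threshold oscillation and supra-threshold spikes.  This module turns a
simulated trajectory into a spike train (peak times and peak amplitudes
``x_max``), the inter-spike-interval (ISI) sequence, and a discharge-regime
label: regular spiking (one spike per repeat), period-n bursting (n spikes
clustered per burst), or chaotic discharge.  Sweeping a model parameter and
collecting the per-value ISI / x_max multisets yields the familiar
bifurcation diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import FohrlearnError, InsufficientDataError
from .fractional import MemoryPolicy, TimeGrid
from .hindmarsh_rose import HRParameters, simulate_hr
from .trajectory import Trajectory

__all__ = [
    "SpikeTrain",
    "RegimeLabel",
    "AnalysisConfig",
    "detect_spikes",
    "compute_isi",
    "classify_regime",
    "classify_simulated",
    "bifurcation_scan",
    "BifurcationScan",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Detected membrane-potential peaks: times and amplitudes (x_max)."""

    peak_times: np.ndarray
    peak_values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times, dtype=float)
        v = np.asarray(self.peak_values, dtype=float)
        object.__setattr__(self, "peak_times", t)
        object.__setattr__(self, "peak_values", v)
        if t.size != v.size:
            raise ValueError("peak_times and peak_values must match in length")
        if t.size > 1 and not (np.diff(t) > 0).all():
            raise ValueError("peak_times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.peak_times.size

    def after(self, t_cut: float) -> "SpikeTrain":
        keep = self.peak_times >= t_cut
        return SpikeTrain(self.peak_times[keep], self.peak_values[keep])


@dataclass(frozen=True)
class RegimeLabel:
    """Discharge-regime call for one post-transient trajectory."""

    kind: Literal["spiking", "bursting", "chaotic"]
    spikes_per_burst: int | None = None

    def __post_init__(self) -> None:
        if self.kind in ("spiking", "bursting"):
            if self.spikes_per_burst is None or self.spikes_per_burst < 1:
                raise ValueError("periodic regimes need spikes_per_burst >= 1")
        if self.kind == "spiking" and self.spikes_per_burst != 1:
            raise ValueError("spiking means one spike per repeat")

    def __str__(self) -> str:
        if self.kind == "chaotic":
            return "chaotic"
        if self.kind == "spiking":
            return "period-1 spiking"
        return f"period-{self.spikes_per_burst} bursting"


def detect_spikes(
    traj: Trajectory | np.ndarray,
    threshold: float = 0.0,
    min_separation: float = 1.0,
    h: float | None = None,
    channel: int | str = 0,
) -> SpikeTrain:
    """Local maxima of the membrane potential above ``threshold``.

    Peaks closer than ``min_separation`` in time are merged (the higher
    one wins), separating genuine spikes from numerical ripple.  An empty
    train is a legal result.
    """
    if isinstance(traj, Trajectory):
        x = traj.channel(channel)
        times = traj.times
        h = traj.h
    else:
        x = np.asarray(traj, dtype=float)
        if h is None:
            raise ValueError("h is required for a plain-array signal")
        times = h * np.arange(x.size)
    distance = max(1, int(round(min_separation / h)))
    idx, _ = find_peaks(x, height=threshold, distance=distance)
    return SpikeTrain(times[idx], x[idx])


def compute_isi(spikes: SpikeTrain) -> np.ndarray:
    """Consecutive peak-time differences; empty for fewer than two spikes."""
    if spikes.n_spikes < 2:
        return np.empty(0)
    return np.diff(spikes.peak_times)


def _burst_sizes(isi: np.ndarray, gap_factor: float) -> tuple[np.ndarray, float]:
    """Split a spike train into bursts at the long (inter-burst) intervals.

    The split threshold is placed inside the widest multiplicative gap of
    the sorted ISI values; if no consecutive pair of sorted ISIs differs
    by more than ``gap_factor``, the train has a single ISI scale and
    every burst holds one spike.  Returns (burst sizes, threshold); the
    threshold is +inf when no gap was found.
    """
    if isi.size == 0:
        return np.empty(0, dtype=int), np.inf
    srt = np.sort(isi)
    ratios = srt[1:] / srt[:-1]
    if ratios.size == 0 or ratios.max() < gap_factor:
        return np.ones(isi.size + 1, dtype=int), np.inf
    j = int(np.argmax(ratios))
    thresh = float(np.sqrt(srt[j] * srt[j + 1]))  # geometric midpoint of the gap
    sizes = []
    current = 1
    for gap in isi:
        if gap > thresh:
            sizes.append(current)
            current = 1
        else:
            current += 1
    sizes.append(current)
    return np.asarray(sizes, dtype=int), thresh


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the spike/regime pipeline (times in model units).

    transient_frac discards the leading fraction of the run before any
    regime call; gap_factor is the minimum ratio between inter-burst and
    intra-burst intervals for burst segmentation; chaos_tolerance is the
    ISI rounding bin used when counting distinct intervals for the chaos
    call; regular_share is the minimal fraction of bursts that must have
    the modal size for a periodic call.
    """

    threshold: float = 0.0
    min_separation: float = 1.0
    transient_frac: float = 0.5
    gap_factor: float = 2.0
    chaos_tolerance: float = 0.5
    max_distinct_isi: int = 20
    regular_share: float = 0.9
    min_spikes: int = 10


def classify_regime(
    spikes: SpikeTrain,
    transient_cut: float,
    gap_factor: float = 2.0,
    chaos_tolerance: float = 0.5,
    max_distinct_isi: int = 20,
    regular_share: float = 0.9,
    min_spikes: int = 10,
) -> RegimeLabel:
    """Label the post-transient discharge regime of a spike train.

    Peaks before ``transient_cut`` are dropped.  Bursts are segmented
    wherever an ISI exceeds the burst-gap threshold (see
    :func:`_burst_sizes`); the label is

    * ``spiking`` - every burst holds one spike and the ISI multiset is
      (nearly) a single value;
    * ``bursting`` - a dominant modal burst size >= 1 repeats regularly
      (share >= ``regular_share``) with few distinct rounded ISIs;
    * ``chaotic`` - many distinct ISIs (more than ``max_distinct_isi``
      after rounding to ``chaos_tolerance``) and no repeating burst
      pattern.
    """
    post = spikes.after(transient_cut)
    if post.n_spikes < min_spikes:
        raise InsufficientDataError(
            f"only {post.n_spikes} post-transient spikes (need {min_spikes})"
        )
    isi = compute_isi(post)
    sizes, _ = _burst_sizes(isi, gap_factor)
    # drop the edge bursts, usually truncated by the window
    core = sizes[1:-1] if sizes.size > 2 else sizes
    if core.size == 0:
        raise InsufficientDataError("no complete burst inside the window")
    counts = np.bincount(core)
    modal = int(np.argmax(counts))
    modal_share = counts[modal] / core.size

    if modal == 1 and (core == 1).all():
        # spiking candidate: chaos shows as an irregular ISI multiset
        distinct = np.unique(np.round(isi / chaos_tolerance)).size
        if distinct > max_distinct_isi:
            return RegimeLabel("chaotic")
        return RegimeLabel("spiking", 1)
    # bursting candidate: chaos shows as non-repeating burst sizes
    if modal_share < regular_share:
        return RegimeLabel("chaotic")
    if modal == 1:
        return RegimeLabel("spiking", 1)
    return RegimeLabel("bursting", modal)


def classify_simulated(
    params: HRParameters,
    q: float,
    x0: Sequence[float] = (0.1, 1.0, 0.2),
    duration: float = 2000.0,
    h: float = 0.01,
    policy: MemoryPolicy = MemoryPolicy(),
    config: AnalysisConfig = AnalysisConfig(),
    method: str = "auto",
) -> tuple[RegimeLabel, SpikeTrain, Trajectory]:
    """Simulate one (FO)HR neuron and classify its asymptotic regime."""
    grid = TimeGrid.from_duration(duration, h)
    traj = simulate_hr(params, q, x0, grid, policy, method=method)
    spikes = detect_spikes(traj, config.threshold, config.min_separation)
    label = classify_regime(
        spikes,
        transient_cut=grid.t0 + config.transient_frac * duration,
        gap_factor=config.gap_factor,
        chaos_tolerance=config.chaos_tolerance,
        max_distinct_isi=config.max_distinct_isi,
        regular_share=config.regular_share,
        min_spikes=config.min_spikes,
    )
    return label, spikes, traj


@dataclass
class ScanRecord:
    value: float
    label: RegimeLabel | None
    isi: np.ndarray
    x_max: np.ndarray
    error: str | None = None


@dataclass
class BifurcationScan:
    """Per-parameter-value ISI / x_max multisets and regime labels."""

    parameter: str
    records: list[ScanRecord] = field(default_factory=list)

    def labels(self) -> dict[float, RegimeLabel | None]:
        return {rec.value: rec.label for rec in self.records}

    def isi_frame(self) -> pd.DataFrame:
        """Long-format (parameter value, ISI) table, plotting-ready."""
        rows = [
            (rec.value, v) for rec in self.records for v in rec.isi
        ]
        return pd.DataFrame(rows, columns=[self.parameter, "isi"])

    def xmax_frame(self) -> pd.DataFrame:
        rows = [
            (rec.value, v) for rec in self.records for v in rec.x_max
        ]
        return pd.DataFrame(rows, columns=[self.parameter, "x_max"])

    def write(self, isi_path, xmax_path) -> None:
        self.isi_frame().to_csv(isi_path, index=False, float_format="%.17g")
        self.xmax_frame().to_csv(xmax_path, index=False, float_format="%.17g")


def bifurcation_scan(
    base_params: HRParameters,
    parameter: Literal["q", "I", "r"],
    values: Sequence[float],
    q: float,
    x0: Sequence[float] = (0.1, 1.0, 0.2),
    duration: float = 2000.0,
    h: float = 0.01,
    policy: MemoryPolicy = MemoryPolicy(),
    config: AnalysisConfig = AnalysisConfig(),
    method: str = "auto",
) -> BifurcationScan:
    """Independent-run bifurcation scan over q, I or r.

    Each grid value restarts from the same initial state (no parameter
    continuation).  A divergent point is recorded and the scan continues.
    Only the post-transient ISI / x_max values enter the records.
    """
    if parameter not in ("q", "I", "r"):
        raise ValueError("parameter must be one of 'q', 'I', 'r'")
    scan = BifurcationScan(parameter)
    for v in values:
        params = base_params
        q_run = q
        if parameter == "q":
            q_run = float(v)
        elif parameter == "I":
            params = base_params.with_current(float(v))
        else:
            params = replace(base_params, r=float(v))
        try:
            label, spk, _ = classify_simulated(
                params, q_run, x0, duration, h, policy, config, method
            )
            post = spk.after(config.transient_frac * duration)
            scan.records.append(
                ScanRecord(float(v), label, compute_isi(post), post.peak_values)
            )
        except FohrlearnError as exc:
            scan.records.append(
                ScanRecord(float(v), None, np.empty(0), np.empty(0), error=str(exc))
            )
    return scan
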