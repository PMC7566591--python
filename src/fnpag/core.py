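"""Core containers shared across the analysis pipeline.

All time axes are in seconds on a single session clock; intervals are
half-open ``[onset, offset)``. Spike trains are kept as sorted 1-D arrays of
spike times; the binary motor state uses the convention ``1 = immobile``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Region labels used for the two simultaneously recorded structures.
REGION_SOURCE = "FN"   # cerebellar fastigial nucleus
REGION_TARGET = "PAG"  # ventrolateral periaqueductal grey

#: Canonical columns of the delimited session files.
SPIKES_COLUMNS = ("unit_id", "region", "time_s")
EVENTS_COLUMNS = ("label", "onset_s", "offset_s")
GYRO_COLUMNS = ("time_s", "wx", "wy", "wz")
FRAMECHANGE_COLUMNS = ("time_s", "fraction_pct")


@dataclass
class SpikeTrain:
    """Sorted spike times (s) of one unit, with its region label."""

    unit_id: str
    region: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if np.any(np.diff(self.times) < 0):
            raise ValueError(f"spike times of unit {self.unit_id!r} are not sorted")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def in_window(self, start_s: float, stop_s: float) -> np.ndarray:
        """Spike times falling in the half-open window [start_s, stop_s)."""
        i0 = np.searchsorted(self.times, start_s, side="left")
        i1 = np.searchsorted(self.times, stop_s, side="left")
        return self.times[i0:i1]


@dataclass
class GyroTrace:
    """Uniformly sampled 3-axis angular-velocity trace (deg/s)."""

    start_s: float
    sample_rate_hz: float
    wx: np.ndarray
    wy: np.ndarray
    wz: np.ndarray

    def __post_init__(self) -> None:
        self.wx = np.asarray(self.wx, dtype=float)
        self.wy = np.asarray(self.wy, dtype=float)
        self.wz = np.asarray(self.wz, dtype=float)
        if not (self.wx.shape == self.wy.shape == self.wz.shape):
            raise ValueError("gyroscope channels must have equal length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.wx.size

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class MotorState:
    """Binary behavioural state per sample (1 = immobile, 0 = active)."""

    times: np.ndarray
    state: np.ndarray
    smoothing_sd_ms: float
    threshold_deg_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.times.shape != self.state.shape:
            raise ValueError("times and state must have equal length")
        if self.state.size and not np.isin(self.state, (0, 1)).all():
            raise ValueError("state values must be 0 or 1")

    def state_at(self, query_times: np.ndarray) -> np.ndarray:
        """Zero-order hold: state at, or immediately preceding, each query time."""
        q = np.asarray(query_times, dtype=float)
        idx = np.searchsorted(self.times, q, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("query time precedes motor-state coverage")
        return self.state[idx]


@dataclass
class ImmobilityEpisode:
    """A maximal run of immobile samples, as a half-open interval."""

    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError("episode offset must exceed onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class FreezingTrace:
    """Per-video-frame pixel-change fraction and its binarization."""

    times: np.ndarray
    fraction_pct: np.ndarray
    freezing: np.ndarray
    threshold_pct: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fraction_pct = np.asarray(self.fraction_pct, dtype=float)
        self.freezing = np.asarray(self.freezing, dtype=np.int8)
        if np.any(self.fraction_pct < 0):
            raise ValueError("pixel-change fractions must be non-negative")


@dataclass
class BinnedSeries:
    """Integer (or binary) counts on a uniform grid — the common currency of
    the information-theoretic operations."""

    bin_s: float
    start_s: float
    values: np.ndarray
    kind: str = "spikes"  # "spikes" or "motor"
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            self.values = self.values.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            raise ValueError("binned values must be non-negative")
        if self.bin_s <= 0:
            raise ValueError("bin size must be positive")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def edges(self) -> np.ndarray:
        """Left edges of the bins (s)."""
        return self.start_s + np.arange(self.n_bins) * self.bin_s

    def same_grid(self, other: "BinnedSeries") -> bool:
        return (
            abs(self.bin_s - other.bin_s) < 1e-12
            and abs(self.start_s - other.start_s) < 1e-9
            and self.n_bins == other.n_bins
        )


@dataclass
class AnalysisConfig:
    """Fixed constants of the information-flow analysis.

    Parameters
    ----------
    bin_ms : bin width for spike-count / motor series (10 ms in the protocol).
    lag_bins : source-to-target lag in bins (sources are read at t - lag).
    history_bins : length of the target's own history conditioned on by the
        transfer-entropy estimator.
    binarize : reduce spike counts to presence/absence per bin (default); when
        False, counts are kept but capped at ``max_count``.
    max_count : alphabet cap applied to raw counts when ``binarize`` is False.
    stages : optional named analysis windows, e.g.
        ``{"baseline": (0, 300), "conditioning": (300, 900), "after": (900, 1200)}``.
    """

    bin_ms: float = 10.0
    lag_bins: int = 1
    history_bins: int = 1
    binarize: bool = True
    max_count: int = 4
    stages: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        if self.lag_bins < 1:
            raise ValueError("lag_bins must be >= 1")
        if self.history_bins < 1:
            raise ValueError("history_bins must be >= 1")
        if self.stages is not None:
            wins = sorted(self.stages.values())
            for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
                if b0 < a1:
                    raise ValueError("stage windows must not overlap")

    @property
    def bin_s(self) -> float:
        return self.bin_ms / 1000.0
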