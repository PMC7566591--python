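"""Behavioural-state extraction from inertial and video signals.

The motor-activity signal is the Euclidean norm of the three angular-velocity
channels, smoothed with a Gaussian kernel (sd 64 ms) and binarized at
12 deg/s: samples below threshold are immobile, samples at or above are
active. Freezing is scored from the per-frame video pixel-change trace with
the sub-0.5% rule.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import FreezingTrace, GyroTrace, ImmobilityEpisode, MotorState

DEFAULT_SMOOTHING_SD_MS = 64.0
DEFAULT_IMMOBILITY_THRESHOLD_DEG_S = 12.0
DEFAULT_FREEZING_THRESHOLD_PCT = 0.5


def rotation_magnitude(trace: GyroTrace) -> np.ndarray:
    """Per-sample Euclidean norm of the three angular-velocity channels."""
    return np.sqrt(trace.wx**2 + trace.wy**2 + trace.wz**2)


def smooth_gaussian(
    series: np.ndarray, sd_ms: float, sample_rate_hz: float
) -> np.ndarray:
    """Convolve with a unit-sum Gaussian kernel truncated at +/- 4 sd.

    At the edges the kernel is renormalized over the available samples (no
    padding), so constants are preserved everywhere including the boundaries.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    if sd_ms <= 0:
        raise ValueError("sd_ms must be positive")
    sd = sd_ms / 1000.0 * sample_rate_hz  # sd in samples
    radius = int(np.ceil(4.0 * sd))
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sd) ** 2)
    k /= k.sum()
    num = np.convolve(x, k, mode="same")
    den = np.convolve(np.ones_like(x), k, mode="same")
    return num / den


def binarize_motor(
    smoothed: np.ndarray,
    times: np.ndarray,
    threshold_deg_s: float = DEFAULT_IMMOBILITY_THRESHOLD_DEG_S,
    smoothing_sd_ms: float = DEFAULT_SMOOTHING_SD_MS,
) -> MotorState:
    """Threshold the smoothed motor signal into immobile (1) / active (0).

    Samples strictly below the threshold are immobile; samples at or above
    it are active (values exactly at threshold count as active).
    """
    if threshold_deg_s <= 0:
        raise ValueError("threshold must be positive")
    smoothed = np.asarray(smoothed, dtype=float)
    state = (smoothed < threshold_deg_s).astype(np.int8)
    return MotorState(
        times=np.asarray(times, dtype=float),
        state=state,
        smoothing_sd_ms=smoothing_sd_ms,
        threshold_deg_s=threshold_deg_s,
    )


def motor_state_from_gyro(
    trace: GyroTrace,
    sd_ms: float = DEFAULT_SMOOTHING_SD_MS,
    threshold_deg_s: float = DEFAULT_IMMOBILITY_THRESHOLD_DEG_S,
) -> MotorState:
    """Full chain: rotation norm -> Gaussian smoothing -> binarization."""
    magnitude = rotation_magnitude(trace)
    smoothed = smooth_gaussian(magnitude, sd_ms, trace.sample_rate_hz)
    return binarize_motor(smoothed, trace.times, threshold_deg_s, sd_ms)


def immobility_episodes(
    state: MotorState,
    min_duration_s: float = 0.0,
    sample_period_s: Optional[float] = None,
) -> list:
    """Maximal runs of immobile samples as half-open episodes.

    Each run of ``state == 1`` becomes an ``ImmobilityEpisode`` whose offset
    is one sample period past the last immobile sample. Episodes shorter than
    ``min_duration_s`` are dropped; the default keeps every episode
    irrespective of duration. The sample period is inferred from the median
    spacing of ``state.times`` unless ``sample_period_s`` is given; a
    single-sample state has no inferable spacing and requires it explicitly.
    """
    s = state.state
    if s.size == 0:
        return []
    if sample_period_s is not None:
        dt = float(sample_period_s)
    elif s.size > 1:
        dt = float(np.median(np.diff(state.times)))
    else:
        raise ValueError(
            "sample period cannot be inferred from a single-sample state; "
            "pass sample_period_s explicitly"
        )
    padded = np.concatenate(([0], s, [0]))
    onsets = np.flatnonzero(np.diff(padded) == 1)
    offsets = np.flatnonzero(np.diff(padded) == -1)
    episodes = []
    for a, b in zip(onsets, offsets):
        onset = state.times[a]
        offset = state.times[b - 1] + dt
        if offset - onset >= min_duration_s and offset > onset:
            episodes.append(ImmobilityEpisode(onset_s=onset, offset_s=offset))
    return episodes


def freezing_from_frame_change(
    frame_times: np.ndarray,
    fraction_pct: np.ndarray,
    threshold_pct: float = DEFAULT_FREEZING_THRESHOLD_PCT,
) -> FreezingTrace:
    """Binarize the per-frame pixel-change trace: freezing where < threshold."""
    fraction_pct = np.asarray(fraction_pct, dtype=float)
    if np.any(fraction_pct < 0):
        raise ValueError("pixel-change fractions must be non-negative")
    freezing = (fraction_pct < threshold_pct).astype(np.int8)
    return FreezingTrace(
        times=np.asarray(frame_times, dtype=float),
        fraction_pct=fraction_pct,
        freezing=freezing,
        threshold_pct=threshold_pct,
    )


def freezing_fraction_per_interval(
    freezing: FreezingTrace, intervals: pd.DataFrame
) -> pd.DataFrame:
    """Percent of frozen frames within each labeled interval.

    ``intervals`` must have columns ``label, onset_s, offset_s``; frames are
    assigned to an interval when their time lies in ``[onset, offset)``. An
    interval reaching outside the recording span raises with the offending
    label.
    """
    t = freezing.times
    if t.size < 2:
        raise ValueError("freezing trace too short")
    dt = float(np.median(np.diff(t)))
    span = (t[0], t[-1] + dt)
    rows = []
    for _, ev in intervals.iterrows():
        on, off = float(ev["onset_s"]), float(ev["offset_s"])
        if on < span[0] - 1e-9 or off > span[1] + 1e-9:
            raise ValueError(
                f"interval {ev['label']!r} [{on}, {off}) outside recording span {span}"
            )
        sel = (t >= on) & (t < off)
        n = int(sel.sum())
        pct = 100.0 * freezing.freezing[sel].sum() / n if n else np.nan
        rows.append((ev["label"], on, off, n, pct))
    return pd.DataFrame(
        rows, columns=["label", "onset_s", "offset_s", "n_frames", "freezing_pct"]
    )
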