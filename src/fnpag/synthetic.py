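"""Synthetic-session generator with recorded ground truth.

Emulates a fear-conditioning recording session: an event schedule (CS/US and
analysis stages), a two-state active/immobile behavioural process with
exponential dwell times, a 3-axis gyroscope trace consistent with that
process, two regions of simultaneously recorded units whose firing is
modulated by the behavioural state, a unidirectional lagged excitatory
coupling from the source region (FN) to the target region (vlPAG), and a
per-frame video pixel-change trace. Every generated quantity is returned
together with the hidden parameters that produced it, so downstream
estimators can be tested against ground truth.

Spiking is simulated as Bernoulli draws on a 1 ms grid — finer than the
10 ms analysis bin, so analysis binning is a genuine operation. The
coupling acts at a lag expressed in 10 ms analysis bins and is spread
uniformly over the 1 ms sub-bins of the lagged window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    EVENTS_COLUMNS,
    REGION_SOURCE,
    REGION_TARGET,
    GyroTrace,
    SpikeTrain,
)

#: Width of the spiking simulation grid (s); ten sub-bins per analysis bin.
SPIKE_GRID_S = 0.001
#: Analysis bin the coupling lag is expressed in (s).
COUPLING_BIN_S = 0.010
#: Length of the "baseline"/"after" stage windows flanking conditioning (s).
STAGE_FLANK_S = 300.0


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolSpec:
    """Event schedule of one Pavlovian session.

    The conditioning default is five pairings of a 30 s tone (CS) with a
    0.5 s footshock (US) delivered during the last 0.5 s of the CS, after a
    180 s acclimation period and with a 120 s inter-trial interval;
    extinction sessions present 25 CS alone separated by 30 s.
    """

    acclimation_s: float = 180.0
    n_cs: int = 5
    cs_duration_s: float = 30.0
    us_duration_s: float = 0.5
    us_at_cs_end: bool = True
    iti_s: float = 120.0
    session_kind: str = "conditioning"  # or "extinction"

    def __post_init__(self) -> None:
        for name in ("acclimation_s", "cs_duration_s", "us_duration_s", "iti_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cs < 1:
            raise ValueError("n_cs must be >= 1")
        if self.us_duration_s > self.cs_duration_s:
            raise ValueError("US cannot outlast the CS")
        if self.session_kind not in ("conditioning", "extinction"):
            raise ValueError("session_kind must be 'conditioning' or 'extinction'")

    @classmethod
    def conditioning(cls) -> "ProtocolSpec":
        return cls()

    @classmethod
    def extinction(cls) -> "ProtocolSpec":
        return cls(n_cs=25, iti_s=30.0, session_kind="extinction")


def make_protocol_events(spec: ProtocolSpec) -> pd.DataFrame:
    """Build the labeled event table for a protocol.

    Returns a DataFrame with columns ``label, onset_s, offset_s`` containing
    one ``cs`` row per tone, one ``us`` row per shock (conditioning only,
    occupying the last ``us_duration_s`` of each CS when ``us_at_cs_end``),
    and three stage rows: ``baseline`` (the window ending at the first CS
    onset), ``conditioning`` (first CS onset to last US offset, or last CS
    offset without US), and ``after`` (the window following the last
    US/CS offset).
    """
    rows = []
    period = spec.cs_duration_s + spec.iti_s
    cs_onsets = spec.acclimation_s + period * np.arange(spec.n_cs)
    for k, on in enumerate(cs_onsets):
        rows.append(("cs", on, on + spec.cs_duration_s))
    with_us = spec.session_kind == "conditioning"
    if with_us:
        for on in cs_onsets:
            if spec.us_at_cs_end:
                us_on = on + spec.cs_duration_s - spec.us_duration_s
            else:
                us_on = on + spec.cs_duration_s
            rows.append(("us", us_on, us_on + spec.us_duration_s))
    first_cs = float(cs_onsets[0])
    last_off = float(cs_onsets[-1] + spec.cs_duration_s)
    rows.append(("baseline", max(0.0, first_cs - STAGE_FLANK_S), first_cs))
    rows.append(("conditioning", first_cs, last_off))
    rows.append(("after", last_off, last_off + STAGE_FLANK_S))
    df = pd.DataFrame(rows, columns=list(EVENTS_COLUMNS))
    return df.sort_values(["onset_s", "label"], kind="stable").reset_index(drop=True)


def stage_windows(events: pd.DataFrame) -> dict:
    """Extract the ``{stage: (onset, offset)}`` mapping from an event table."""
    out = {}
    for stage in ("baseline", "conditioning", "after"):
        sel = events[events["label"] == stage]
        if len(sel):
            out[stage] = (float(sel["onset_s"].iloc[0]), float(sel["offset_s"].iloc[0]))
    return out


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Free parameters of the synthetic session.

    ``base_rate_hz`` and ``immobility_gain`` accept either a scalar (applied
    to every cell) or a sequence of length ``n_source_cells + n_target_cells``
    (source cells first). ``coupling_strength`` is the spike probability added
    to a target cell's lagged analysis bin per spike of its coupled source
    cell; ``coupling_lag_bins`` is expressed in 10 ms analysis bins.
    """

    duration_s: float = 900.0
    sample_rate_hz: float = 100.0
    n_source_cells: int = 5
    n_target_cells: int = 5
    base_rate_hz: Union[float, Sequence[float]] = 10.0
    immobility_gain: Union[float, Sequence[float]] = 0.2
    coupling_strength: float = 0.3
    coupling_lag_bins: int = 1
    active_speed_deg_s: float = 100.0
    immobile_speed_deg_s: float = 5.0
    speed_noise_sd: float = 2.0
    mean_dwell_active_s: float = 20.0
    mean_dwell_immobile_s: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration_s and sample_rate_hz must be positive")
        if self.duration_s * self.sample_rate_hz < 1:
            raise ValueError("duration shorter than one gyroscope sample")
        if np.any(np.asarray(self.base_rate_hz, dtype=float) < 0):
            raise ValueError("base_rate_hz must be non-negative")
        if np.any(np.asarray(self.immobility_gain, dtype=float) < 0):
            raise ValueError("immobility_gain must be non-negative")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.coupling_lag_bins < 1:
            raise ValueError("coupling_lag_bins must be >= 1")
        if self.mean_dwell_active_s <= 0 or self.mean_dwell_immobile_s <= 0:
            raise ValueError("dwell means must be positive")
        if self.active_speed_deg_s < 0 or self.immobile_speed_deg_s < 0:
            raise ValueError("speed levels must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.n_source_cells + self.n_target_cells

    def _per_cell(self, value: Union[float, Sequence[float]]) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(self.n_cells, float(arr))
        if arr.size != self.n_cells:
            raise ValueError("per-cell parameter length must equal the cell count")
        return arr.copy()

    @property
    def rates(self) -> np.ndarray:
        return self._per_cell(self.base_rate_hz)

    @property
    def gains(self) -> np.ndarray:
        return self._per_cell(self.immobility_gain)


#: A cell is assigned ground-truth cluster 1 (strong firing drop at immobility
#: onset) when its immobility gain falls below this value, else cluster 2.
CLUSTER1_GAIN_CUTOFF = 0.5


@dataclass
class SimGroundTruth:
    """Hidden parameters of one synthetic session."""

    state_path: np.ndarray                 # 1 = immobile, at gyro sampling
    sample_rate_hz: float
    gains: dict                            # unit_id -> immobility gain
    base_rates_hz: dict                    # unit_id -> base rate
    coupling: dict                         # (source_id, target_id) -> strength
    coupling_lag_bins: int
    cluster_labels: dict = field(default_factory=dict)  # unit_id -> 1 | 2
    clipped_probability: bool = False      # p > 1 occurred before clipping

    def episodes(self) -> list:
        """Run-length encoding of the state path as (state, onset_s, offset_s)."""
        return run_length_episodes(self.state_path, self.sample_rate_hz)


def run_length_episodes(path: np.ndarray, sample_rate_hz: float) -> list:
    """Run-length encode a sampled binary path into (state, onset_s, offset_s)."""
    path = np.asarray(path)
    if path.size == 0:
        return []
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [path.size]))
    return [
        (int(path[a]), a / sample_rate_hz, b / sample_rate_hz)
        for a, b in zip(starts, stops)
    ]


# ---------------------------------------------------------------------------
# behavioural state and gyroscope
# ---------------------------------------------------------------------------

def simulate_behavior_states(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple:
    """Alternating two-state semi-Markov path with exponential dwell times.

    Returns ``(state_path, episodes)`` where ``state_path`` is sampled at
    ``cfg.sample_rate_hz`` (1 = immobile) and ``episodes`` is its run-length
    encoding as ``(state, onset_s, offset_s)`` tuples. The path starts in the
    active state. Deterministic given the generator/seed.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    if n < 1:
        raise ValueError("duration shorter than one sample")
    dt = 1.0 / cfg.sample_rate_hz
    path = np.empty(n, dtype=np.int8)
    pos = 0
    state = 0  # start active
    means = {0: cfg.mean_dwell_active_s, 1: cfg.mean_dwell_immobile_s}
    while pos < n:
        dwell = rng.exponential(means[state])
        length = max(1, int(round(dwell / dt)))
        path[pos : pos + length] = state
        pos += length
        state = 1 - state
    return path, run_length_episodes(path, cfg.sample_rate_hz)


def simulate_gyro(
    state_path: np.ndarray,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> GyroTrace:
    """3-axis gyroscope trace whose magnitude tracks the behavioural state.

    The per-sample magnitude is the state's speed level plus Gaussian noise
    (sd ``cfg.speed_noise_sd``), truncated at 0, and is distributed over the
    three axes along an isotropic random unit direction so that the Euclidean
    norm of the channels reproduces the magnitude exactly.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    state_path = np.asarray(state_path)
    n = state_path.size
    levels = np.where(state_path == 1, cfg.immobile_speed_deg_s, cfg.active_speed_deg_s)
    magnitude = levels + (
        rng.normal(0.0, cfg.speed_noise_sd, size=n) if cfg.speed_noise_sd > 0 else 0.0
    )
    magnitude = np.maximum(magnitude, 0.0)
    direction = rng.normal(size=(n, 3))
    norms = np.linalg.norm(direction, axis=1)
    norms[norms == 0] = 1.0
    xyz = direction / norms[:, None] * magnitude[:, None]
    return GyroTrace(
        start_s=0.0,
        sample_rate_hz=cfg.sample_rate_hz,
        wx=xyz[:, 0],
        wy=xyz[:, 1],
        wz=xyz[:, 2],
    )


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def _unit_ids(cfg: SimConfig) -> tuple:
    src = [f"FN{i:02d}" for i in range(cfg.n_source_cells)]
    tgt = [f"PAG{i:02d}" for i in range(cfg.n_target_cells)]
    return src, tgt


def simulate_spiketrains(
    state_path: np.ndarray,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    coupling_scale: Optional[np.ndarray] = None,
) -> tuple:
    """Coupled two-region Bernoulli spiking on a 1 ms grid.

    Per-cell spike probability per 1 ms step is
    ``base_rate * (immobility_gain if immobile else 1) * 1 ms``. Each target
    cell is coupled to one source cell (cyclic assignment): a source spike in
    10 ms analysis bin ``b`` adds ``coupling_strength`` spike probability to
    the target, spread uniformly over the 1 ms sub-bins of analysis bin
    ``b + coupling_lag_bins``. ``coupling_scale``, when given, is a per-1 ms
    multiplier of the coupling term (used to vary the coupling across
    protocol stages). Probabilities are clipped to [0, 1]; pre-clip
    excursions above 1 set ``SimGroundTruth.clipped_probability``.

    Returns ``(spiketrains, ground_truth)``.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    state_path = np.asarray(state_path)
    duration_s = state_path.size / cfg.sample_rate_hz
    n_ms = int(round(duration_s / SPIKE_GRID_S))
    sub = int(round(COUPLING_BIN_S / SPIKE_GRID_S))  # 1 ms sub-bins per 10 ms bin
    n_coarse = n_ms // sub

    # behavioural state on the 1 ms grid (zero-order hold)
    idx = np.minimum(
        (np.arange(n_ms) * SPIKE_GRID_S * cfg.sample_rate_hz).astype(np.int64),
        state_path.size - 1,
    )
    immobile_ms = state_path[idx] == 1

    src_ids, tgt_ids = _unit_ids(cfg)
    rates = cfg.rates
    gains = cfg.gains
    if coupling_scale is not None:
        coupling_scale = np.asarray(coupling_scale, dtype=float)
        if coupling_scale.size != n_ms:
            raise ValueError("coupling_scale must have one value per 1 ms step")

    trains = []
    clipped = False
    spikes_ms_by_source = {}
    centers = (np.arange(n_ms) + 0.5) * SPIKE_GRID_S

    def _draw(p: np.ndarray) -> np.ndarray:
        return rng.random(n_ms) < p

    # source region first (its spikes drive the targets)
    for i, uid in enumerate(src_ids):
        p = rates[i] * SPIKE_GRID_S * np.where(immobile_ms, gains[i], 1.0)
        if np.any(p > 1.0):
            clipped = True
            p = np.clip(p, 0.0, 1.0)
        spiked = _draw(p)
        spikes_ms_by_source[uid] = spiked
        trains.append(SpikeTrain(uid, REGION_SOURCE, centers[spiked]))

    coupling = {}
    for j, uid in enumerate(tgt_ids):
        k = cfg.n_source_cells + j
        p = rates[k] * SPIKE_GRID_S * np.where(immobile_ms, gains[k], 1.0)
        if cfg.n_source_cells > 0 and cfg.coupling_strength > 0:
            src_uid = src_ids[j % cfg.n_source_cells]
            coupling[(src_uid, uid)] = cfg.coupling_strength
            src_counts = np.add.reduceat(
                spikes_ms_by_source[src_uid][: n_coarse * sub].astype(np.int64),
                np.arange(0, n_coarse * sub, sub),
            )
            lagged = np.zeros(n_coarse, dtype=np.int64)
            lag = cfg.coupling_lag_bins
            if lag < n_coarse:
                lagged[lag:] = src_counts[: n_coarse - lag]
            add_ms = np.zeros(n_ms)
            add_ms[: n_coarse * sub] = np.repeat(
                lagged * (cfg.coupling_strength / sub), sub
            )
            if coupling_scale is not None:
                add_ms = add_ms * coupling_scale
            p = p + add_ms
        if np.any(p > 1.0):
            clipped = True
            p = np.clip(p, 0.0, 1.0)
        spiked = _draw(p)
        trains.append(SpikeTrain(uid, REGION_TARGET, centers[spiked]))

    all_ids = src_ids + tgt_ids
    truth = SimGroundTruth(
        state_path=state_path,
        sample_rate_hz=cfg.sample_rate_hz,
        gains={uid: float(gains[i]) for i, uid in enumerate(all_ids)},
        base_rates_hz={uid: float(rates[i]) for i, uid in enumerate(all_ids)},
        coupling=coupling,
        coupling_lag_bins=cfg.coupling_lag_bins,
        cluster_labels={
            uid: (1 if gains[i] < CLUSTER1_GAIN_CUTOFF else 2)
            for i, uid in enumerate(all_ids)
        },
        clipped_probability=clipped,
    )
    return trains, truth


# ---------------------------------------------------------------------------
# optogenetic responses
# ---------------------------------------------------------------------------

def simulate_opto_responses(
    pulse_times: Sequence[float],
    latency_ms: float,
    response_prob: float,
    jitter_ms: float,
    base_rate_hz: float,
    duration_s: float,
    seed: int = 0,
    unit_id: str = "PAG00",
) -> SpikeTrain:
    """Baseline Poisson spiking plus a probabilistic evoked spike per pulse.

    Each light pulse elicits, with probability ``response_prob``, one extra
    spike at ``pulse + latency_ms + N(0, jitter_ms)``; with ``jitter_ms = 0``
    and ``response_prob = 1`` the evoked latency is deterministic.
    """
    if latency_ms < 0:
        raise ValueError("latency_ms must be non-negative")
    if not 0.0 <= response_prob <= 1.0:
        raise ValueError("response_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_base = rng.poisson(base_rate_hz * duration_s)
    times = list(rng.uniform(0.0, duration_s, size=n_base))
    pulses = np.asarray(pulse_times, dtype=float)
    responds = rng.random(pulses.size) < response_prob
    evoked = pulses[responds] + latency_ms / 1000.0
    if jitter_ms > 0:
        evoked = evoked + rng.normal(0.0, jitter_ms / 1000.0, size=evoked.size)
    times.extend(evoked.tolist())
    return SpikeTrain(unit_id, REGION_TARGET, np.sort(times))


# ---------------------------------------------------------------------------
# video pixel-change trace
# ---------------------------------------------------------------------------

def simulate_frame_change(
    freezing_bouts: Sequence,
    frame_rate_hz: float,
    active_level: float,
    frozen_level: float,
    duration_s: float,
) -> tuple:
    """Piecewise-constant per-frame pixel-change series (percent).

    Frames inside ``freezing_bouts`` (list of ``(onset_s, offset_s)``) take
    ``frozen_level``; all others take ``active_level``. Returns
    ``(frame_times, fraction_pct)``.
    """
    if not frozen_level < 0.5 < active_level:
        raise ValueError("levels must straddle the 0.5% freezing threshold")
    bouts = sorted((float(a), float(b)) for a, b in freezing_bouts)
    for (a0, a1), (b0, b1) in zip(bouts, bouts[1:]):
        if b0 < a1:
            raise ValueError("freezing bouts must not overlap")
    n_frames = int(round(duration_s * frame_rate_hz))
    times = np.arange(n_frames) / frame_rate_hz
    fraction = np.full(n_frames, float(active_level))
    for a, b in bouts:
        fraction[(times >= a) & (times < b)] = frozen_level
    return times, fraction
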