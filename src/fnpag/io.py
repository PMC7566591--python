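"""Session file formats, result writing, and pipeline orchestration.

Sessions are stored as plain tab-separated files plus JSON: ``spikes.tsv``
(unit_id, region, time_s), ``gyro.tsv`` (time_s, wx, wy, wz), ``events.tsv``
(label, onset_s, offset_s), optional ``framechange.tsv`` (time_s,
fraction_pct) and optional ``truth.json`` holding a synthetic session's
ground truth. All times are seconds on one session clock; intervals are
half-open. Numeric output uses 17 significant digits so that write/read
round-trips preserve float64 values exactly and re-runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .core import (
    AnalysisConfig,
    EVENTS_COLUMNS,
    FRAMECHANGE_COLUMNS,
    GYRO_COLUMNS,
    SPIKES_COLUMNS,
    GyroTrace,
    SpikeTrain,
)
from .infoflow import (
    align_motor_to_bins,
    bin_spiketrain,
    pairwise_te_summary,
    pairwise_te_table,
    pid_two_sources,
    stage_proportions,
    stage_proportions_table,
)
from .motor import (
    immobility_episodes,
    motor_state_from_gyro,
    rotation_magnitude,
    smooth_gaussian,
)
from .responses import build_psth, cluster_immobility_profiles, state_rates
from .synthetic import (
    ProtocolSpec,
    SimConfig,
    SimGroundTruth,
    make_protocol_events,
    simulate_behavior_states,
    simulate_frame_change,
    simulate_gyro,
    simulate_spiketrains,
    stage_windows,
)

FLOAT_FORMAT = "%.17g"


@dataclass
class SessionBundle:
    """One session's data with shared clock: spikes, gyro, events, extras."""

    spikes: list                      # list[SpikeTrain]
    gyro: GyroTrace
    events: pd.DataFrame
    framechange: Optional[tuple] = None       # (times, fraction_pct)
    truth: Optional[SimGroundTruth] = None
    provenance: dict = field(default_factory=dict)

    @property
    def span(self) -> tuple:
        t = self.gyro.times
        return (float(t[0]), float(t[-1]) + 1.0 / self.gyro.sample_rate_hz)

    def units(self, region: Optional[str] = None) -> list:
        return [s for s in self.spikes if region is None or s.region == region]


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing columns: {missing}")


def write_session(bundle: SessionBundle, outdir) -> dict:
    """Write a session bundle to a directory; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = [
        (s.unit_id, s.region, t) for s in bundle.spikes for t in s.times
    ]
    spikes_df = pd.DataFrame(rows, columns=list(SPIKES_COLUMNS))
    paths["spikes"] = outdir / "spikes.tsv"
    spikes_df.to_csv(paths["spikes"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    gyro_df = pd.DataFrame(
        {
            "time_s": bundle.gyro.times,
            "wx": bundle.gyro.wx,
            "wy": bundle.gyro.wy,
            "wz": bundle.gyro.wz,
        }
    )
    paths["gyro"] = outdir / "gyro.tsv"
    gyro_df.to_csv(paths["gyro"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    paths["events"] = outdir / "events.tsv"
    bundle.events.to_csv(paths["events"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    if bundle.framechange is not None:
        times, fraction = bundle.framechange
        fc = pd.DataFrame({"time_s": times, "fraction_pct": fraction})
        paths["framechange"] = outdir / "framechange.tsv"
        fc.to_csv(paths["framechange"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    if bundle.truth is not None:
        t = bundle.truth
        payload = {
            "sample_rate_hz": t.sample_rate_hz,
            "state_path": np.asarray(t.state_path, dtype=int).tolist(),
            "gains": t.gains,
            "base_rates_hz": t.base_rates_hz,
            "coupling": [
                {"source": a, "target": b, "strength": v}
                for (a, b), v in sorted(t.coupling.items())
            ],
            "coupling_lag_bins": t.coupling_lag_bins,
            "cluster_labels": t.cluster_labels,
            "clipped_probability": t.clipped_probability,
        }
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(payload, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}


def read_session(indir, strict: bool = False) -> SessionBundle:
    """Load and validate a session directory written by :func:`write_session`.

    Spike times are sorted per unit on load; unsorted input is an error in
    strict mode and a warning otherwise. Events outside the gyroscope
    recording span raise an error naming the event.
    """
    indir = Path(indir)
    spikes_df = pd.read_csv(indir / "spikes.tsv", sep="\t", float_precision="round_trip")
    _require_columns(spikes_df, SPIKES_COLUMNS, "spikes.tsv")
    gyro_df = pd.read_csv(indir / "gyro.tsv", sep="\t", float_precision="round_trip")
    _require_columns(gyro_df, GYRO_COLUMNS, "gyro.tsv")
    events = pd.read_csv(indir / "events.tsv", sep="\t", float_precision="round_trip")
    _require_columns(events, EVENTS_COLUMNS, "events.tsv")
    events = events.astype({"onset_s": float, "offset_s": float})

    t = gyro_df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
    gyro = GyroTrace(
        start_s=float(t[0]),
        sample_rate_hz=rate,
        wx=gyro_df["wx"].to_numpy(),
        wy=gyro_df["wy"].to_numpy(),
        wz=gyro_df["wz"].to_numpy(),
    )
    span = (float(t[0]), float(t[-1]) + 1.0 / rate)

    spikes = []
    for (uid, region), grp in spikes_df.groupby(["unit_id", "region"], sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            if strict:
                raise ValueError(f"spike times of unit {uid!r} are not sorted")
            warnings.warn(f"sorting unsorted spike times of unit {uid!r}")
            times = np.sort(times)
        spikes.append(SpikeTrain(str(uid), str(region), times))

    for _, ev in events.iterrows():
        if ev["onset_s"] < span[0] - 1e-9 or ev["offset_s"] > span[1] + 1e-9:
            raise ValueError(
                f"event {ev['label']!r} [{ev['onset_s']}, {ev['offset_s']}) "
                f"lies outside the recording span {span}"
            )

    framechange = None
    fc_path = indir / "framechange.tsv"
    if fc_path.exists():
        fc = pd.read_csv(fc_path, sep="\t", float_precision="round_trip")
        _require_columns(fc, FRAMECHANGE_COLUMNS, "framechange.tsv")
        framechange = (fc["time_s"].to_numpy(), fc["fraction_pct"].to_numpy())

    truth = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        truth = SimGroundTruth(
            state_path=np.asarray(payload["state_path"], dtype=np.int8),
            sample_rate_hz=payload["sample_rate_hz"],
            gains=payload["gains"],
            base_rates_hz=payload["base_rates_hz"],
            coupling={
                (c["source"], c["target"]): c["strength"]
                for c in payload["coupling"]
            },
            coupling_lag_bins=payload["coupling_lag_bins"],
            cluster_labels={k: int(v) for k, v in payload["cluster_labels"].items()},
            clipped_probability=payload["clipped_probability"],
        )
    return SessionBundle(
        spikes=spikes,
        gyro=gyro,
        events=events,
        framechange=framechange,
        truth=truth,
        provenance={"path": str(indir)},
    )


def write_results(tables: Mapping[str, pd.DataFrame], outdir, manifest: dict) -> dict:
    """Write result tables as TSV with fixed formatting, plus the manifest.

    Column order is taken from each DataFrame as given; numbers are printed
    with 15 significant digits, so identical inputs produce byte-identical
    files. Returns ``{name: path}`` including the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        paths[name] = str(path)
    manifest = dict(manifest)
    manifest["outputs"] = {
        name: {"path": p, "sha256": _sha256(p)} for name, p in sorted(paths.items())
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, sort_keys=True, indent=2, default=str))
    paths["manifest"] = str(mpath)
    return paths


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def simulate_session(
    cfg: SimConfig,
    protocol: Optional[ProtocolSpec] = None,
    conditioning_coupling_scale: float = 1.0,
    frame_rate_hz: float = 25.0,
) -> SessionBundle:
    """Generate a complete synthetic session bundle.

    The event schedule comes from ``protocol`` (conditioning default); the
    session duration is the larger of ``cfg.duration_s`` and the end of the
    protocol's "after" window. ``conditioning_coupling_scale`` multiplies the
    source-to-target coupling inside the conditioning stage window (1 leaves
    it stationary). The video pixel-change trace mirrors the immobility
    bouts of the ground-truth state path.
    """
    protocol = ProtocolSpec.conditioning() if protocol is None else protocol
    events = make_protocol_events(protocol)
    needed = float(events.loc[events["label"] == "after", "offset_s"].iloc[0])
    duration = max(cfg.duration_s, needed)
    if duration != cfg.duration_s:
        cfg = SimConfig(**{**asdict(cfg), "duration_s": duration})

    rng = np.random.default_rng(cfg.seed)
    streams = rng.spawn(4)
    state_path, _ = simulate_behavior_states(cfg, rng=streams[0])
    gyro = simulate_gyro(state_path, cfg, rng=streams[1])

    coupling_scale = None
    if conditioning_coupling_scale != 1.0:
        n_ms = int(round(duration * 1000))
        coupling_scale = np.ones(n_ms)
        w0, w1 = stage_windows(events)["conditioning"]
        t_ms = np.arange(n_ms) / 1000.0
        coupling_scale[(t_ms >= w0) & (t_ms < w1)] = conditioning_coupling_scale
    spikes, truth = simulate_spiketrains(
        state_path, cfg, rng=streams[2], coupling_scale=coupling_scale
    )

    bouts = [(a, b) for st, a, b in truth.episodes() if st == 1]
    fc_times, fc_frac = simulate_frame_change(
        bouts, frame_rate_hz, active_level=2.0, frozen_level=0.1, duration_s=duration
    )
    return SessionBundle(
        spikes=spikes,
        gyro=gyro,
        events=events,
        framechange=(fc_times, fc_frac),
        truth=truth,
        provenance={"generator": "fnpag.synthetic", "seed": cfg.seed},
    )


@dataclass
class RunManifest:
    """Snapshot of one pipeline run: config, seed, versions, outputs."""

    config: dict
    seed: int
    version: str
    outputs: dict = field(default_factory=dict)

    def hash(self) -> str:
        payload = json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "outputs": {k: v.get("sha256") for k, v in sorted(self.outputs.items())},
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


DEFAULT_PIPELINE_CONFIG = {
    "simulate": {},            # SimConfig fields; ignored when session_dir given
    "protocol": {},            # ProtocolSpec fields
    "session_dir": None,       # read an existing session instead of simulating
    "conditioning_coupling_scale": 1.0,
    "analysis": {},            # AnalysisConfig fields
    "smoothing_sd_ms": 64.0,
    "immobility_threshold_deg_s": 12.0,
    "immobility_psth_bin_ms": 100.0,
    "immobility_psth_window_s": [2.0, 2.0],
    "seed": 0,
}


def load_config(path) -> dict:
    """Read a YAML/JSON pipeline config, filling in defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_PIPELINE_CONFIG, **user}
    return cfg


def run_pipeline(config: dict, outdir) -> RunManifest:
    """Run the full analysis chain and write all tables plus a manifest.

    Stages: obtain the session (simulate or read) -> motor-state extraction
    -> immobility episodes and two-cluster PSTH classification ->
    state-conditioned firing rates per stage -> pairwise transfer entropy ->
    stage-wise PID for every FN x PAG pair. Any stage error aborts with the
    stage name prefixed.
    """
    config = {**DEFAULT_PIPELINE_CONFIG, **(config or {})}
    stage = "setup"
    try:
        seed = int(config["seed"])
        if config.get("session_dir"):
            stage = "read_session"
            bundle = read_session(config["session_dir"])
        else:
            stage = "simulate"
            sim = SimConfig(**{**config["simulate"], "seed": seed})
            protocol = ProtocolSpec(**config["protocol"]) if config["protocol"] else None
            bundle = simulate_session(
                sim,
                protocol,
                conditioning_coupling_scale=config["conditioning_coupling_scale"],
            )

        stage = "motor_state"
        state = motor_state_from_gyro(
            bundle.gyro,
            sd_ms=config["smoothing_sd_ms"],
            threshold_deg_s=config["immobility_threshold_deg_s"],
        )
        magnitude = rotation_magnitude(bundle.gyro)
        smoothed = smooth_gaussian(
            magnitude, config["smoothing_sd_ms"], bundle.gyro.sample_rate_hz
        )
        state_df = pd.DataFrame(
            {
                "time_s": state.times,
                "speed_deg_s": magnitude,
                "smoothed": smoothed,
                "state": state.state,
            }
        )
        episodes = immobility_episodes(state)
        episodes_df = pd.DataFrame(
            [(e.onset_s, e.offset_s, e.duration_s) for e in episodes],
            columns=["onset_s", "offset_s", "duration_s"],
        )

        stage = "cluster_immobility_profiles"
        pre_w, post_w = config["immobility_psth_window_s"]
        onsets = [e.onset_s for e in episodes if e.onset_s >= pre_w]
        psths = {
            s.unit_id: build_psth(
                s, onsets, config["immobility_psth_bin_ms"], (pre_w, post_w)
            )
            for s in bundle.spikes
        }
        assignment = cluster_immobility_profiles(psths)
        clusters_df = pd.DataFrame(
            sorted(assignment.labels.items()), columns=["unit_id", "cluster"]
        )

        stage = "state_rates"
        stages = stage_windows(bundle.events)
        rate_rows = []
        for s in bundle.spikes:
            for st_name, win in stages.items():
                r = state_rates(s, state, win)
                rate_rows.append(
                    (
                        s.unit_id,
                        s.region,
                        st_name,
                        r.rate_active_hz,
                        r.rate_immobile_hz,
                        r.modulation_index,
                        r.defined,
                    )
                )
        rates_df = pd.DataFrame(
            rate_rows,
            columns=[
                "unit_id", "region", "stage",
                "rate_active_hz", "rate_immobile_hz", "modulation_index", "defined",
            ],
        )

        stage = "transfer_entropy"
        acfg = AnalysisConfig(**{**config["analysis"], "stages": stages})
        span = bundle.span
        fn_binned = [bin_spiketrain(s, acfg, span) for s in bundle.units("FN")]
        pag_binned = [bin_spiketrain(s, acfg, span) for s in bundle.units("PAG")]
        motor_binned = align_motor_to_bins(state, acfg, span)
        te_pairs = pairwise_te_table(fn_binned, pag_binned, motor_binned, acfg)
        te_summary = pairwise_te_summary(fn_binned, pag_binned, motor_binned, acfg)

        stage = "stage_pid"
        pid_frames = []
        for fn in fn_binned:
            for pag in pag_binned:
                res = stage_proportions(fn, motor_binned, pag, acfg)
                pid_frames.append(stage_proportions_table(res))
        pid_df = (
            pd.concat(pid_frames, ignore_index=True)
            if pid_frames
            else stage_proportions_table({})
        )

        stage = "write_results"
        manifest = RunManifest(config=config, seed=seed, version=_version)
        paths = write_results(
            {
                "state": state_df,
                "episodes": episodes_df,
                "clusters": clusters_df,
                "rates": rates_df,
                "te_pairs": te_pairs,
                "te_summary": te_summary,
                "pid_stages": pid_df,
            },
            outdir,
            {"config": config, "seed": seed, "version": _version},
        )
        mdata = json.loads(Path(paths["manifest"]).read_text())
        manifest.outputs = mdata["outputs"]
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
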