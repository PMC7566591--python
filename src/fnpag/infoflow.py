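"""Discrete information-theoretic core: binning, transfer entropy, and
partial information decomposition (PID).

All estimators are plug-in: empirical frequencies are substituted for
probabilities and entropies are summed directly (log base 2, bits), with the
convention 0·log 0 = 0. Spike trains are counted on a uniform 10 ms grid
(binarized to presence/absence by default); the binary motor state is
resampled at each bin's left edge by zero-order hold. Transfer entropy from
source S to target T with lag l and target history h is the conditional
mutual information

    TE(S -> T) = I(T_t ; S_{t-l} | T_{t-1}, ..., T_{t-h}),

the classic history-conditioned directed measure. The PID splits the joint
mutual information I((S1, S2); T), with both sources read one lag before the
target, into redundancy, two unique contributions and synergy using the
minimum-specific-information redundancy measure, which is non-negative and
satisfies the lattice consistency equations

    redundancy + unique_i = I(S_i; T)        (i = 1, 2)
    redundancy + unique_1 + unique_2 + synergy = I((S1, S2); T).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import AnalysisConfig, BinnedSeries, MotorState, SpikeTrain


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_spiketrain(
    spikes: SpikeTrain, cfg: AnalysisConfig, span: tuple
) -> BinnedSeries:
    """Spike counts per half-open ``[edge, edge + bin)`` bin over ``span``.

    When ``cfg.binarize`` the counts are reduced to presence/absence;
    otherwise they are capped at ``cfg.max_count``.
    """
    t0, t1 = float(span[0]), float(span[1])
    n = int(np.floor((t1 - t0) / cfg.bin_s + 1e-9))
    if n < 1:
        raise ValueError("span shorter than one bin")
    edges = t0 + np.arange(n + 1) * cfg.bin_s
    counts = np.histogram(spikes.times, bins=edges)[0]
    if cfg.binarize:
        counts = (counts > 0).astype(np.int64)
    else:
        counts = np.minimum(counts, cfg.max_count)
    return BinnedSeries(
        bin_s=cfg.bin_s, start_s=t0, values=counts, kind="spikes", label=spikes.unit_id
    )


def align_motor_to_bins(
    state: MotorState, cfg: AnalysisConfig, span: tuple
) -> BinnedSeries:
    """Motor state resampled at each bin's left edge (zero-order hold)."""
    t0, t1 = float(span[0]), float(span[1])
    n = int(np.floor((t1 - t0) / cfg.bin_s + 1e-9))
    if n < 1:
        raise ValueError("span shorter than one bin")
    edges = t0 + np.arange(n) * cfg.bin_s
    if edges[0] < state.times[0] - 1e-9:
        raise ValueError("span starts before motor-state coverage")
    values = state.state_at(edges + 1e-9).astype(np.int64)
    return BinnedSeries(bin_s=cfg.bin_s, start_s=t0, values=values, kind="motor",
                        label="motor")


# ---------------------------------------------------------------------------
# entropy helpers
# ---------------------------------------------------------------------------

def _plugin_entropy(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a count table, 0·log0 = 0."""
    c = np.asarray(counts, dtype=float).ravel()
    c = c[c > 0]
    p = c / c.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_counts(columns: Sequence[np.ndarray]) -> tuple:
    """Unique rows and counts of the stacked columns."""
    rows = np.column_stack(columns)
    return np.unique(rows, axis=0, return_counts=True)


# ---------------------------------------------------------------------------
# transfer entropy
# ---------------------------------------------------------------------------

@dataclass
class TeResult:
    """Plug-in transfer entropy between two equally binned series."""

    source_id: str
    target_id: str
    lag_bins: int
    history_bins: int
    bits: float
    n_bins: int
    degenerate: bool = False


def transfer_entropy(
    source: BinnedSeries, target: BinnedSeries, cfg: AnalysisConfig
) -> TeResult:
    """TE(source -> target) = I(T_t ; S_{t-lag} | T_{t-1..t-h}) in bits.

    Estimated by direct summation over the empirical joint frequency table
    of (T_t, target history, lagged source). Always non-negative. When both
    series are constant the value is 0 with the ``degenerate`` flag set.
    """
    if not source.same_grid(target):
        raise ValueError("source and target must share the binning grid")
    s = source.values
    t = target.values
    l, h = cfg.lag_bins, cfg.history_bins
    m = max(l, h)
    n = t.size
    if n < m + 1:
        raise ValueError("need at least lag + history + 1 bins")
    t_now = t[m:]
    # encode the h-bin target history as one symbol
    base = int(max(t.max(), 1)) + 1
    hist = np.zeros(n - m, dtype=np.int64)
    for j in range(1, h + 1):
        hist = hist * base + t[m - j : n - j]
    s_past = s[m - l : n - l]

    degenerate = bool(np.all(t == t[0]) and np.all(s == s[0]))
    uniq, cnt = _joint_counts([t_now, hist, s_past])
    total = cnt.sum()
    # marginal count tables over the (small) set of observed symbol triples
    from collections import defaultdict

    c_th: dict = defaultdict(float)
    c_hs: dict = defaultdict(float)
    c_h: dict = defaultdict(float)
    for (tv, hv, sv), c in zip(uniq, cnt):
        c_th[(tv, hv)] += c
        c_hs[(hv, sv)] += c
        c_h[hv] += c
    te = 0.0
    for (tv, hv, sv), c in zip(uniq, cnt):
        p = c / total
        te += p * np.log2(c * c_h[hv] / (c_th[(tv, hv)] * c_hs[(hv, sv)]))
    te = max(te, 0.0)  # clip tiny negative rounding residue
    return TeResult(
        source_id=source.label,
        target_id=target.label,
        lag_bins=l,
        history_bins=h,
        bits=float(te),
        n_bins=int(total),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# partial information decomposition
# ---------------------------------------------------------------------------

@dataclass
class PidResult:
    """Four PID atoms, marginal and joint mutual information, proportions."""

    unique_source1: float
    unique_source2: float
    redundancy: float
    synergy: float
    mi_joint: float
    mi_source1: float
    mi_source2: float
    n_bins: int = 0
    source1_id: str = ""
    source2_id: str = ""
    target_id: str = ""
    degenerate: bool = False   # joint MI = 0: proportions undefined

    @property
    def atoms(self) -> dict:
        return {
            "unique_source1": self.unique_source1,
            "unique_source2": self.unique_source2,
            "redundancy": self.redundancy,
            "synergy": self.synergy,
        }

    @property
    def proportions(self) -> Optional[dict]:
        if self.degenerate or self.mi_joint <= 0:
            return None
        return {k: v / self.mi_joint for k, v in self.atoms.items()}


def pid_from_joint(p: np.ndarray, **ids) -> PidResult:
    """PID of a joint distribution ``p[s1, s2, t]``.

    Redundancy is the minimum specific information
    ``R = sum_t p(t) min_i I_spec(T=t; S_i)`` with
    ``I_spec(T=t; S_i) = sum_s p(s|t) [log2 p(t|s) - log2 p(t)]``; the unique
    and synergy atoms follow from the lattice consistency equations.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 3:
        raise ValueError("joint distribution must be 3-dimensional (s1, s2, t)")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("joint distribution must be a normalized probability table")
    p_t = p.sum(axis=(0, 1))
    p_s1 = p.sum(axis=(1, 2))
    p_s2 = p.sum(axis=(0, 2))
    p_s1t = p.sum(axis=1)
    p_s2t = p.sum(axis=0)
    p_s12 = p.sum(axis=2)

    def _mi(joint: np.ndarray, pa: np.ndarray, pb: np.ndarray) -> float:
        return _plugin_entropy(pa) + _plugin_entropy(pb) - _plugin_entropy(joint)

    mi1 = _mi(p_s1t, p_s1, p_t)
    mi2 = _mi(p_s2t, p_s2, p_t)
    mi_joint = _mi(p.reshape(-1, p.shape[2]), p_s12, p_t)

    def _specific(p_st: np.ndarray, p_s: np.ndarray) -> np.ndarray:
        """I_spec(T = t; S) for every t (0 where p(t) = 0)."""
        out = np.zeros(p_t.size)
        for ti in range(p_t.size):
            if p_t[ti] <= 0:
                continue
            acc = 0.0
            for si in range(p_s.size):
                joint = p_st[si, ti]
                if joint <= 0:
                    continue
                p_s_given_t = joint / p_t[ti]
                p_t_given_s = joint / p_s[si]
                acc += p_s_given_t * (np.log2(p_t_given_s) - np.log2(p_t[ti]))
            out[ti] = acc
        return out

    spec1 = _specific(p_s1t, p_s1)
    spec2 = _specific(p_s2t, p_s2)
    redundancy = float((p_t * np.minimum(spec1, spec2)).sum())
    u1 = mi1 - redundancy
    u2 = mi2 - redundancy
    synergy = mi_joint - redundancy - u1 - u2
    # clip numerical residue; the identities hold to ~1e-15 by construction
    eps = 1e-12
    redundancy = 0.0 if abs(redundancy) < eps else redundancy
    u1 = 0.0 if abs(u1) < eps else u1
    u2 = 0.0 if abs(u2) < eps else u2
    synergy = 0.0 if abs(synergy) < eps else synergy
    return PidResult(
        unique_source1=u1,
        unique_source2=u2,
        redundancy=redundancy,
        synergy=synergy,
        mi_joint=mi_joint,
        mi_source1=mi1,
        mi_source2=mi2,
        degenerate=bool(mi_joint <= eps),
        **ids,
    )


def pid_two_sources(
    source1: BinnedSeries,
    source2: BinnedSeries,
    target: BinnedSeries,
    cfg: AnalysisConfig,
) -> PidResult:
    """PID of the empirical joint of (S1_{t-lag}, S2_{t-lag}, T_t)."""
    if not (source1.same_grid(source2) and source1.same_grid(target)):
        raise ValueError("all series must share the binning grid")
    l = cfg.lag_bins
    n = target.n_bins
    if n < l + 1:
        raise ValueError("need at least lag + 1 bins")
    s1 = source1.values[: n - l]
    s2 = source2.values[: n - l]
    t = target.values[l:]
    k1 = int(s1.max()) + 1 if s1.size else 1
    k2 = int(s2.max()) + 1 if s2.size else 1
    kt = int(t.max()) + 1 if t.size else 1
    table = np.zeros((k1, k2, kt))
    np.add.at(table, (s1, s2, t), 1.0)
    result = pid_from_joint(
        table / table.sum(),
        source1_id=source1.label,
        source2_id=source2.label,
        target_id=target.label,
    )
    result.n_bins = int(n - l)
    return result


# ---------------------------------------------------------------------------
# session-level summaries
# ---------------------------------------------------------------------------

DIRECTION_CLASSES = (
    "FN->PAG", "PAG->FN", "FN->motor", "motor->FN", "PAG->motor", "motor->PAG",
)


def pairwise_te_table(
    fn_cells: Sequence[BinnedSeries],
    pag_cells: Sequence[BinnedSeries],
    motor: BinnedSeries,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """TE for every ordered pair among FN cells, PAG cells and the motor
    signal, one row per pair with its direction class."""
    if not fn_cells or not pag_cells:
        raise ValueError("need at least one cell per region")
    groups = {"FN": list(fn_cells), "PAG": list(pag_cells), "motor": [motor]}
    rows = []
    for a, b in product(("FN", "PAG", "motor"), repeat=2):
        if a == b:
            continue
        for src in groups[a]:
            for tgt in groups[b]:
                r = transfer_entropy(src, tgt, cfg)
                rows.append((f"{a}->{b}", r.source_id, r.target_id, r.bits, r.n_bins))
    return pd.DataFrame(
        rows, columns=["direction", "source_id", "target_id", "te_bits", "n_bins"]
    )


def pairwise_te_summary(
    fn_cells: Sequence[BinnedSeries],
    pag_cells: Sequence[BinnedSeries],
    motor: BinnedSeries,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Mean TE per direction class over all ordered pairs."""
    table = pairwise_te_table(fn_cells, pag_cells, motor, cfg)
    out = (
        table.groupby("direction", sort=False)["te_bits"]
        .agg(mean_te_bits="mean", n_pairs="size")
        .reset_index()
    )
    order = {d: i for i, d in enumerate(DIRECTION_CLASSES)}
    return out.sort_values("direction", key=lambda c: c.map(order)).reset_index(
        drop=True
    )


def stage_proportions(
    fn_cell: BinnedSeries,
    motor: BinnedSeries,
    pag_cell: BinnedSeries,
    cfg: AnalysisConfig,
    min_bins: int = 100,
) -> dict:
    """PID (sources: FN cell and motor; target: PAG cell) per analysis stage.

    ``cfg.stages`` must name the stage windows (seconds). Each stage is
    analysed independently on the bins whose left edge falls inside its
    window. Returns ``{stage: PidResult}``; a stage with zero joint MI
    carries the ``degenerate`` flag.
    """
    if not cfg.stages:
        raise ValueError("cfg.stages must define the analysis windows")
    out = {}
    for stage, (w0, w1) in cfg.stages.items():
        i0 = int(np.ceil((w0 - fn_cell.start_s) / cfg.bin_s - 1e-9))
        i1 = int(np.floor((w1 - fn_cell.start_s) / cfg.bin_s + 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, fn_cell.n_bins)
        if i1 - i0 < min_bins:
            raise ValueError(f"stage {stage!r} contains fewer than {min_bins} bins")

        def _slice(series: BinnedSeries) -> BinnedSeries:
            return BinnedSeries(
                bin_s=series.bin_s,
                start_s=series.start_s + i0 * series.bin_s,
                values=series.values[i0:i1],
                kind=series.kind,
                label=series.label,
            )

        out[stage] = pid_two_sources(_slice(fn_cell), _slice(motor), _slice(pag_cell), cfg)
    return out


def stage_proportions_table(results: Mapping) -> pd.DataFrame:
    """Tidy table (stage x atom) of PID bits and proportions."""
    rows = []
    for stage, r in results.items():
        props = r.proportions
        for atom, bits in r.atoms.items():
            rows.append(
                (
                    stage,
                    r.source1_id,
                    r.source2_id,
                    r.target_id,
                    atom,
                    bits,
                    props[atom] if props else np.nan,
                    r.mi_joint,
                    r.n_bins,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "stage", "source1_id", "source2_id", "target_id",
            "atom", "bits", "proportion", "mi_joint_bits", "n_bins",
        ],
    )
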