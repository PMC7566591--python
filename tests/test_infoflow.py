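"""Information-theoretic core: binning, motor resampling, plug-in transfer
entropy against brute-force oracles, and PID lattice identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fnpag
from fnpag.core import AnalysisConfig, BinnedSeries, MotorState, SpikeTrain
from fnpag.infoflow import (
    align_motor_to_bins,
    bin_spiketrain,
    pairwise_te_summary,
    pairwise_te_table,
    pid_from_joint,
    pid_two_sources,
    stage_proportions,
    transfer_entropy,
)


def _series(values, label="x", bin_s=0.01, start_s=0.0):
    return BinnedSeries(bin_s=bin_s, start_s=start_s,
                        values=np.asarray(values), label=label)


def _entropy(counts):
    c = np.asarray(counts, float).ravel()
    c = c[c > 0]
    p = c / c.sum()
    return -(p * np.log2(p)).sum()


def te_oracle(s, t):
    """Independent oracle: TE as the chain-rule entropy difference
    H(T_t | T_{t-1}) - H(T_t | T_{t-1}, S_{t-1}) from histogram tables."""
    t_now, t_past, s_past = t[1:], t[:-1], s[:-1]
    k = int(max(t.max(), s.max())) + 1
    c_tts, _ = np.histogramdd(
        np.column_stack([t_now, t_past, s_past]), bins=(k, k, k),
        range=[(-0.5, k - 0.5)] * 3,
    )
    c_tt = c_tts.sum(axis=2)
    c_ts = c_tts.sum(axis=0)
    c_t = c_tts.sum(axis=(0, 2))
    h_t_given_tpast = _entropy(c_tt) - _entropy(c_t)
    h_t_given_both = _entropy(c_tts) - _entropy(c_ts)
    return h_t_given_tpast - h_t_given_both


class TestBinning:
    def test_spike_placement(self, analysis_cfg):
        train = SpikeTrain("u", "FN", [0.005, 0.012])
        out = bin_spiketrain(train, analysis_cfg, (0.0, 0.03))
        assert out.values.tolist() == [1, 1, 0]

    def test_empty_train(self, analysis_cfg):
        out = bin_spiketrain(SpikeTrain("u", "FN", []), analysis_cfg, (0.0, 0.05))
        assert out.values.sum() == 0 and out.n_bins == 5

    def test_binarize_flag_semantics(self):
        train = SpikeTrain("u", "FN", [0.001, 0.002])
        on = bin_spiketrain(train, AnalysisConfig(binarize=True), (0.0, 0.01))
        off = bin_spiketrain(train, AnalysisConfig(binarize=False), (0.0, 0.01))
        assert on.values.tolist() == [1]
        assert off.values.tolist() == [2]

    def test_count_cap_without_binarization(self):
        train = SpikeTrain("u", "FN", np.linspace(0.0005, 0.0095, 7))
        out = bin_spiketrain(train, AnalysisConfig(binarize=False, max_count=4),
                             (0.0, 0.01))
        assert out.values.tolist() == [4]


class TestMotorAlignment:
    def test_constant_state(self, analysis_cfg):
        state = MotorState(np.arange(100) / 100.0, np.ones(100, np.int8), 0, 0)
        out = align_motor_to_bins(state, analysis_cfg, (0.0, 1.0))
        assert out.values.all() and out.n_bins == 100

    def test_left_edge_rule_at_flip(self, analysis_cfg):
        # state flips at 15 ms: edges 0 and 10 ms pre-flip, 20 ms post-flip
        times = np.arange(0, 0.04, 0.005)
        statev = (times >= 0.015).astype(np.int8)
        state = MotorState(times, statev, 0, 0)
        out = align_motor_to_bins(state, analysis_cfg, (0.0, 0.03))
        assert out.values.tolist() == [0, 0, 1]

    def test_matches_last_value_oracle(self, analysis_cfg):
        rng = np.random.default_rng(4)
        times = np.arange(0, 5.0, 0.013)
        statev = rng.integers(0, 2, times.size).astype(np.int8)
        state = MotorState(times, statev, 0, 0)
        out = align_motor_to_bins(state, analysis_cfg, (0.1, 4.9))
        for edge, v in zip(out.edges, out.values):
            expected = statev[np.flatnonzero(times <= edge + 1e-9)[-1]]
            assert v == expected

    def test_span_before_coverage_rejected(self, analysis_cfg):
        state = MotorState(np.arange(100) / 100.0 + 1.0, np.ones(100, np.int8), 0, 0)
        with pytest.raises(ValueError):
            align_motor_to_bins(state, analysis_cfg, (0.0, 1.0))


class TestTransferEntropy:
    def test_deterministic_copy_limits(self, analysis_cfg):
        rng = np.random.default_rng(0)
        s = rng.integers(0, 2, 100_000)
        t = np.concatenate([[0], s[:-1]])
        te_fwd = transfer_entropy(_series(s, "S"), _series(t, "T"), analysis_cfg)
        te_rev = transfer_entropy(_series(t, "T"), _series(s, "S"), analysis_cfg)
        assert te_fwd.bits == pytest.approx(1.0, abs=0.01)
        assert te_rev.bits < 0.01

    def test_constant_series_degenerate_zero(self, analysis_cfg):
        c = _series(np.zeros(100, dtype=int))
        r = transfer_entropy(c, c, analysis_cfg)
        assert r.bits == 0.0 and r.degenerate

    def test_noisy_copy_matches_enumeration_oracle(self, analysis_cfg):
        """Flip noise eps: the true TE is 1 - H_b(eps), obtained here by
        brute-force summation over the 8-cell joint distribution."""
        eps = 0.1
        # enumerate the true joint of (T_t, T_{t-1}, S_{t-1})
        p = np.zeros((2, 2, 2))
        for s_past in (0, 1):
            for t_past in (0, 1):
                for t_now in (0, 1):
                    flip = eps if t_now != s_past else 1 - eps
                    p[t_now, t_past, s_past] = 0.25 * flip
        p_th = p.sum(axis=2)
        p_hs = p.sum(axis=0)
        p_h = p.sum(axis=(0, 2))
        true_te = 0.0
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    if p[i, j, k] > 0:
                        true_te += p[i, j, k] * np.log2(
                            p[i, j, k] * p_h[j] / (p_th[i, j] * p_hs[j, k]))
        hb = -(eps * np.log2(eps) + (1 - eps) * np.log2(1 - eps))
        assert true_te == pytest.approx(1 - hb, abs=1e-12)

        rng = np.random.default_rng(1)
        s = rng.integers(0, 2, 100_000)
        t = np.concatenate([[0], s[:-1]])
        flips = rng.random(t.size) < eps
        t = np.where(flips, 1 - t, t)
        est = transfer_entropy(_series(s, "S"), _series(t, "T"), analysis_cfg)
        assert est.bits == pytest.approx(true_te, abs=0.02)

    def test_null_bias_small_and_decreasing(self, analysis_cfg):
        means = {}
        for n in (10_000, 40_000):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                s = rng.integers(0, 2, n)
                t = rng.integers(0, 2, n)
                vals.append(
                    transfer_entropy(_series(s), _series(t), analysis_cfg).bits)
            means[n] = np.mean(vals)
        assert means[10_000] < 0.01
        assert means[40_000] < means[10_000]

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=30)
    def test_matches_chain_rule_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(50, 500)
        s = rng.integers(0, 2, n)
        t = rng.integers(0, 2, n)
        got = transfer_entropy(_series(s), _series(t), AnalysisConfig()).bits
        assert got == pytest.approx(te_oracle(s, t), abs=1e-12)
        assert got >= 0.0

    def test_invariant_under_symbol_relabeling(self, analysis_cfg):
        rng = np.random.default_rng(7)
        s = rng.integers(0, 2, 5000)
        t = rng.integers(0, 2, 5000)
        a = transfer_entropy(_series(s), _series(t), analysis_cfg).bits
        b = transfer_entropy(_series(1 - s), _series(1 - t), analysis_cfg).bits
        assert a == pytest.approx(b, abs=1e-12)

    def test_grid_mismatch_rejected(self, analysis_cfg):
        with pytest.raises(ValueError):
            transfer_entropy(_series([0, 1]), _series([0, 1], start_s=5.0),
                             analysis_cfg)


class TestPid:
    def test_xor_is_pure_synergy(self):
        p = np.zeros((2, 2, 2))
        for a in (0, 1):
            for b in (0, 1):
                p[a, b, a ^ b] = 0.25
        r = pid_from_joint(p)
        assert r.synergy == pytest.approx(1.0, abs=1e-12)
        assert r.redundancy == r.unique_source1 == r.unique_source2 == 0.0

    def test_duplicated_source_is_pure_redundancy(self):
        p = np.zeros((2, 2, 2))
        p[0, 0, 0] = p[1, 1, 1] = 0.5
        r = pid_from_joint(p)
        assert r.redundancy == pytest.approx(1.0, abs=1e-12)
        assert r.synergy == r.unique_source1 == r.unique_source2 == 0.0

    def test_single_informative_source_is_pure_unique(self):
        p = np.zeros((2, 2, 2))
        for a in (0, 1):
            for b in (0, 1):
                p[a, b, a] = 0.25
        r = pid_from_joint(p)
        assert r.unique_source1 == pytest.approx(1.0, abs=1e-12)
        assert r.redundancy == r.unique_source2 == r.synergy == 0.0

    def test_sampled_forced_cases_within_tolerance(self, analysis_cfg):
        rng = np.random.default_rng(3)
        n = 10_000
        s1 = rng.integers(0, 2, n)
        s2 = rng.integers(0, 2, n)
        # target realises XOR one lag later
        t = np.concatenate([[0], (s1 ^ s2)[:-1]])
        r = pid_two_sources(_series(s1, "s1"), _series(s2, "s2"),
                            _series(t, "t"), analysis_cfg)
        assert r.synergy == pytest.approx(1.0, abs=0.02)
        assert r.redundancy < 0.02
        t2 = np.concatenate([[0], s1[:-1]])
        r2 = pid_two_sources(_series(s1, "s1"), _series(s1, "s1b"),
                             _series(t2, "t"), analysis_cfg)
        assert r2.redundancy == pytest.approx(1.0, abs=0.02)
        r3 = pid_two_sources(_series(s1, "s1"), _series(s2, "s2"),
                             _series(t2, "t"), analysis_cfg)
        assert r3.unique_source1 == pytest.approx(1.0, abs=0.02)
        assert r3.unique_source2 < 0.02

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=100)
    def test_lattice_identities_on_random_distributions(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((2, 2, 2))
        p /= p.sum()
        r = pid_from_joint(p)
        assert r.redundancy >= 0 and r.synergy >= 0
        assert r.unique_source1 >= 0 and r.unique_source2 >= 0
        assert r.redundancy + r.unique_source1 == pytest.approx(r.mi_source1, abs=1e-10)
        assert r.redundancy + r.unique_source2 == pytest.approx(r.mi_source2, abs=1e-10)
        total = (r.redundancy + r.unique_source1 + r.unique_source2 + r.synergy)
        assert total == pytest.approx(r.mi_joint, abs=1e-10)

    def test_zero_joint_mi_flagged(self, analysis_cfg):
        n = 2000
        s = np.zeros(n, dtype=int)
        r = pid_two_sources(_series(s, "a"), _series(s, "b"), _series(s, "c"),
                            analysis_cfg)
        assert r.degenerate and r.proportions is None

    def test_proportions_sum_to_one(self, analysis_cfg):
        rng = np.random.default_rng(9)
        s1 = rng.integers(0, 2, 5000)
        s2 = rng.integers(0, 2, 5000)
        t = np.concatenate([[0], s1[:-1] | s2[:-1]])
        r = pid_two_sources(_series(s1), _series(s2), _series(t), analysis_cfg)
        assert sum(r.proportions.values()) == pytest.approx(1.0, abs=1e-10)


class TestSessionSummaries:
    def test_single_pair_yields_six_directions(self, analysis_cfg):
        rng = np.random.default_rng(0)
        mk = lambda lbl: _series(rng.integers(0, 2, 2000), lbl)
        out = pairwise_te_summary([mk("fn")], [mk("pag")], mk("motor"),
                                  analysis_cfg)
        assert len(out) == 6
        assert set(out.direction) == {"FN->PAG", "PAG->FN", "FN->motor",
                                      "motor->FN", "PAG->motor", "motor->PAG"}
        assert (out.n_pairs == 1).all()

    def test_independent_cells_have_negligible_te(self, analysis_cfg):
        rng = np.random.default_rng(1)
        mk = lambda lbl: _series(rng.integers(0, 2, 10_000), lbl)
        out = pairwise_te_summary([mk("f0"), mk("f1")], [mk("p0"), mk("p1")],
                                  mk("motor"), analysis_cfg)
        assert (out.mean_te_bits < 0.01).all()

    def test_directed_coupling_recovered(self):
        wins = 0
        for seed in range(20):
            cfg = fnpag.SimConfig(duration_s=300.0, n_source_cells=2,
                                  n_target_cells=2, seed=seed)
            path, _ = fnpag.simulate_behavior_states(cfg)
            trains, _ = fnpag.simulate_spiketrains(path, cfg)
            acfg = AnalysisConfig()
            span = (0.0, 300.0)
            fn = [bin_spiketrain(t, acfg, span) for t in trains if t.region == "FN"]
            pag = [bin_spiketrain(t, acfg, span) for t in trains if t.region == "PAG"]
            state = MotorState(np.arange(path.size) / cfg.sample_rate_hz, path, 0, 0)
            motor = align_motor_to_bins(state, acfg, span)
            out = pairwise_te_summary(fn, pag, motor, acfg).set_index("direction")
            wins += (out.loc["FN->PAG", "mean_te_bits"]
                     > out.loc["PAG->FN", "mean_te_bits"])
        assert wins >= 19

    def test_stationary_stages_have_similar_proportions(self):
        cfg = fnpag.SimConfig(duration_s=900.0, n_source_cells=1,
                              n_target_cells=1, seed=5)
        path, _ = fnpag.simulate_behavior_states(cfg)
        trains, _ = fnpag.simulate_spiketrains(path, cfg)
        stages = {"baseline": (0.0, 300.0), "conditioning": (300.0, 600.0),
                  "after": (600.0, 900.0)}
        acfg = AnalysisConfig(stages=stages)
        span = (0.0, 900.0)
        fn = bin_spiketrain(trains[0], acfg, span)
        pag = bin_spiketrain(trains[1], acfg, span)
        state = MotorState(np.arange(path.size) / cfg.sample_rate_hz, path, 0, 0)
        motor = align_motor_to_bins(state, acfg, span)
        res = stage_proportions(fn, motor, pag, acfg)
        props = [res[s].proportions["unique_source1"] for s in stages]
        assert max(props) - min(props) < 0.25
        for s in stages:
            assert sum(res[s].proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_short_stage_window_rejected(self, analysis_cfg):
        rng = np.random.default_rng(0)
        series = _series(rng.integers(0, 2, 1000))
        cfg = AnalysisConfig(stages={"baseline": (0.0, 0.5)})
        with pytest.raises(ValueError, match="fewer"):
            stage_proportions(series, series, series, cfg)
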