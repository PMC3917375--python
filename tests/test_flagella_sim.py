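"""Motor telegraph kernel, waveform overlay, run rules and cell assembly."""

import numpy as np
import pytest

from vetoflag import (
    ModelParams,
    MotorParams,
    WaveformParams,
    apply_run_rule,
    overlay_waveforms,
    simulate_cell,
    simulate_motor,
)
from vetoflag.flagella_sim import (
    CCW,
    CURLY_1,
    CW,
    NORMAL,
    SEMI_COILED,
    StabilityError,
)
from vetoflag.trace_analysis import cell_cw_bias, cell_tumble_bias


def dwell_lengths(states, which):
    padded = np.diff(np.concatenate(([0], (states == which).astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return ends - starts


class TestSimulateMotor:
    def test_zero_bias_stays_ccw(self):
        trace = simulate_motor(np.zeros(5000), omega=0.5, dt=0.001, seed=0)
        assert np.all(trace.states == CCW)

    def test_printed_rates(self):
        mp = MotorParams(omega=0.5)
        assert mp.k_ccw_cw(0.13) == pytest.approx(0.26)
        assert mp.k_cw_ccw(0.13) == pytest.approx(1.74)
        assert round(mp.k_cw_ccw(0.13), 1) == 1.7

    def test_telegraph_closed_forms(self):
        # occupancy CB, mean CW dwell omega/(1-CB), mean CCW dwell omega/CB
        dt, omega, cb = 0.001, 0.5, 0.13
        trace = simulate_motor(np.full(500_000, cb), omega=omega, dt=dt, seed=1)
        assert trace.cw_fraction == pytest.approx(cb, abs=0.015)
        cw_d = dwell_lengths(trace.states, CW)[1:-1] * dt
        ccw_d = dwell_lengths(trace.states, CCW)[1:-1] * dt
        assert cw_d.mean() == pytest.approx(omega / (1 - cb), rel=0.1)
        assert ccw_d.mean() == pytest.approx(omega / cb, rel=0.1)

    def test_stability_guard(self):
        with pytest.raises(StabilityError):
            simulate_motor(np.full(10, 0.5), omega=0.5, dt=0.2, seed=0)

    def test_deterministic(self):
        cb = np.full(2000, 0.3)
        a = simulate_motor(cb, 0.5, 0.001, seed=7)
        b = simulate_motor(cb, 0.5, 0.001, seed=7)
        assert np.array_equal(a.states, b.states)


class TestOverlayWaveforms:
    def make_motor(self, cb=0.13, n=5_000_000, seed=2):
        # ~0.26 CW episodes per second: 5000 s gives >1000 episodes
        return simulate_motor(np.full(n, cb), omega=0.5, dt=0.001, seed=seed)

    def test_ccw_is_normal_and_cw_never_normal(self):
        motor = self.make_motor(n=50_000)
        wf = overlay_waveforms(motor, WaveformParams(), seed=3)
        assert np.all(wf.states[motor.states == CCW] == NORMAL)
        assert np.all(wf.states[motor.states == CW] != NORMAL)

    def test_entry_branching_matches_rate_ratio(self):
        # direct curly-1 entries at rate ratio 0.08/(0.28+0.08) = 0.2222
        motor = self.make_motor(seed=4)
        wf = overlay_waveforms(motor, WaveformParams(), seed=5)
        padded = np.diff(np.concatenate(([0], (motor.states == CW).astype(int), [0])))
        starts = np.flatnonzero(padded == 1)
        assert starts.size >= 1000
        entries = wf.states[starts]
        frac_curly = np.mean(entries == CURLY_1)
        p = 0.08 / 0.36
        se = np.sqrt(p * (1 - p) / starts.size)
        assert abs(frac_curly - p) < 4 * se

    def test_curly_entry_interval_never_semi_coiled(self):
        motor = self.make_motor(n=200_000, seed=6)
        wf = overlay_waveforms(motor, WaveformParams(), seed=7)
        padded = np.diff(np.concatenate(([0], (motor.states == CW).astype(int), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        checked = 0
        for i, j in zip(starts, ends):
            seq = wf.states[i:j]
            if seq[0] == CURLY_1:
                assert not np.any(seq == SEMI_COILED)
                checked += 1
            else:
                # semi-coiled may convert to curly-1 but never revert
                switch = np.flatnonzero(np.diff(seq))
                assert len(switch) <= 1
        assert checked > 0

    def test_zero_conversion_rate_freezes_entry_state(self):
        # with no semi-coiled -> curly-1 conversion, every CW interval
        # keeps its entry waveform for its whole duration
        motor = self.make_motor(n=100_000, seed=8)
        wf = overlay_waveforms(motor, WaveformParams(lambda_rate=0.0), seed=9)
        padded = np.diff(np.concatenate(([0], (motor.states == CW).astype(int), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        saw_semi = False
        for i, j in zip(starts, ends):
            seq = wf.states[i:j]
            assert len(np.unique(seq)) == 1
            assert seq[0] in (SEMI_COILED, CURLY_1)
            saw_semi = saw_semi or seq[0] == SEMI_COILED
        assert saw_semi


class TestApplyRunRule:
    def test_all_ccw_is_all_run(self):
        out = apply_run_rule(np.zeros((3, 50), dtype=np.int8))
        assert np.all(out == 0)

    def test_hand_built_trace_veto(self, toy_cell):
        out = apply_run_rule(toy_cell.motor)
        expected = np.zeros(20, dtype=np.int8)
        expected[4:9] = 1  # windows 5-9, 1-indexed
        assert np.array_equal(out, expected)

    def test_matches_and_oracle_on_random_traces(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            mats = (rng.random((rng.integers(1, 5), 30)) < 0.3).astype(np.int8)
            oracle = np.array([int(any(mats[:, t])) for t in range(30)], dtype=np.int8)
            assert np.array_equal(apply_run_rule(mats), oracle)

    def test_curly_run_prob_one_relabels_all_single_curly_intervals(self):
        wf = np.zeros((3, 30), dtype=np.int8)
        wf[0, 5:10] = CURLY_1
        wf[1, 15:20] = SEMI_COILED
        params = WaveformParams(curly_run_prob=1.0)
        out = apply_run_rule(wf, params, seed=0, variant="curly_run")
        assert np.all(out[5:10] == 0)  # single curly-1, others normal: run
        assert np.all(out[15:20] == 1)  # semi-coiled still vetoes

    def test_x_rule(self):
        wf = np.zeros((3, 20), dtype=np.int8)
        wf[0, 2:6] = CURLY_1  # 2 normal flagella, CW one is curly-1
        wf[0, 10:14] = SEMI_COILED
        params = WaveformParams(x_rule=2)
        out = apply_run_rule(wf, params, variant="x_rule")
        assert np.all(out[2:6] == 0)
        assert np.all(out[10:14] == 1)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            apply_run_rule([np.zeros(5, dtype=np.int8), np.zeros(6, dtype=np.int8)])


class TestSimulateCell:
    def test_single_flagellum_tb_equals_cb(self, model):
        cell = simulate_cell(model, 1, 30.0, "constant_cb", seed=0)
        assert cell_tumble_bias(cell) == pytest.approx(cell_cw_bias(cell), abs=1e-12)

    def test_constant_cb_matches_veto_prediction(self, model):
        cell = simulate_cell(model, 3, 500.0, "constant_cb", seed=1, with_waveforms=False)
        tb, cb = cell_tumble_bias(cell), cell_cw_bias(cell)
        assert tb == pytest.approx(1 - (1 - 0.13) ** 3, abs=0.03)
        from vetoflag import deviation_eta

        assert deviation_eta(tb, cb, 3) == pytest.approx(0.0, abs=0.35)

    def test_veto_consistency_every_step(self, model):
        cell = simulate_cell(model, 4, 20.0, "constant_cb", seed=2)
        oracle = (cell.motor == CW).any(axis=0).astype(np.int8)
        assert np.array_equal(cell.tumble, oracle)

    def test_occupancy_tracks_driving_bias(self, model):
        cell = simulate_cell(
            model, 2, 200.0, "wildtype_fluctuating", seed=3, cb_range=None,
            with_waveforms=False,
        )
        from vetoflag import hill_cw_bias

        drive = hill_cw_bias(cell.chey_trace.values, model.hill)
        assert cell_cw_bias(cell) == pytest.approx(drive.mean(), abs=0.04)

    def test_bitwise_reproducible(self, model):
        a = simulate_cell(model, 3, 10.0, "wildtype_fluctuating", seed=11, cb_range=None)
        b = simulate_cell(model, 3, 10.0, "wildtype_fluctuating", seed=11, cb_range=None)
        assert np.array_equal(a.motor, b.motor)
        assert np.array_equal(a.tumble, b.tumble)
        assert np.array_equal(a.waveform, b.waveform)

    def test_adding_flagellum_preserves_other_streams(self, model):
        small = simulate_cell(model, 2, 10.0, "constant_cb", seed=12)
        big = simulate_cell(model, 3, 10.0, "constant_cb", seed=12)
        assert np.array_equal(small.motor[0], big.motor[0])
        assert np.array_equal(small.motor[1], big.motor[1])
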