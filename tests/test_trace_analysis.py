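"""Trace estimators against brute-force oracles and closed forms."""

import numpy as np
import pytest

from vetoflag import (
    ModelParams,
    WaveformParams,
    cell_cw_bias,
    cell_tumble_bias,
    estimate_rates,
    filter_cells,
    independent_null,
    mean_max_cw,
    overlay_waveforms,
    pair_cross_correlation,
    simulate_motor,
    summarize_cell,
    tumble_events,
)
from vetoflag.model_core import CellSummary
from vetoflag.trace_analysis import EmptyTraceError, group_eta


# ---------------------------------------------------------------------------
# brute-force oracles (naive loops, independent of the implementation)


def oracle_cw_bias(motor):
    fracs = []
    for row in motor:
        fracs.append(sum(1 for s in row if s == 1) / len(row))
    return sum(fracs) / len(fracs)


def oracle_events(tumble):
    events, start = [], None
    for t, s in enumerate(tumble):
        if s == 1 and start is None:
            start = t
        elif s == 0 and start is not None:
            events.append((start, t))
            start = None
    if start is not None:
        events.append((start, len(tumble)))
    return events


def oracle_xcorr_lag0(a, b):
    ma, mb = np.mean(a), np.mean(b)
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / len(a)
    return num / (np.std(a) * np.std(b))


class TestBiases:
    def test_toy_cell_biases(self, toy_cell):
        assert cell_cw_bias(toy_cell) == pytest.approx(0.15)
        assert cell_tumble_bias(toy_cell) == pytest.approx(0.25)

    def test_toy_cell_eta(self, toy_cell):
        summary = summarize_cell(toy_cell)
        assert summary.eta == pytest.approx(-1.2299, abs=1e-4)

    def test_two_flagella_mean(self, toy_factory):
        motor = np.zeros((2, 10), dtype=np.int8)
        motor[0, :2] = 1
        motor[1, :4] = 1
        assert cell_cw_bias(toy_factory(motor)) == pytest.approx(0.3)

    def test_matches_oracle_on_random_traces(self, toy_factory):
        rng = np.random.default_rng(0)
        for _ in range(25):
            motor = (rng.random((rng.integers(1, 5), 10)) < 0.4).astype(np.int8)
            cell = toy_factory(motor)
            assert cell_cw_bias(cell) == pytest.approx(oracle_cw_bias(motor), abs=1e-12)
            assert cell_tumble_bias(cell) == pytest.approx(
                np.mean(motor.max(axis=0)), abs=1e-12
            )

    def test_empty_trace_errors(self, toy_factory):
        cell = toy_factory(np.zeros((1, 0), dtype=np.int8))
        with pytest.raises(EmptyTraceError):
            cell_cw_bias(cell)


class TestTumbleEvents:
    def test_toy_cell_single_event(self, toy_cell):
        events = tumble_events(toy_cell)
        assert len(events) == 1
        ev = events[0]
        assert ev.start == pytest.approx(0.4)
        assert ev.end == pytest.approx(0.9)
        assert ev.max_cw == 3
        assert ev.complete

    def test_all_run_gives_no_events(self, toy_factory):
        cell = toy_factory(np.zeros((2, 15), dtype=np.int8))
        assert tumble_events(cell) == []

    def test_boundary_event_incomplete(self, toy_factory):
        motor = np.zeros((1, 10), dtype=np.int8)
        motor[0, :3] = 1
        events = tumble_events(toy_factory(motor))
        assert len(events) == 1 and not events[0].complete
        assert mean_max_cw([toy_factory(motor)]).empty

    def test_matches_oracle_scanner(self, toy_factory):
        rng = np.random.default_rng(1)
        for _ in range(25):
            motor = (rng.random((3, 12)) < 0.35).astype(np.int8)
            cell = toy_factory(motor)
            got = [(int(e.start / 0.1 + 0.5), int(e.end / 0.1 + 0.5)) for e in tumble_events(cell)]
            assert got == oracle_events(motor.max(axis=0))

    def test_single_flagellum_max_cw_is_one(self, model):
        from vetoflag import simulate_cell

        cell = simulate_cell(model, 1, 60.0, "constant_cb", seed=5)
        df = mean_max_cw([cell])
        if not df.empty:
            assert df.mean_max_cw.iloc[0] == pytest.approx(1.0)


class TestCrossCorrelation:
    def test_identical_traces_give_one_at_lag0(self, toy_factory):
        rng = np.random.default_rng(2)
        row = (rng.random(50) < 0.3).astype(np.int8)
        cell = toy_factory(np.vstack([row, row]))
        xc = pair_cross_correlation(cell, max_lag=0.5)
        mid = xc.values.size // 2
        assert xc.values[mid] == pytest.approx(1.0, abs=1e-12)

    def test_shifted_trace_peaks_at_shift(self, toy_factory):
        rng = np.random.default_rng(3)
        row = (rng.random(300) < 0.3).astype(np.int8)
        k = 4
        cell = toy_factory(np.vstack([row, np.roll(row, k)]))
        xc = pair_cross_correlation(cell, max_lag=1.0)
        peak_lag = xc.lags[np.argmax(xc.values)]
        assert peak_lag == pytest.approx(k * 0.1, abs=1e-9)

    def test_independent_motors_uncorrelated(self, model):
        cb = np.full(500_000, 0.13)
        m1 = simulate_motor(cb, 0.5, 0.001, seed=4).states
        m2 = simulate_motor(cb, 0.5, 0.001, seed=5).states
        cell = type("C", (), {"n_flag": 2, "motor": np.vstack([m1, m2]), "step": 0.001})
        xc = pair_cross_correlation(cell, max_lag=0.01)
        mid = xc.values.size // 2
        # MC standard error of the sample correlation over 500 s with a
        # 0.5 s motor relaxation time is ~0.03; stay within 3 SE
        assert abs(xc.values[mid]) < 0.1

    def test_symmetric_in_pair_order_and_matches_oracle(self, toy_factory):
        rng = np.random.default_rng(6)
        a = (rng.random(40) < 0.4).astype(np.int8)
        b = (rng.random(40) < 0.4).astype(np.int8)
        xc_ab = pair_cross_correlation(toy_factory(np.vstack([a, b])), max_lag=0.3)
        xc_ba = pair_cross_correlation(toy_factory(np.vstack([b, a])), max_lag=0.3)
        mid = xc_ab.values.size // 2
        assert xc_ab.values[mid] == pytest.approx(xc_ba.values[mid], abs=1e-12)
        assert xc_ab.values[mid] == pytest.approx(oracle_xcorr_lag0(a, b), abs=1e-12)
        assert np.all(np.abs(xc_ab.values) <= 1 + 1e-9)

    def test_zero_variance_pair_skipped(self, toy_factory):
        motor = np.zeros((2, 30), dtype=np.int8)
        motor[0, ::3] = 1
        with pytest.warns(UserWarning, match="zero-variance"):
            xc = pair_cross_correlation(toy_factory(motor))
        assert xc.n_pairs == 0


class TestRateEstimation:
    def test_single_transition_rate(self, toy_factory):
        # one normal->semi transition over 10 s of normal dwell
        wf = np.zeros(101, dtype=np.int8)
        wf[100] = 1
        motor = (wf > 0).astype(np.int8)
        cell = toy_factory(motor[None, :], step=0.1)
        cell.waveform = wf[None, :]
        rates = estimate_rates([cell])
        row = rates.waveform_rates.query(
            "from_state=='normal' and to_state=='semi_coiled'"
        ).iloc[0]
        assert row.rate == pytest.approx(1 / 10.0, abs=1e-12)

    def test_recovers_generating_rates(self, model):
        cb = np.full(400_000, 0.13)
        cells = []
        for seed in range(3):
            m = simulate_motor(cb, 0.5, 0.001, seed=seed)
            wf = overlay_waveforms(m, WaveformParams(), seed=seed + 10)
            cell = type("C", (), {
                "n_flag": 1, "motor": m.states[None, :],
                "waveform": wf.states[None, :], "step": 0.001,
            })
            cells.append(cell)
        rates = estimate_rates(cells)
        assert rates.k_ccw_cw == pytest.approx(0.26, abs=3 * rates.k_ccw_cw_se)
        assert rates.k_cw_ccw == pytest.approx(1.74, abs=3 * rates.k_cw_ccw_se)
        sc = rates.waveform_rates.query(
            "from_state=='semi_coiled' and to_state=='curly_1'"
        ).iloc[0]
        assert sc.rate == pytest.approx(0.68, abs=3 * sc.se)

    def test_direct_curly_branching_fraction(self, model):
        cb = np.full(5_000_000, 0.13)
        m = simulate_motor(cb, 0.5, 0.001, seed=20)
        wf = overlay_waveforms(m, WaveformParams(), seed=21)
        cell = type("C", (), {
            "n_flag": 1, "motor": m.states[None, :],
            "waveform": wf.states[None, :], "step": 0.001,
        })
        hist = estimate_rates([cell]).sequence_histogram
        n_direct = sum(v for k, v in hist.items() if k.startswith("NC"))
        n_total = sum(hist.values())
        assert n_total >= 1000
        p = 0.08 / 0.36
        se = np.sqrt(p * (1 - p) / n_total)
        assert abs(n_direct / n_total - p) < 4 * se


class TestIndependentNull:
    def test_null_statistics(self, model):
        etas = []
        for seed in range(100):
            out = independent_null(3, 0.13, 30.0, model, seed=seed)
            if out["events"]:
                assert min(e.max_cw for e in out["events"]) >= 1
            if out["summary"].eta is not None:
                etas.append(out["summary"].eta)
        etas = np.array(etas)
        sem = etas.std(ddof=1) / np.sqrt(etas.size)
        assert abs(etas.mean()) < 3 * max(sem, 0.02)

    def test_null_max_cw_trends_upward(self, model):
        means = {}
        for n_flag in (1, 3, 5):
            cells = []
            from vetoflag import simulate_cell

            for seed in range(20):
                cells.append(
                    simulate_cell(model, n_flag, 40.0, "constant_cb",
                                  seed=1000 + 50 * n_flag + seed, cb_constant=0.13,
                                  with_waveforms=False)
                )
            df = mean_max_cw(cells)
            means[n_flag] = float(df.mean_max_cw.iloc[0])
        assert means[1] == pytest.approx(1.0)
        assert means[1] <= means[3] <= means[5]


class TestFilters:
    def test_identity_interval(self):
        cells = [CellSummary(2, 0.3, 0.2), CellSummary(2, 0.5, 0.6)]
        assert filter_cells(cells, (0.0, 1.0)) == cells

    def test_outlier_excluded(self):
        cells = [CellSummary(2, 0.3, 0.3)]
        assert filter_cells(cells, (0.0, 0.25)) == []

    def test_cohort_counting(self):
        rng = np.random.default_rng(7)
        inside = [CellSummary(2, 0.2, float(c)) for c in rng.uniform(0.01, 0.25, 61)]
        outside = [CellSummary(2, 0.4, float(c)) for c in rng.uniform(0.26, 0.5, 8)]
        kept = filter_cells(inside + outside, (0.0, 0.25))
        assert len(inside + outside) == 69 and len(kept) == 61

    def test_group_eta_averages_per_cell_then_group(self):
        cells = [
            CellSummary(2, 0.2, 0.1, eta=-0.5),
            CellSummary(2, 0.25, 0.12, eta=-1.0),
            CellSummary(3, 0.3, 0.1, eta=0.25),
        ]
        df = group_eta(cells)
        assert df[df.n_flag == 2].eta_mean.iloc[0] == pytest.approx(-0.75)
        assert df[df.n_flag == 3].n_cells.iloc[0] == 1
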