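"""Point-process fiber model: threshold statistics, refractoriness, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

import cisync as cs
from cisync.current_spread import FieldTraceSet
from cisync.neuron import (
    CalibrationError,
    FiberParams,
    _fiber_streams,
    _run_population,
    default_threshold_grid,
)
from cisync.strategies import PulseParams


def _pulse_traces(times_us, amps, n_pos=1, duration_us=None):
    times_us = np.asarray(times_us, float)
    amps = np.asarray(amps, float)
    E = np.tile(amps[:, None], (1, n_pos))
    return FieldTraceSet(
        positions_mm=np.arange(n_pos, dtype=float),
        pulse_times_us=times_us,
        eff_amplitudes_ma=E,
        params=PulseParams(),
        duration_us=duration_us or (times_us.max() + 1000.0),
    )


def _single_pulse_prob(rel_amp, n_trials=100_000, seed=3):
    """Empirical firing probability for one isolated pulse at rel_amp * theta."""
    p = FiberParams(threshold_ma=0.4)
    theta = np.full(n_trials, p.threshold_ma)
    eff = np.full((1, n_trials), rel_amp * p.threshold_ma)
    keys = [(i,) for i in range(n_trials)]
    U, G = _fiber_streams(seed, keys, 1)
    out = _run_population(np.array([100.0]), eff, theta, p, U, G)
    return np.mean([len(s) for s in out])


class TestSinglePulseStatistics:
    def test_probability_half_at_threshold(self):
        # the defining property of a threshold/relative-spread model
        assert _single_pulse_prob(1.0) == pytest.approx(0.5, abs=0.01)

    def test_probability_phi2_two_sigmas_above(self):
        p = FiberParams()
        rel = 1.0 + 2.0 * p.relative_spread
        assert _single_pulse_prob(rel) == pytest.approx(ndtr(2.0), abs=0.01)

    def test_probability_monotone_in_amplitude(self):
        probs = [_single_pulse_prob(r, n_trials=20_000) for r in
                 (0.8, 0.95, 1.0, 1.1, 1.3)]
        assert np.all(np.diff(probs) >= 0)
        assert probs[0] < 0.01 and probs[-1] > 0.99


class TestRefractoriness:
    def test_no_intervals_below_absolute_refractory(self):
        # hammer one fiber with a suprathreshold 90 kpps single-channel train
        p = FiberParams(threshold_ma=0.2)
        t = np.arange(0, 50_000.0, 11.0)
        traces = _pulse_traces(t, np.full(len(t), 0.5))
        for seed in range(20):
            spikes = cs.simulate_fiber(traces.trace(0), p, seed=seed)
            if len(spikes) > 1:
                # 1e-6 µs slack for the µs -> s -> µs float round trip
                assert np.min(np.diff(spikes)) * 1e6 >= p.abs_refractory_us - 1e-6

    def test_relative_refractory_elevates_threshold(self):
        # pulse pairs: the second pulse, just after the absolute period,
        # fires less often than an unconditioned pulse at the same level
        p = FiberParams(threshold_ma=0.4, jitter_sd_us=0.0)
        n = 20_000
        theta = np.full(n, p.threshold_ma)
        strong = 5.0 * p.threshold_ma   # first pulse: always fires
        probe = 1.0 * p.threshold_ma
        eff = np.tile(np.array([[strong], [probe]]), (1, n))
        U, G = _fiber_streams(11, [(i,) for i in range(n)], 2)
        out = _run_population(
            np.array([100.0, 100.0 + p.abs_refractory_us + 50.0]),
            eff, theta, p, U, G,
        )
        second = np.mean([len(s) == 2 for s in out])
        assert second < 0.25  # far below the unconditioned 0.5

    def test_deterministic_periodic_limit(self):
        # no jitter, strong periodic pulses slower than refractoriness
        p = FiberParams(threshold_ma=0.2, jitter_sd_us=0.0)
        t = np.arange(0, 20_000.0, 2000.0)
        traces = _pulse_traces(t, np.full(len(t), 1.0))
        spikes = cs.simulate_fiber(traces.trace(0), p, seed=0)
        assert len(spikes) == len(t)
        np.testing.assert_allclose(np.diff(spikes), 2000e-6, atol=1e-12)

    def test_summation_of_subthreshold_pulse_pairs(self):
        # two 0.6-threshold pulses 20 µs apart integrate to fire;
        # the same pair 5 ms apart does not
        p = FiberParams(threshold_ma=0.4, jitter_sd_us=0.0)

        def fire_frac(gap_us):
            n = 5000
            theta = np.full(n, p.threshold_ma)
            eff = np.tile(np.array([[0.6 * 0.4], [0.6 * 0.4]]), (1, n))
            U, G = _fiber_streams(21, [(i,) for i in range(n)], 2)
            out = _run_population(
                np.array([100.0, 100.0 + gap_us]), eff, theta, p, U, G
            )
            return np.mean([len(s) > 0 for s in out])

        assert fire_frac(20.0) > 0.9
        assert fire_frac(5000.0) < 0.01


class TestPopulation:
    def test_default_threshold_grid_has_15_values(self):
        g = default_threshold_grid()
        assert len(g) == 15
        assert g[0] == pytest.approx(0.1)
        assert g[-1] == pytest.approx(0.8)
        np.testing.assert_allclose(np.diff(g), 0.05)

    def test_standard_position_grids(self):
        # single-electrode neural maps: +/-10 mm in 0.1 mm steps
        single = np.arange(-10.0, 10.0 + 1e-9, 0.1)
        assert len(single) == 201
        # rate study: 0-30 mm in 0.1 mm steps
        rate = np.arange(0.0, 30.0 + 1e-9, 0.1)
        assert len(rate) == 301

    def test_population_shape_and_seed_reproducibility(self):
        t = np.arange(0.0, 5000.0, 244.0)
        traces = _pulse_traces(t, np.full(len(t), 0.4), n_pos=3)
        r1 = cs.simulate_population(traces, master_seed=5)
        r2 = cs.simulate_population(traces, master_seed=5)
        assert r1.n_fibers == 3 * 15
        for a, b in zip(r1.spikes, r2.spikes):
            np.testing.assert_array_equal(a, b)

    def test_fiber_streams_stable_under_population_growth(self):
        t = np.arange(0.0, 5000.0, 244.0)
        small = _pulse_traces(t, np.full(len(t), 0.4), n_pos=2)
        large = _pulse_traces(t, np.full(len(t), 0.4), n_pos=4)
        thr = np.array([0.1, 0.2])
        r_small = cs.simulate_population(small, thr, master_seed=9)
        r_large = cs.simulate_population(large, thr, master_seed=9)
        # fibers sharing (position index, threshold index) get identical spikes
        tab_s = r_small.fiber_table
        tab_l = r_large.fiber_table
        for i in range(len(tab_s)):
            pos, th = tab_s.iloc[i][["position_mm", "threshold_mA"]]
            j = np.flatnonzero(
                (tab_l["position_mm"] == pos) & (tab_l["threshold_mA"] == th)
            )[0]
            np.testing.assert_array_equal(r_small.spikes[i], r_large.spikes[j])

    def test_raster_csv(self, tmp_path):
        t = np.arange(0.0, 3000.0, 244.0)
        traces = _pulse_traces(t, np.full(len(t), 0.6))
        r = cs.simulate_population(traces, np.array([0.1]), master_seed=1)
        p = tmp_path / "raster.csv"
        r.to_csv(p)
        df = pd.read_csv(p)
        assert {"position_mm", "threshold_mA", "spike_time_s"} <= set(df.columns)
        assert len(df) == r.n_spikes


class TestCalibration:
    def _traces(self):
        t = np.arange(0.0, 30_000.0, 244.0)
        return _pulse_traces(t, np.maximum(np.sin(2 * np.pi * 500 * t * 1e-6), 0),
                             n_pos=21)

    def test_scale_monotonicity(self):
        traces = self._traces()
        thr = default_threshold_grid()
        rates = []
        for s in (0.05, 0.2, 0.8, 3.0):
            r = cs.simulate_population(traces, thr, master_seed=2, scale=s)
            rates.append(r.mean_rate())
        assert np.all(np.diff(rates) >= 0)

    def test_calibrated_rate_within_10pct(self):
        traces = self._traces()
        s = cs.calibrate_level(traces, 100.0, master_seed=2)
        r = cs.simulate_population(traces, master_seed=2, scale=s)
        assert 90.0 <= r.mean_rate() <= 110.0

    def test_unreachable_target_raises(self):
        traces = self._traces()
        with pytest.raises(CalibrationError):
            cs.calibrate_level(traces, 1e7, master_seed=2, bounds=(1e-3, 1.0))

    def test_near_zero_target_limit(self):
        # driving far below threshold: rate collapses toward zero
        traces = self._traces()
        r = cs.simulate_population(traces, master_seed=2, scale=1e-4)
        assert r.mean_rate() < 1.0
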