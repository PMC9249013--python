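"""Pulse-coding strategies: envelopes, carriers, peak timing, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cisync as cs
from cisync.filterbank import ChannelSignals
from cisync.strategies import FrameOverrunError, PulseParams, read_pulse_table, write_pulse_table

FS = 100_000.0


def _signals(data, fb):
    return ChannelSignals(data=np.asarray(data, float), spec=fb, sample_rate=FS)


class TestEnvelopes:
    def test_hilbert_envelope_flat_for_steady_tone(self, fb22):
        # steady in-band sinusoid: near-constant envelope after 5 cycles
        t = np.arange(3000) / FS
        data = np.zeros((22, 3000))
        data[7] = np.sin(2 * np.pi * 500.0 * t)
        env = cs.cis_envelopes(_signals(data, fb22)).data[7]
        steady = env[1000:2800]  # past onset, clear of the FFT edge
        ripple = (steady.max() - steady.min()) / steady.mean()
        assert ripple < 0.05

    def test_zero_in_zero_out(self, fb22):
        z = _signals(np.zeros((22, 1000)), fb22)
        assert np.all(cs.cis_envelopes(z).data == 0)
        assert np.all(cs.hdcis_envelopes(z).data == 0)

    def test_halfwave_zeros_negative_lobes(self, ch500):
        env = cs.hdcis_envelopes(ch500)
        assert np.all(env.data >= 0)
        neg = ch500.data < 0
        assert np.all(env.data[neg] == 0)

    def test_halfwave_period_equals_tone_period(self, ch500):
        env = cs.hdcis_envelopes(ch500).data[7]
        # autocorrelation peak of the steady envelope at one tone period
        steady = env[1000:] - env[1000:].mean()
        ac = np.correlate(steady, steady, "full")[len(steady) - 1 :]
        lag = np.argmax(ac[100:300]) + 100  # search 1-3 ms
        assert lag == pytest.approx(200, abs=2)  # 2 ms at 100 kHz

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_halfwave_nonnegative_for_arbitrary_input(self, fb22, seed):
        rng = np.random.default_rng(seed)
        sig = _signals(rng.normal(size=(22, 300)), fb22)
        assert np.all(cs.hdcis_envelopes(sig).data >= 0)


class TestCarrier:
    def test_per_channel_rate(self, hdcis500):
        # 90,000 pps over 22 channels -> ~4,090.9 pps per channel
        for e in (1, 8, 22):
            n = np.sum(hdcis500.electrodes == e)
            rate = n / (hdcis500.duration_us * 1e-6)
            assert rate == pytest.approx(90_000 / 22, rel=0.01)

    def test_constant_envelope_gives_constant_ipi(self, fb22):
        env = _signals(np.ones((22, 3000)), fb22)
        eg = cs.schedule_carrier(env, 90_000.0)
        t1 = np.sort(eg.times_us[eg.electrodes == 1])
        ipi = np.diff(t1)
        assert np.mean(ipi) == pytest.approx(22 / 90_000 * 1e6, abs=0.05)
        assert np.ptp(ipi) <= 1.0  # 1 µs grid rounding only

    def test_zero_envelope_zero_amplitudes(self, fb22):
        env = _signals(np.zeros((22, 3000)), fb22)
        eg = cs.schedule_carrier(env, 90_000.0)
        assert eg.n_pulses > 0
        assert np.all(eg.amplitudes_ma == 0)

    def test_amplitude_samples_envelope_at_onset(self, fb22):
        data = np.tile(np.linspace(0, 1, 3000), (22, 1))
        eg = cs.schedule_carrier(_signals(data, fb22), 90_000.0)
        expect = np.minimum(np.round(eg.times_us * 1e-6 * FS), 2999) / 2999
        np.testing.assert_allclose(eg.amplitudes_ma, expect, atol=1e-9)

    def test_cis_pulse_times_independent_of_frequency(self, fb22):
        def times(freq):
            w = cs.make_pure_tone(freq, 0.010, FS)
            ch = cs.apply_filterbank(w, fb22)
            return cs.schedule_carrier(cs.cis_envelopes(ch)).times_us

        np.testing.assert_array_equal(times(500.0), times(1234.5))

    def test_footprint_must_fit_frame(self, fb22):
        env = _signals(np.ones((22, 3000)), fb22)
        # 22 channels at 500,000 pps: frame of 44 µs < 58 µs footprint
        with pytest.raises(FrameOverrunError):
            cs.schedule_carrier(env, 500_000.0)

    def test_onsets_unique_and_sorted(self, hdcis500, cis500):
        for eg in (hdcis500, cis500):
            assert np.all(np.diff(eg.times_us) > 0)

    def test_charge_bookkeeping(self, hdcis500):
        assert hdcis500.total_charge == pytest.approx(
            np.sum(hdcis500.amplitudes_ma * hdcis500.params.phase_us)
        )


class TestPDT:
    def test_pulse_rate_matches_tone_frequency(self, pdt500):
        # ~1 pulse per 2 ms on the 500 Hz channel
        n = np.sum(pdt500.electrodes == 8)
        assert abs(n - 0.030 * 500) <= 2

    def test_monotonic_signal_has_no_pulses(self, fb22):
        data = np.tile(np.linspace(0.0, 1.0, 1000), (22, 1))
        eg = cs.pdt_encode(_signals(data, fb22))
        assert eg.n_pulses == 0

    def test_colliding_peaks_are_offset(self, fb22):
        # two channels peak at the same sample; both emitted, no shared onset
        row = np.zeros(1000)
        row[500] = 1.0
        row[499] = row[501] = 0.5
        data = np.zeros((22, 1000))
        data[3] = row
        data[9] = row
        eg = cs.pdt_encode(_signals(data, fb22))
        assert eg.n_pulses == 2
        assert len(set(eg.times_us.tolist())) == 2
        assert np.min(np.abs(np.diff(eg.times_us))) >= eg.params.footprint_us

    def test_plateau_takes_first_sample(self, fb22):
        row = np.zeros(1000)
        row[300:310] = 1.0  # flat top reached by a rise, left by a fall
        data = np.zeros((22, 1000))
        data[0] = row
        eg = cs.pdt_encode(_signals(data, fb22))
        assert eg.n_pulses == 1
        assert eg.times_us[0] == pytest.approx(300 / FS * 1e6)

    def test_amplitudes_equal_peak_values(self, pdt500, ch500):
        m = pdt500.electrodes == 8
        peaks = pdt500.amplitudes_ma[m]
        assert np.all(peaks > 0)
        assert peaks.max() == pytest.approx(ch500.data[7].max(), rel=1e-9)


class TestHDACE:
    @pytest.mark.parametrize(
        "total,n_max,expected",
        [(14_400.0, 8, 1800.0), (3_500.0, 5, 700.0), (90_000.0, 8, 11_250.0)],
    )
    def test_per_electrode_rate(self, fb22, total, n_max, expected):
        env = _signals(np.ones((22, 3000)), fb22)
        eg = cs.hd_ace_select(env, total, n_max)
        # every frame picks the same channels (constant envelope, low ties)
        sel = np.unique(eg.electrodes)
        assert len(sel) == n_max
        n = np.sum(eg.electrodes == sel[0])
        assert n / (eg.duration_us * 1e-6) == pytest.approx(expected, rel=0.02)

    def test_ties_break_to_lower_channel(self, fb22):
        env = _signals(np.ones((22, 3000)), fb22)
        eg = cs.hd_ace_select(env, 14_400.0, 4)
        assert set(np.unique(eg.electrodes)) == {1, 2, 3, 4}

    def test_selection_of_all_channels_is_plain_carrier(self, ch500):
        env = cs.hdcis_envelopes(ch500)
        full = cs.hd_ace_select(env, 90_000.0, 22)
        plain = cs.schedule_carrier(env, 90_000.0)
        np.testing.assert_array_equal(full.times_us, plain.times_us)
        np.testing.assert_array_equal(full.electrodes, plain.electrodes)
        np.testing.assert_allclose(full.amplitudes_ma, plain.amplitudes_ma)

    def test_selects_highest_envelope_channels(self, ch500):
        env = cs.hdcis_envelopes(ch500)
        eg = cs.hd_ace_select(env, 14_400.0, 4)
        charges = eg.channel_charges()
        # the 500 Hz channel (electrode 8) must dominate
        assert np.argmax(charges) + 1 == 8


class TestHighRateLimit:
    def test_hdcis_charge_weighted_vs_approaches_pi_over_4(self, fb22):
        """Analytic oracle: half-wave sine weights on a dense uniform grid.

        |int_0^pi sin(t) e^{jt} dt| / int_0^pi sin(t) dt = (pi/2) / 2.
        """
        f = 500.0
        t = np.arange(0, 1.0, 1 / 360_000)  # dense carrier, many cycles
        q = np.maximum(np.sin(2 * np.pi * f * t), 0.0)
        vs = cs.vs_pulses(t, q, f)
        assert vs == pytest.approx(np.pi / 4, abs=1e-3)

    def test_hdcis_encoder_matches_oracle_at_500(self, hdcis500):
        vs = cs.vs_electrodogram(hdcis500, 500.0, "max_charge")
        assert vs == pytest.approx(np.pi / 4, abs=0.02)


def test_pulse_table_roundtrip(tmp_path, pdt500):
    p = tmp_path / "pulses.csv"
    write_pulse_table(pdt500, p)
    back = read_pulse_table(p)
    np.testing.assert_allclose(back.times_us, pdt500.times_us)
    np.testing.assert_array_equal(back.electrodes, pdt500.electrodes)
    np.testing.assert_allclose(back.amplitudes_ma, pdt500.amplitudes_ma)
    assert back.strategy == "pdt"
    assert back.params == pdt500.params
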