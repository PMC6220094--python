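import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasowave.analysis import (AnalysisError, kinase_rate, oscillation_metrics,
                               phospho_rate, phospho_steady, region_means,
                               simulate_phospho, temporal_average,
                               time_average_W, trace_period, wave_front_speed)
from vasowave.params import PhosphoParams
from vasowave.simulator import TimeSeriesRecord


def _record_from_traces(times, smc_traces, ec_traces=None):
    smc = np.zeros((len(times), 5, smc_traces.shape[1]))
    smc[:, 0, :] = smc_traces
    if ec_traces is None:
        ec_traces = np.zeros((len(times), 1))
    ec = np.zeros((len(times), 5, ec_traces.shape[1]))
    ec[:, 0, :] = ec_traces
    return TimeSeriesRecord(times=np.asarray(times, float), ec=ec, smc=smc)


class TestTemporalAverage:
    def test_constant_trace(self):
        t = np.arange(0, 101.0)
        rec = _record_from_traces(t, np.full((101, 1), 0.7))
        avg = temporal_average(rec, 0.0, 100.0)
        assert avg.mean[0] == pytest.approx(0.7)

    def test_alternating_trace(self):
        t = np.arange(0, 101.0)
        x = (np.arange(101) % 2).astype(float).reshape(-1, 1)
        rec = _record_from_traces(t, x)
        # an odd sample count over an even window: inclusive endpoints
        avg = temporal_average(rec, 0.0, 99.0)
        assert avg.mean[0] == pytest.approx(0.5)

    def test_sinusoid_closed_form(self):
        """Integer number of 20 s periods averages to the offset."""
        t = np.arange(0, 501.0)
        x = (0.5 + 0.3 * np.sin(2 * np.pi * t / 20.0)).reshape(-1, 1)
        rec = _record_from_traces(t, x)
        avg = temporal_average(rec, 300.0, 500.0)
        assert avg.mean[0] == pytest.approx(0.5, abs=0.01)

    def test_mean_bounded_by_extremes(self, seam_run):
        _, rec = seam_run
        avg = temporal_average(rec, 300.0, 500.0, layer="smc")
        win = rec.smc[(rec.times >= 300) & (rec.times <= 500), 0, :]
        assert np.all(avg.mean >= win.min(axis=0) - 1e-12)
        assert np.all(avg.mean <= win.max(axis=0) + 1e-12)

    def test_bad_windows_rejected(self):
        t = np.arange(0, 11.0)
        rec = _record_from_traces(t, np.ones((11, 1)))
        with pytest.raises(AnalysisError):
            temporal_average(rec, 5.0, 5.0)
        with pytest.raises(AnalysisError):
            temporal_average(rec, 100.0, 200.0)


class TestKinase:
    def test_reference_points(self, params):
        p = params.phospho
        assert kinase_rate(0.0, p) == 0.0
        assert kinase_rate(p.K_a, p) == pytest.approx(p.V_MK / 2)
        assert kinase_rate(1e9, p) == pytest.approx(p.V_MK, rel=1e-6)

    def test_negative_ca_rejected(self, params):
        with pytest.raises(AnalysisError):
            kinase_rate(-0.1, params.phospho)


class TestPhosphoCycle:
    def test_absorbing_state_without_kinase(self, params):
        assert phospho_rate(0.0, 0.0, params.phospho) == 0.0

    def test_rate_signs_at_boundaries(self, params):
        p = params.phospho
        assert phospho_rate(0.0, 0.5 * p.v_p, p) > 0.0
        assert phospho_rate(1.0, 0.5 * p.v_p, p) < 0.0

    def test_out_of_range_rejected(self, params):
        with pytest.raises(AnalysisError):
            phospho_rate(1.5, 1.0, params.phospho)

    @pytest.mark.parametrize("vk_over_vp", [0.3, 0.8, 1.0, 1.3, 2.0])
    def test_steady_state_is_root(self, params, vk_over_vp):
        p = params.phospho
        w = phospho_steady(vk_over_vp * p.v_p, p)
        assert 0.0 <= w <= 1.0
        if 0.0 < w < 1.0:
            assert phospho_rate(w, vk_over_vp * p.v_p, p) == pytest.approx(
                0.0, abs=1e-8)

    def test_zero_order_switch_at_unity_ratio(self):
        """With K1 = K2 << 1 the steady state crosses 0.5 at v_k/v_p = 1 and
        switches sharply around it."""
        p = PhosphoParams(K_1=0.01, K_2=0.01)
        w_lo = phospho_steady(0.8 * p.v_p, p)
        w_mid = phospho_steady(1.0 * p.v_p, p)
        w_hi = phospho_steady(1.2 * p.v_p, p)
        assert w_mid == pytest.approx(0.5, abs=0.01)
        assert w_lo < 0.1
        assert w_hi > 0.9

    def test_zero_order_regime_is_ultrasensitive(self):
        """The switch is steeper at small K1, K2 than at K1 = K2 = 1."""
        ratios = np.linspace(0.5, 1.5, 41)

        def max_slope(p):
            w = np.array([phospho_steady(r * p.v_p, p) for r in ratios])
            return np.max(np.abs(np.gradient(w, ratios)))

        assert max_slope(PhosphoParams(K_1=0.01, K_2=0.01)) > \
            4 * max_slope(PhosphoParams(K_1=1.0, K_2=1.0))


class TestPhosphoTrajectory:
    def test_constant_drive_converges_to_steady_state(self, params):
        p = params.phospho
        t = np.arange(0, 101.0)
        ca = np.full_like(t, 0.4)
        W = simulate_phospho(ca, t, p, W0=0.0)
        assert W[-1] == pytest.approx(phospho_steady(kinase_rate(0.4, p), p),
                                      abs=0.01)

    def test_zero_drive_decays(self, params):
        t = np.arange(0, 51.0)
        W = simulate_phospho(np.zeros_like(t), t, params.phospho, W0=0.9)
        assert W[-1] < 0.01
        assert np.all(np.diff(W) <= 1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_invariant_region_under_bounded_drive(self, seed):
        """W* stays in [0, 1] for any non-negative bounded Ca2+ drive."""
        rng = np.random.default_rng(seed)
        t = np.arange(0, 60.0)
        ca = np.abs(rng.normal(0.4, 0.3, t.shape))
        W = simulate_phospho(ca, t, PhosphoParams(), W0=rng.uniform(0, 1))
        assert np.all(W >= 0.0)
        assert np.all(W <= 1.0)

    def test_time_average_examples(self, params):
        t = np.arange(0, 101.0)
        assert time_average_W(np.full_like(t, 0.3), t) == pytest.approx(0.3)
        square = (t % 20 < 10).astype(float)
        assert time_average_W(square, t, 0.0, 100.0) == pytest.approx(0.5, abs=0.06)

    def test_mean_W_monotone_in_spike_frequency(self, params):
        """Higher Ca2+ spike frequency yields a higher mean phosphorylated
        fraction, all else fixed — the frequency-encoding property."""
        p = params.phospho
        t = np.arange(0, 400.0, 0.25)
        means = []
        for period in (80.0, 40.0, 20.0, 10.0):
            spikes = ((t % period) < 4.0).astype(float)
            ca = 0.15 + 0.65 * spikes
            W = simulate_phospho(ca, t, p)
            means.append(time_average_W(W, t, 100.0, 400.0))
        assert means[0] < means[1] < means[2] < means[3]


class TestOscillationMetrics:
    def test_pure_sinusoid_period(self):
        t = np.arange(0, 201.0)
        x = (0.5 + 0.3 * np.sin(2 * np.pi * t / 20.0)).reshape(-1, 1)
        rec = _record_from_traces(t, x)
        wm = oscillation_metrics(rec)
        assert wm.oscillatory[0]
        assert wm.period[0] == pytest.approx(20.0, abs=0.5)
        assert wm.amplitude[0] == pytest.approx(0.57, abs=0.1)

    def test_flat_trace_flagged_non_oscillatory(self):
        t = np.arange(0, 101.0)
        rec = _record_from_traces(t, np.full((101, 1), 0.2))
        wm = oscillation_metrics(rec)
        assert not wm.oscillatory[0]
        assert np.isnan(wm.period[0])
        assert wm.amplitude[0] == 0.0

    def test_dominant_period_of_two_tone_signal(self):
        t = np.arange(0, 401.0)
        x = (0.5 + 0.3 * np.sin(2 * np.pi * t / 20.0)
             + 0.03 * np.sin(2 * np.pi * t / 7.0)).reshape(-1, 1)
        rec = _record_from_traces(t, x)
        wm = oscillation_metrics(rec)
        assert wm.period[0] == pytest.approx(20.0, abs=1.0)

    def test_autocorrelation_fallback(self):
        """A weak regular oscillation below peak prominence still gets a
        period from the autocorrelation."""
        t = np.arange(0, 201.0)
        x = 0.5 + 0.01 * np.sin(2 * np.pi * t / 25.0)
        per, _ = trace_period(t, x, prominence=0.05)
        assert per == pytest.approx(25.0, abs=1.0)


class TestWaveFrontSpeed:
    def _pulse_record(self, speed, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 120.0, 0.5)
        cells = np.arange(30)
        dist = cells * 0.1                       # mm spacing
        arrival = 20.0 + dist / speed
        x = 0.1 + 0.7 * (1.0 / (1.0 + np.exp(-(t[:, None] - arrival[None, :]) / 0.5)))
        x += noise * rng.standard_normal(x.shape)
        return _record_from_traces(t, x), cells, dist

    def test_recovers_known_speed(self):
        rec, cells, dist = self._pulse_record(speed=0.02)
        out = wave_front_speed(rec, cells, distances=dist, threshold=0.45)
        assert out["flag"] == "ok"
        assert out["speed"] == pytest.approx(0.02, rel=0.05)

    def test_robust_to_noise(self):
        rec, cells, dist = self._pulse_record(speed=0.02, noise=0.07, seed=3)
        out = wave_front_speed(rec, cells, distances=dist, threshold=0.45)
        assert out["flag"] == "ok"
        assert out["speed"] == pytest.approx(0.02, rel=0.10)

    def test_standing_oscillation_flagged(self):
        t = np.arange(0, 100.0, 0.5)
        x = np.tile((0.4 + 0.4 * np.sin(2 * np.pi * t / 20.0))[:, None], (1, 10))
        rec = _record_from_traces(t, x)
        out = wave_front_speed(rec, np.arange(10), threshold=0.5)
        assert out["flag"] == "standing"
        assert np.isinf(out["speed"])

    def test_no_crossing_flagged(self):
        t = np.arange(0, 50.0)
        rec = _record_from_traces(t, np.full((50, 5), 0.1))
        out = wave_front_speed(rec, np.arange(5), threshold=0.9)
        assert out["flag"] == "no_crossing"


def test_region_means_by_label(seam_run):
    lat, rec = seam_run
    avg = temporal_average(rec, 300.0, 500.0, layer="smc")
    means = region_means(avg, lat.smc_region)
    assert "uniform" in means
    assert means["uniform"] > 0.0
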