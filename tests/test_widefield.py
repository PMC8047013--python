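import numpy as np
import pytest

from csdflow.io import TimeWindow, Trace, extract_roi_trace
from csdflow.synth import WidefieldScenario, simulate_widefield
from csdflow.widefield import (
    CSDEvent, band_rms_amplitude, compute_dff, detect_csd_events,
    half_max_times, inter_event_interval, peak_by_spline, recovery_curve,
    wave_speed,
)


def _trace(vals, rate=10.0, t0=-120.0, unit="dff"):
    return Trace(values=np.asarray(vals, dtype=float), rate_hz=rate, t0_s=t0, unit=unit)


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        out = compute_dff(_trace(np.full(2000, 5.0), unit="au"), 0.0)
        np.testing.assert_allclose(out.values, 0.0)
        assert out.unit == "dff"

    def test_tripling_baseline_gives_200_percent(self):
        vals = np.full(2000, 10.0)
        vals[1500] = 30.0
        out = compute_dff(_trace(vals, unit="au"), 0.0)
        assert out.values[1500] == pytest.approx(2.0)

    def test_matches_direct_recomputation(self, rng):
        vals = rng.uniform(50, 150, size=3000)
        t = _trace(vals, unit="au")
        out = compute_dff(t, 0.0)
        # oracle: mean over [-60, -20) is samples 600..1000 of a t0=-120 trace
        f0 = vals[600:1000].mean()
        np.testing.assert_allclose(out.values, (vals - f0) / f0)

    def test_insufficient_coverage_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(_trace(np.ones(100), t0=-5.0, unit="au"), 0.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="not positive"):
            compute_dff(_trace(np.zeros(2000), unit="au"), 0.0)


class TestDetectCsdEvents:
    def test_pure_noise_has_no_events(self, noise_trace, baseline_window):
        assert detect_csd_events(noise_trace, baseline_window) == []

    def test_ramp_onset_matches_closed_form(self, baseline_window):
        """A noiseless linear ramp crosses mean + 5 SD at an analytic time."""
        rate, t0 = 10.0, -120.0
        t = t0 + np.arange(4200) / rate
        # zero-mean baseline wiggle confined to t < 0, pure ramp afterwards
        base_noise = np.where(t < 0, 0.01 * np.sin(2 * np.pi * np.arange(4200) / 7.0), 0.0)
        ramp = np.where(t >= 30.0, (t - 30.0) * 0.05, 0.0)
        ramp = np.minimum(ramp, 2.0)
        ramp = np.where(t >= 120.0, np.maximum(2.0 - (t - 120.0) * 0.05, 0.0), ramp)
        tr = _trace(base_noise + ramp, rate=rate, t0=t0)
        base = tr.window_values(baseline_window)
        threshold = base.mean() + 5 * base.std()
        t_cross = 30.0 + threshold / 0.05
        events = detect_csd_events(tr, baseline_window)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(t_cross, abs=1.0 / rate)

    def test_two_planted_waves_detected_as_two_events(self):
        s = WidefieldScenario(duration_s=620.0, t0_s=-120.0, grid=32, field_mm=6.4,
                              origin_px=(4, 16), wave_onsets_s=(30.0, 310.0),
                              noise_sd_dff=0.01, suppression_recovery_s=300.0,
                              allow_truncation=True, seed=11)
        movie, _ = simulate_widefield(s)
        dff = compute_dff(extract_roi_trace(movie, (8, 13, 14, 19)), 0.0)
        events = detect_csd_events(dff, TimeWindow(-60, -20))
        assert len(events) == 2

    def test_zero_variance_baseline_rejected(self, baseline_window):
        with pytest.raises(ValueError, match="zero variance"):
            detect_csd_events(_trace(np.zeros(4200)), baseline_window)

    def test_event_fields_are_ordered(self):
        s = WidefieldScenario(duration_s=300.0, t0_s=-120.0, grid=32, field_mm=6.4,
                              origin_px=(4, 16), wave_onsets_s=(20.0,),
                              noise_sd_dff=0.01, allow_truncation=True, seed=2)
        movie, _ = simulate_widefield(s)
        dff = compute_dff(extract_roi_trace(movie, (8, 13, 14, 19)), 0.0)
        (e,) = detect_csd_events(dff, TimeWindow(-60, -20))
        assert e.onset_s <= e.arrival_s <= e.peak_s <= e.passage_s
        assert e.duration_s == pytest.approx(s.wave_duration_s, abs=0.5)


class TestPeakBySpline:
    def test_parabola_vertex_recovered(self):
        rate = 10.0
        t = np.arange(0, 40, 1 / rate)
        vertex_t, vertex_v = 20.037, 2.0
        vals = vertex_v - 0.05 * (t - vertex_t) ** 2
        tr = _trace(vals, rate=rate, t0=0.0)
        ev = CSDEvent(onset_s=15.0, peak_s=t[np.argmax(vals)], peak_dff=vals.max())
        peak_s, peak_v = peak_by_spline(tr, ev)
        assert peak_s == pytest.approx(vertex_t, abs=1e-6)
        assert peak_v == pytest.approx(vertex_v, abs=1e-6)

    def test_on_sample_symmetric_peak_unchanged(self):
        t = np.arange(0, 40, 0.1)
        vals = np.exp(-((t - 20.0) ** 2) / 4.0)     # peak exactly on a sample
        tr = _trace(vals, rate=10.0, t0=0.0)
        ev = CSDEvent(onset_s=18.0, peak_s=20.0, peak_dff=1.0)
        peak_s, peak_v = peak_by_spline(tr, ev)
        assert peak_s == pytest.approx(20.0, abs=1e-9)
        assert peak_v == pytest.approx(1.0, abs=1e-9)

    def test_never_below_discrete_maximum(self, rng):
        vals = rng.normal(size=400)
        vals[200] += 5.0
        tr = _trace(vals, rate=10.0, t0=0.0)
        ev = CSDEvent(onset_s=19.0, peak_s=20.0, peak_dff=vals[200])
        _, peak_v = peak_by_spline(tr, ev)
        assert peak_v >= vals[200]

    def test_truncated_window_falls_back_with_warning(self):
        vals = np.linspace(0, 1, 15)
        tr = _trace(vals, rate=10.0, t0=0.0)
        ev = CSDEvent(onset_s=1.0, peak_s=1.4, peak_dff=1.0)
        with pytest.warns(UserWarning, match="truncated"):
            peak_s, peak_v = peak_by_spline(tr, ev)
        assert peak_v == pytest.approx(1.0)

    def test_generator_wave_peak_recovered_within_1pct(self):
        s = WidefieldScenario(duration_s=300.0, t0_s=-120.0, grid=32, field_mm=6.4,
                              origin_px=(4, 16), wave_onsets_s=(20.0,),
                              noise_sd_dff=0.0, slowwave_rms_dff=0.005,
                              allow_truncation=True)
        movie, _ = simulate_widefield(s)
        dff = compute_dff(extract_roi_trace(movie, (10, 11, 16, 17)), 0.0)
        (e,) = detect_csd_events(dff, TimeWindow(-60, -20))
        assert e.peak_dff == pytest.approx(s.wave_peak_dff, rel=0.01)


class TestHalfMaxTimes:
    def test_triangle_geometry(self):
        """Symmetric triangle of base width W: half-max at peak -/+ W/4."""
        rate = 100.0
        t = np.arange(0, 60, 1 / rate)
        p, W, A = 30.0, 20.0, 2.0
        vals = np.maximum(0.0, A * (1 - np.abs(t - p) / (W / 2)))
        tr = _trace(vals, rate=rate, t0=0.0)
        ev = CSDEvent(onset_s=25.0, peak_s=p, peak_dff=A)
        arrival, passage = half_max_times(tr, ev)
        assert arrival == pytest.approx(p - W / 4, abs=1e-9)
        assert passage == pytest.approx(p + W / 4, abs=1e-9)

    def test_crossings_match_dense_grid_oracle(self, rng):
        rate = 10.0
        t = np.arange(0, 80, 1 / rate)
        center = 40.0 + rng.uniform(-0.05, 0.05)
        width = 8.0
        vals = 1.7 * np.exp(-((t - center) ** 2) / (2 * width ** 2))
        tr = _trace(vals, rate=rate, t0=0.0)
        ev = CSDEvent(onset_s=30.0, peak_s=center, peak_dff=vals.max())
        arrival, passage = half_max_times(tr, ev)
        td = np.arange(0, 80, 1e-4)
        vd = 1.7 * np.exp(-((td - center) ** 2) / (2 * width ** 2))
        half = vals.max() / 2
        oracle_up = td[np.argmax(vd >= half)]
        oracle_down = td[len(vd) - 1 - np.argmax(vd[::-1] >= half)]
        assert arrival == pytest.approx(oracle_up, abs=1 / rate)
        assert passage == pytest.approx(oracle_down, abs=1 / rate)

    def test_unsubsided_passage_flagged(self):
        vals = np.concatenate([np.zeros(50), np.linspace(0, 2, 150)])
        tr = _trace(vals, rate=10.0, t0=0.0)
        ev = CSDEvent(onset_s=10.0, peak_s=19.9, peak_dff=2.0)
        with pytest.warns(UserWarning, match="passage undefined"):
            _, passage = half_max_times(tr, ev)
        assert np.isnan(passage)

    def test_generator_duration_recovered(self):
        s = WidefieldScenario(duration_s=300.0, t0_s=-120.0, grid=32, field_mm=6.4,
                              origin_px=(4, 16), wave_onsets_s=(20.0,),
                              wave_duration_s=50.0, noise_sd_dff=0.0,
                              slowwave_rms_dff=0.005, allow_truncation=True)
        movie, _ = simulate_widefield(s)
        dff = compute_dff(extract_roi_trace(movie, (10, 11, 16, 17)), 0.0)
        (e,) = detect_csd_events(dff, TimeWindow(-60, -20))
        assert e.duration_s == pytest.approx(50.0, abs=0.1)


class TestWaveSpeed:
    def test_reported_transit_examples(self):
        near = [CSDEvent(onset_s=0, peak_s=0, peak_dff=2, arrival_s=10.0)]
        far_44 = [CSDEvent(onset_s=0, peak_s=0, peak_dff=2, arrival_s=10.0 + 2.0 / 4.4 * 60)]
        far_20 = [CSDEvent(onset_s=0, peak_s=0, peak_dff=2, arrival_s=70.0)]
        assert wave_speed(near, far_44)[0] == pytest.approx(4.4)
        assert wave_speed(near, far_20)[0] == pytest.approx(2.0)

    def test_nonpositive_transit_flagged_not_dropped(self):
        near = [CSDEvent(onset_s=0, peak_s=0, peak_dff=2, arrival_s=20.0)]
        far = [CSDEvent(onset_s=0, peak_s=0, peak_dff=2, arrival_s=15.0)]
        with pytest.warns(UserWarning, match="non-positive transit"):
            out = wave_speed(near, far)
        assert len(out) == 1 and np.isnan(out[0])

    def test_unmatched_waves_warn(self):
        e = CSDEvent(onset_s=0, peak_s=0, peak_dff=2, arrival_s=10.0)
        f = CSDEvent(onset_s=0, peak_s=0, peak_dff=2, arrival_s=40.0)
        with pytest.warns(UserWarning, match="unmatched"):
            out = wave_speed([e, e], [f])
        assert len(out) == 1

    def test_speed_invariant_to_intensity_scaling(self):
        """dF/F and half-max timing are scale-free, so speed must be too."""
        s = WidefieldScenario(duration_s=420.0, t0_s=-120.0, kcl_window=TimeWindow(0, 120),
                              wave_onsets_s=(30.0,), speed_mm_per_min=4.4,
                              geometry="planar", origin_px=(8, 32),
                              noise_sd_dff=0.0, allow_truncation=True)
        movie, _ = simulate_widefield(s)
        speeds = []
        for gain in (1.0, 37.5):
            movie.data = movie.data * gain if gain != 1.0 else movie.data
            evs = {}
            for name, r in (("near", 11), ("far", 21)):
                dff = compute_dff(extract_roi_trace(movie, (r - 1, r + 2, 30, 35)), 0.0)
                evs[name] = detect_csd_events(dff, TimeWindow(-60, -20))
            speeds.append(wave_speed(evs["near"], evs["far"],
                                     separation_mm=10 * s.pixel_pitch_mm)[0])
        # float32 storage rounds the scaled intensities; timing agrees to ~1e-7
        assert speeds[0] == pytest.approx(speeds[1], rel=1e-5)


class TestIntervalsAndAmplitude:
    def test_interval_is_onset_difference(self):
        evs = [CSDEvent(onset_s=38.3, peak_s=0, peak_dff=2),
               CSDEvent(onset_s=38.3 + 281.1, peak_s=0, peak_dff=2)]
        assert inter_event_interval(evs) == pytest.approx([281.1])

    def test_single_event_empty(self):
        assert inter_event_interval([CSDEvent(onset_s=1, peak_s=2, peak_dff=2)]) == []

    def test_k_sorted_onsets_match_diff_oracle(self, rng):
        onsets = np.sort(rng.uniform(0, 1000, size=7))
        evs = [CSDEvent(onset_s=o, peak_s=o, peak_dff=2) for o in onsets]
        np.testing.assert_allclose(inter_event_interval(evs), np.diff(onsets))

    def test_inband_sinusoid_rms(self):
        t = np.arange(0, 600, 0.1)
        A = 0.05
        tr = _trace(A * np.sin(2 * np.pi * 1.0 * t), rate=10.0, t0=0.0)
        out = band_rms_amplitude(tr)
        assert len(out.values) == 2
        np.testing.assert_allclose(out.values, A / np.sqrt(2), rtol=0.02)
        np.testing.assert_allclose(out.times_s, [150.0, 450.0])

    def test_dc_is_rejected_by_the_band(self):
        tr = _trace(np.full(6000, 0.5), rate=10.0, t0=0.0)
        out = band_rms_amplitude(tr)
        assert np.all(out.values < 0.005)

    def test_windowed_rms_equals_direct_recomputation(self, rng):
        from scipy import signal as sg
        vals = rng.normal(0, 0.02, size=6000)
        tr = _trace(vals, rate=10.0, t0=0.0)
        out = band_rms_amplitude(tr)
        sos = sg.butter(2, (0.1, 3.0), btype="bandpass", fs=10.0, output="sos")
        filt = sg.sosfiltfilt(sos, vals)
        for w in range(2):
            seg = filt[w * 3000:(w + 1) * 3000]
            assert out.values[w] == pytest.approx(np.sqrt(np.mean(seg ** 2)), abs=1e-15)

    def test_monotone_in_gain(self, rng):
        vals = rng.normal(0, 0.02, size=6000)
        out1 = band_rms_amplitude(_trace(vals, rate=10.0, t0=0.0))
        out3 = band_rms_amplitude(_trace(3.0 * vals, rate=10.0, t0=0.0))
        np.testing.assert_allclose(out3.values, 3.0 * out1.values, rtol=1e-12)

    def test_rate_too_low_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            band_rms_amplitude(_trace(np.zeros(3000), rate=5.0, t0=0.0))


class TestRecoveryCurve:
    def test_constant_amplitude_is_unity(self):
        amp = Trace(values=np.full(10, 0.03), rate_hz=1 / 300.0, t0_s=-450.0, unit="dff")
        curve = recovery_curve(amp, TimeWindow(0.0, 600.0))
        np.testing.assert_allclose(curve.relative_amplitude, 1.0)

    def test_exponential_recovery_halves_at_tau_ln2(self):
        tau = 900.0
        centers = -450.0 + 300.0 * np.arange(16)
        rel = np.where(centers < 600, 1.0, 1.0 - np.exp(-(centers - 600.0) / tau))
        rel[(centers >= 0) & (centers < 600)] = 0.05
        amp = Trace(values=0.03 * rel, rate_hz=1 / 300.0, t0_s=-450.0, unit="dff")
        curve = recovery_curve(amp, TimeWindow(0.0, 600.0))
        t_half = 600.0 + tau * np.log(2.0)
        assert curve.at(t_half) == pytest.approx(0.5, abs=0.1)
        post = curve.window_centers_s >= 600.0
        fit = np.polyfit(curve.window_centers_s[post] - 600.0,
                         np.log(1.0 - np.minimum(curve.relative_amplitude[post], 0.999)), 1)
        assert -1.0 / fit[0] == pytest.approx(tau, rel=0.10)

    def test_full_recovery_plateaus_at_unity(self):
        centers = -450.0 + 300.0 * np.arange(20)
        rel = np.where(centers < 0, 1.0, np.where(centers < 2400, 0.3, 1.0))
        amp = Trace(values=0.03 * rel, rate_hz=1 / 300.0, t0_s=-450.0, unit="dff")
        curve = recovery_curve(amp, TimeWindow(0.0, 600.0))
        assert curve.relative_amplitude[-1] == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        amp = Trace(values=np.ones(5), rate_hz=1 / 300.0, t0_s=900.0, unit="dff")
        with pytest.raises(ValueError, match="reference"):
            recovery_curve(amp, TimeWindow(0.0, 600.0))
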