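"""Saccade detector: analytic speed profiles, metrics, normalized profiles."""
import numpy as np
import pytest

from scvigor.errors import DataFormatError, ScvigorError
from scvigor.kinematics import (EyeTrace, SaccadeEvent, detect_saccades,
                                normalize_profile, saccade_metrics,
                                trial_saccade)
from scvigor.synth import minimum_jerk

from conftest import make_session


def gaussian_speed_trace(peak=400.0, center=150.0, sd=15.0, total=600):
    """Trace whose radial speed is a Gaussian bump along +x."""
    t = np.arange(total, dtype=float)
    speed = peak * np.exp(-0.5 * ((t - center) / sd) ** 2)  # deg/s
    x = np.cumsum(speed) / 1000.0
    return EyeTrace(t, x, np.zeros(total))


def minjerk_trace(amp=10.0, pv=500.0, onset=200, total=700):
    dur = 1.875 * amp / pv * 1000.0
    t = np.arange(total, dtype=float)
    x = minimum_jerk(amp, dur, t - onset)
    return EyeTrace(t, x, np.zeros(total)), dur


class TestDetection:
    def test_stationary_trace_yields_no_events(self):
        t = np.arange(1000.0)
        assert detect_saccades(EyeTrace(t, np.zeros(1000), np.zeros(1000))) == []

    def test_gaussian_profile_analytic_onset_offset_and_peak(self):
        """Speed 400*exp(-(t-150)^2 / (2*15^2)): the 30 deg/s crossings are at
        150 -/+ 15*sqrt(2 ln(400/30)) = 115.9 / 184.1 ms; peak 400 deg/s."""
        trace = gaussian_speed_trace()
        events = detect_saccades(trace)
        assert len(events) == 1
        ev = events[0]
        half = 15.0 * np.sqrt(2.0 * np.log(400.0 / 30.0))
        assert ev.onset_ms == pytest.approx(150.0 - half, abs=1.0)
        assert ev.offset_ms == pytest.approx(150.0 + half, abs=1.0)
        assert ev.pv_deg_s == pytest.approx(400.0, rel=0.01)
        assert ev.valid

    def test_blink_speed_flags_event_invalid(self):
        events = detect_saccades(gaussian_speed_trace(peak=900.0))
        assert len(events) == 1
        assert not events[0].valid
        assert events[0].reject_reason == "blink"

    def test_time_translation_invariance(self):
        on1 = detect_saccades(gaussian_speed_trace(center=150.0))[0].onset_ms
        on2 = detect_saccades(gaussian_speed_trace(center=350.0))[0].onset_ms
        assert on2 - on1 == pytest.approx(200.0, abs=1.0)

    @pytest.mark.parametrize("angle_deg", [0, 30, 117, 245])
    def test_rotation_invariance_in_xy(self, angle_deg):
        trace = gaussian_speed_trace()
        a = np.deg2rad(angle_deg)
        rot = EyeTrace(trace.t, trace.x * np.cos(a), trace.x * np.sin(a))
        ev0 = detect_saccades(trace)[0]
        ev1 = detect_saccades(rot)[0]
        assert ev1.onset_ms == ev0.onset_ms
        assert ev1.pv_deg_s == pytest.approx(ev0.pv_deg_s, rel=1e-9)

    def test_short_trace_rejected(self):
        t = np.arange(30.0)
        with pytest.raises(DataFormatError):
            detect_saccades(EyeTrace(t, np.zeros(30), np.zeros(30)))

    def test_nonuniform_sampling_rejected(self):
        t = np.concatenate([np.arange(50.0), np.arange(51.0, 101.0)])
        with pytest.raises(DataFormatError):
            EyeTrace(t, np.zeros(t.size), np.zeros(t.size))


class TestMetrics:
    def test_rt_is_onset_minus_target_on(self):
        trace = gaussian_speed_trace()
        ev = detect_saccades(trace)[0]
        done = saccade_metrics(ev, trace, target_on=50.0,
                               target_pos=(trace.x[-1], 0.0))
        assert done.rt_ms == pytest.approx(ev.onset_ms - 50.0)

    def test_amplitude_is_euclidean_displacement(self):
        trace, _ = minjerk_trace(amp=10.0)
        ev = detect_saccades(trace)[0]
        done = saccade_metrics(ev, trace, 100.0, (10.0, 0.0))
        assert done.amplitude_deg == pytest.approx(10.0, rel=0.02)

    def test_landing_beyond_8_degrees_rejected(self):
        trace, _ = minjerk_trace(amp=10.0)
        ev = detect_saccades(trace)[0]
        done = saccade_metrics(ev, trace, 100.0, (19.5, 0.0))
        assert not done.valid
        assert done.reject_reason == "off_target"

    def test_target_after_offset_rejected(self):
        trace = gaussian_speed_trace()
        ev = detect_saccades(trace)[0]
        with pytest.raises(ScvigorError):
            saccade_metrics(ev, trace, target_on=500.0, target_pos=(0.0, 0.0))

    def test_trial_saccade_selection_window(self):
        trace = gaussian_speed_trace(center=150.0)
        events = detect_saccades(trace)
        # RT ~ 116 - target_on; inside [50, 600] only for suitable targets
        assert trial_saccade(events, target_on=20.0) is not None
        assert trial_saccade(events, target_on=110.0) is None  # anticipatory


class TestNormalizedProfile:
    def test_linear_displacement_gives_linear_profile(self):
        t = np.arange(400.0)
        x = np.clip((t - 100.0) * 0.1, 0.0, 10.0)  # 0 -> 10 deg over 100 ms
        trace = EyeTrace(t, x, np.zeros(400))
        ev = SaccadeEvent(onset_ms=100.0, offset_ms=200.0, pv_deg_s=100.0)
        prof = normalize_profile(trace, ev)
        assert prof.grid.size == 20
        assert prof.displacement[9] == pytest.approx(5.0, rel=0.01)   # 50%
        assert prof.velocity[9] == pytest.approx(10.0 / 100.0 * 1000, rel=0.02)

    def test_always_exactly_20_points(self):
        trace, _ = minjerk_trace()
        ev = detect_saccades(trace)[0]
        prof = normalize_profile(trace, ev)
        assert prof.grid.size == prof.displacement.size == prof.velocity.size == 20

    def test_minjerk_normalized_velocity_peak_matches_pv(self):
        """The normalized-profile velocity maximum reproduces the trace PV."""
        trace, _ = minjerk_trace(amp=12.0, pv=550.0)
        ev = detect_saccades(trace)[0]
        prof = normalize_profile(trace, ev)
        assert prof.velocity.max() == pytest.approx(ev.pv_deg_s, rel=0.01)

    def test_displacement_monotone_for_outward_saccade(self):
        trace, _ = minjerk_trace()
        ev = detect_saccades(trace)[0]
        prof = normalize_profile(trace, ev)
        assert np.all(np.diff(prof.displacement) >= -1e-6)

    def test_too_short_saccade_rejected(self):
        trace = gaussian_speed_trace()
        ev = SaccadeEvent(onset_ms=100.0, offset_ms=105.0, pv_deg_s=100.0)
        with pytest.raises(ScvigorError):
            normalize_profile(trace, ev)


class TestRoundTrip:
    def test_generated_sessions_recover_rt_and_pv(self):
        """On default-noise synthetic sessions the detector recovers the drawn
        RT within 2 ms and PV within 1% for >= 99% of trials."""
        from scvigor import session as sess
        rt_err, pv_err = [], []
        for seed in (301, 302, 303):
            b = make_session(seed, n_units=1)
            sacc = sess.analyze_saccades(b)
            ok = sacc["valid"].to_numpy()
            rt_true = np.array(b.truth["rt_ms"])
            pv_true = np.array(b.truth["pv_deg_s"])
            rt_err += list(np.abs(sacc["rt_ms"].to_numpy()[ok] - rt_true[ok]))
            pv_err += list(np.abs(sacc["pv_deg_s"].to_numpy()[ok] - pv_true[ok])
                           / pv_true[ok])
        assert np.mean(np.array(rt_err) <= 2.0) >= 0.99
        assert np.mean(np.array(pv_err) <= 0.01) >= 0.99
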