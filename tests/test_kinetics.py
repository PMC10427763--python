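"""Twitch dissection, frequency, velocity and fatigue analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twitchkit import kinetics as kin
from twitchkit import synthetic as syn
from twitchkit.piv import DisplacementTrace


def exhaustive_extrema(y):
    """Oracle: scan every sample for strict local extrema (incl. endpoints)."""
    mins, maxs = [], []
    n = len(y)
    for i in range(n):
        left = y[i - 1] if i > 0 else None
        right = y[i + 1] if i < n - 1 else None
        lo = all(v is None or y[i] < v for v in (left, right))
        hi = all(v is None or y[i] > v for v in (left, right))
        if lo:
            mins.append(i)
        elif hi:
            maxs.append(i)
    return mins, maxs


def make_trace(y, dt=0.02):
    y = np.asarray(y, float)
    return DisplacementTrace(
        times=np.arange(len(y)) * dt,
        displacement=y,
        velocity=np.abs(np.diff(y)) / dt,
    )


class TestDetectExtrema:
    def test_flat_trace_no_extrema(self):
        mins, maxs = kin.detect_extrema(make_trace(np.zeros(50)))
        assert len(mins) == 0 and len(maxs) == 0

    def test_rectified_sine_matches_exhaustive_scan(self):
        spec = syn.WaveformSpec(kind="sine", frequency=5.0, amplitude=1.0,
                                duration=2.0, sample_interval=0.02)
        trace, _ = syn.generate_trace(spec, seed=0)
        mins, maxs = kin.detect_extrema(trace)
        o_mins, o_maxs = exhaustive_extrema(trace.displacement)
        assert len(maxs) == 10
        assert list(maxs) == o_maxs
        assert set(mins) <= set(o_mins) | {0, len(trace.displacement) - 1}
        # alternation
        merged = sorted([(i, "m") for i in mins] + [(i, "M") for i in maxs])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_single_triangular_pulse(self):
        y = np.concatenate([np.zeros(10), np.linspace(0, 1, 11),
                            np.linspace(1, 0, 11)[1:], np.zeros(10)])
        mins, maxs = kin.detect_extrema(make_trace(y))
        assert len(maxs) == 1
        assert y[maxs[0]] == 1.0
        assert len(mins) == 2

    def test_nonfinite_rejected(self):
        y = np.zeros(20)
        y[3] = np.nan
        with pytest.raises(ValueError):
            kin.detect_extrema(make_trace(y))


class TestDissectTwitches:
    def test_asymmetric_twitch_phase_times(self):
        spec = syn.WaveformSpec(kind="asymmetric_twitch", frequency=2.0,
                                amplitude=1.0, acceleration_fraction=0.3,
                                duration=2.0, sample_interval=0.02)
        trace, truth = syn.generate_trace(spec, seed=0)
        events = kin.dissect_twitches(trace)
        assert len(events) >= 3
        for e in events:
            assert abs(e.acceleration_time - 0.15) <= 0.02 + 1e-12
            assert abs(e.relaxation_time - 0.35) <= 0.02 + 1e-12

    def test_symmetric_sine_equal_phases(self):
        spec = syn.WaveformSpec(kind="sine", frequency=5.0, amplitude=1.0,
                                duration=2.0, sample_interval=0.02)
        trace, _ = syn.generate_trace(spec, seed=0)
        for e in kin.dissect_twitches(trace):
            assert abs(e.acceleration_time - e.relaxation_time) <= 0.02 + 1e-12

    def test_truncated_final_rise_yields_no_event(self):
        y = np.concatenate([np.zeros(5), np.linspace(0, 1, 11),
                            np.linspace(1, 0, 11)[1:], np.linspace(0, 0.8, 9)])
        events = kin.dissect_twitches(make_trace(y))
        assert len(events) == 1  # the complete pulse only

    def test_no_extrema_empty(self):
        assert kin.dissect_twitches(make_trace(np.zeros(30))) == []

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 100.0), shift_samples=st.integers(0, 40))
    def test_scale_equivariance_and_shift_invariance(self, scale, shift_samples):
        """Amplitudes scale with the trace; times survive a flat prefix."""
        spec = syn.WaveformSpec(kind="asymmetric_twitch", frequency=2.0,
                                amplitude=1.0, acceleration_fraction=0.3,
                                duration=2.0, sample_interval=0.02)
        trace, _ = syn.generate_trace(spec, seed=1)
        base = kin.dissect_twitches(trace)
        scaled = kin.dissect_twitches(make_trace(trace.displacement * scale))
        assert len(scaled) == len(base)
        for a, b in zip(base, scaled):
            assert np.isclose(b.amplitude, a.amplitude * scale)
            assert b.acceleration_time == a.acceleration_time
            assert b.relaxation_time == a.relaxation_time
        padded = np.concatenate([np.zeros(shift_samples), trace.displacement])
        shifted = kin.dissect_twitches(make_trace(padded))
        assert len(shifted) >= len(base)
        match = shifted[-len(base):] if base else []
        for a, b in zip(base, match):
            assert b.acceleration_time == a.acceleration_time
            assert b.relaxation_time == a.relaxation_time


class TestDominantFrequency:
    def test_pure_sine_within_padded_bin(self):
        t = np.arange(100) * 0.02
        y = np.sin(2 * np.pi * 5.0 * t)
        assert abs(kin.dominant_frequency(y, dt=0.02) - 5.0) <= 0.125

    def test_flat_trace_zero(self):
        assert kin.dominant_frequency(np.zeros(100), dt=0.02) == 0.0

    def test_noisy_asymmetric_twitch(self):
        spec = syn.WaveformSpec(kind="asymmetric_twitch", frequency=2.0,
                                amplitude=1.0, acceleration_fraction=0.3,
                                noise_sd=0.1, duration=2.0, sample_interval=0.02)
        trace, _ = syn.generate_trace(spec, seed=3)
        assert abs(kin.dominant_frequency(trace) - 2.0) <= 0.125

    def test_nonuniform_sampling_rejected(self):
        tr = DisplacementTrace(
            times=np.array([0.0, 0.02, 0.05, 0.06, 0.1, 0.12, 0.2, 0.22, 0.3]),
            displacement=np.zeros(9),
            velocity=np.zeros(8),
        )
        with pytest.raises(ValueError, match="uniform"):
            kin.dominant_frequency(tr)


class TestContractionVelocity:
    def test_flat_zero(self):
        assert kin.contraction_velocity(np.zeros(200), dt=0.02) == 0.0

    def test_constant_ramp_exact(self):
        t = np.arange(150) * 0.02
        assert np.isclose(kin.contraction_velocity(t * 1.0, dt=0.02), 1.0)

    def test_short_trace_suggests_shorter_window(self):
        with pytest.raises(ValueError, match="shorter window"):
            kin.contraction_velocity(np.zeros(20), window=2.0, dt=0.02)

    def test_end_to_end_matches_analytic_mean_speed(self, sine_movie_trace):
        """PIV-tracked sine: mean speed approaches the rectified-wave value 2·A·f."""
        spec, scene, trace, _ = sine_movie_trace
        analytic = 2.0 * spec.amplitude * spec.frequency
        measured = kin.contraction_velocity(trace, window=1.9)
        assert abs(measured - analytic) / analytic < 0.1


class TestFatigueTime:
    FIXTURE = dict(kind="fatigue_decay", frequency=10.0, amplitude=0.2,
                   decay_time=5.0, noise_sd=0.01, duration=25.0,
                   sample_interval=0.02, onset=2.0)

    @staticmethod
    def analytic_crossing(spec, sustain=1.0, factor=2.0):
        """Envelope crossing of the sustain-window RMS velocity vs threshold."""
        from scipy.optimize import brentq

        base = math.sqrt(2) * spec.noise_sd / spec.sample_interval
        thr = factor * base
        sig0 = math.pi * spec.amplitude * spec.frequency / math.sqrt(2)
        tau = spec.decay_time

        def win_rms(t):
            m = (sig0**2 * math.exp(-2 * t / tau)
                 * tau * (1 - math.exp(-2 * sustain / tau)) / (2 * sustain))
            return math.sqrt(m + base**2)

        return brentq(lambda t: win_rms(t) - thr, 0.0, spec.duration)

    def test_decay_crossing_recovered(self):
        spec = syn.WaveformSpec(**self.FIXTURE)
        t_star = self.analytic_crossing(spec)
        errs = []
        for seed in range(20):
            trace, _ = syn.generate_trace(spec, seed)
            ft = kin.fatigue_time(trace, baseline_window=2.0)
            assert ft is not None
            errs.append(abs(ft - t_star) / t_star)
        assert np.median(errs) < 0.15

    def test_non_decaying_sine_never_fatigues(self):
        spec = syn.WaveformSpec(kind="sine", frequency=5.0, amplitude=1.0,
                                noise_sd=0.01, duration=10.0,
                                sample_interval=0.02, onset=2.0)
        trace, _ = syn.generate_trace(spec, seed=0)
        assert kin.fatigue_time(trace, baseline_window=2.0) is None

    def test_zero_amplitude_fatigue_time_zero(self):
        spec = syn.WaveformSpec(kind="flat", amplitude=0.0, duration=10.0,
                                sample_interval=0.02)
        trace, _ = syn.generate_trace(spec, seed=0)
        assert kin.fatigue_time(trace, baseline_window=2.0) == 0.0

    def test_missing_baseline_rejected(self):
        spec = syn.WaveformSpec(**self.FIXTURE)
        trace, _ = syn.generate_trace(spec, 0)
        with pytest.raises(ValueError, match="baseline"):
            kin.fatigue_time(trace, baseline_window=30.0)


class TestSummarize:
    def test_summary_consistency(self, sine_movie_trace):
        spec, scene, trace, _ = sine_movie_trace
        s = kin.summarize(trace, window=1.9)
        assert abs(s.dominant_frequency - 5.0) <= 0.125
        assert np.isclose(s.period, 1.0 / s.dominant_frequency)
        assert s.n_twitches >= 9
        assert s.fatigue_time is None

    def test_parameter_recovery_over_seeds(self):
        """Median phase-time error over 100 seeded noisy traces is within one
        sample interval, and the frequency is exact to the padded FFT bin."""
        spec = syn.WaveformSpec(kind="asymmetric_twitch", frequency=5.0,
                                amplitude=1.0, acceleration_fraction=0.3,
                                noise_sd=0.1, duration=2.0, sample_interval=0.02)
        acc_err, rel_err = [], []
        for seed in range(100):
            trace, truth = syn.generate_trace(spec, seed)
            assert abs(kin.dominant_frequency(trace) - 5.0) <= 0.125
            for e in kin.dissect_twitches(trace):
                acc_err.append(abs(e.acceleration_time - 0.06))
                rel_err.append(abs(e.relaxation_time - 0.14))
        assert np.median(acc_err) <= 0.02 + 1e-12
        assert np.median(rel_err) <= 0.02 + 1e-12
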