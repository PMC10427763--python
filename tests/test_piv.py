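"""PIV engine: shift theorem, subpixel accuracy, validation, tracking."""

import numpy as np
import pytest
from scipy.ndimage import fourier_shift

from twitchkit import piv
from twitchkit import synthetic as syn


def subpixel_shift(img, dx):
    """Periodic-exact subpixel shift along x (Fourier phase ramp)."""
    return np.fft.ifftn(fourier_shift(np.fft.fftn(img), (0.0, dx))).real


def brute_force_u(frame_a, frame_b, x0, y0, win, max_lag=8):
    """Independent oracle: direct spatial cross-correlation over integer x-lags
    of one zero-mean window pair, with a 3-point parabolic subpixel fit."""
    wa = frame_a[y0 : y0 + win, x0 : x0 + win].astype(float)
    wa = wa - wa.mean()
    scores = []
    lags = np.arange(-max_lag, max_lag + 1)
    for lag in lags:
        wb = np.roll(frame_b, -lag, axis=1)[y0 : y0 + win, x0 : x0 + win].astype(float)
        scores.append(np.sum(wa * (wb - wb.mean())))
    scores = np.array(scores)
    k = int(np.argmax(scores))
    if 0 < k < len(scores) - 1:
        cm, cc, cp = scores[k - 1 : k + 2]
        denom = cm - 2 * cc + cp
        frac = 0.5 * (cm - cp) / denom if denom != 0 else 0.0
    else:
        frac = 0.0
    return lags[k] + frac


class TestCorrelatePair:
    def test_identical_frames_exact_zero(self, speckle_frame):
        vf = piv.correlate_pair(speckle_frame, speckle_frame)
        assert np.abs(vf.u).max() < 1e-12
        assert np.abs(vf.v).max() < 1e-12
        assert vf.valid.all()

    @pytest.mark.parametrize("shift", [1, 3, 8])
    def test_integer_shift_theorem(self, speckle_frame, shift):
        b = np.roll(speckle_frame, shift, axis=1)
        vf = piv.correlate_pair(speckle_frame, b)
        inner_u = vf.u[1:-1, 1:-1]
        inner_v = vf.v[1:-1, 1:-1]
        assert abs(inner_u.mean() - shift) < 0.05
        assert abs(inner_v.mean()) < 0.05

    def test_subpixel_shift_and_oracle(self, speckle_frame):
        b = subpixel_shift(speckle_frame, 2.5)
        vf = piv.correlate_pair(speckle_frame, b)
        inner_u = vf.u[1:-1, 1:-1]
        assert np.abs(inner_u - 2.5).max() < 0.1
        # dual route: single-pass engine vs brute-force spatial correlation
        cfg = piv.PivConfig(pass_windows=(64,))
        vf1 = piv.correlate_pair(speckle_frame, b, cfg)
        for iy, y0 in enumerate([64]):
            for ix, x0 in enumerate([0, 64]):
                oracle = brute_force_u(speckle_frame, b, x0, y0, 64)
                gy = int(np.argmin(np.abs(vf1.y - (y0 + 31.5))))
                gx = int(np.argmin(np.abs(vf1.x - (x0 + 31.5))))
                assert abs(vf1.u[gy, gx] - oracle) < 0.1

    def test_antisymmetry(self, speckle_frame):
        b = subpixel_shift(speckle_frame, 1.5)
        fwd = piv.correlate_pair(speckle_frame, b)
        bwd = piv.correlate_pair(b, speckle_frame)
        diff = fwd.u[1:-1, 1:-1] + bwd.u[1:-1, 1:-1]
        assert np.abs(diff).max() < 0.1

    def test_constant_window_flagged_invalid(self):
        rng = np.random.default_rng(0)
        a = syn.speckle((64, 128), rng) * 100
        a[:, 64:] = 5.0  # right window has zero correlation energy
        vf = piv.correlate_pair(a, a.copy(), piv.PivConfig(pass_windows=(64,)))
        assert not vf.valid[0, 2]  # the window fully inside the flat region
        assert vf.replaced[0, 2]

    def test_frame_smaller_than_window_errors(self):
        small = np.zeros((32, 32))
        with pytest.raises(ValueError, match="window"):
            piv.correlate_pair(small, small)

    def test_outlier_vector_replaced_by_neighbours(self, speckle_frame):
        # corrupt one interrogation window of frame_b so its vector disagrees
        # with the surrounding field and must be interpolated from neighbours
        b = np.roll(speckle_frame, 2, axis=1)
        rng = np.random.default_rng(1)
        b[80:112, 80:112] = rng.uniform(0, 100, (32, 32))
        vf = piv.correlate_pair(speckle_frame, b)
        assert vf.replaced.any()
        assert np.abs(vf.u[1:-1, 1:-1] - 2.0).max() < 0.5


class TestMovieToFields:
    def test_static_movie_all_zero_fields(self):
        rng = np.random.default_rng(2)
        frame = syn.speckle((96, 96), rng) * 100
        stack = piv.MovieStack(np.repeat(frame[None], 100, axis=0), 0.5, 0.02)
        fields = piv.movie_to_fields(stack)
        assert len(fields) == 99
        assert all(np.abs(f.u).max() < 1e-9 for f in fields)

    def test_two_frame_movie_single_field(self):
        rng = np.random.default_rng(3)
        frame = syn.speckle((96, 96), rng) * 100
        stack = piv.MovieStack(np.stack([frame, frame]), 0.5, 0.02)
        assert len(piv.movie_to_fields(stack)) == 1

    def test_pairwise_increments_match_waveform(self):
        spec = syn.WaveformSpec(kind="sine", frequency=5.0, amplitude=1.0,
                                duration=0.6, sample_interval=0.02)
        scene = syn.make_tube_scene(noise_sd=0.0)
        stack, _ = syn.generate_movie(spec, scene, seed=4)
        fields = piv.movie_to_fields(stack)
        increments = np.diff(spec.clean_values(spec.times())) / scene.pixel_size
        mid_y = len(fields[0].y) // 2
        mid_x = len(fields[0].x) // 2
        for f, inc in zip(fields, increments):
            assert abs(f.u[mid_y, mid_x] - inc) < 0.1


class TestTrackPoint:
    def _uniform_fields(self, u, n):
        x = np.array([8.0, 40.0, 72.0, 104.0])
        y = np.array([8.0, 40.0, 72.0, 104.0])
        shape = (len(y), len(x))
        return [
            piv.VectorField(
                x=x, y=y,
                u=np.full(shape, u), v=np.zeros(shape),
                valid=np.ones(shape, bool), replaced=np.zeros(shape, bool),
            )
            for _ in range(n)
        ]

    def test_zero_fields_zero_displacement(self):
        fields = self._uniform_fields(0.0, 5)
        tr = piv.track_point(fields, (50, 50), 0.5, 0.02)
        assert np.all(tr.displacement == 0.0)

    def test_constant_field_closed_form(self):
        fields = self._uniform_fields(1.0, 10)
        tr = piv.track_point(fields, (20, 50), 0.5, 0.02)
        assert np.isclose(tr.displacement[-1], 5.0)  # 10 px * 0.5 µm/px
        assert np.allclose(tr.velocity, 0.5 / 0.02)
        assert not tr.truncated

    def test_trajectory_leaving_hull_truncates(self):
        fields = self._uniform_fields(20.0, 10)
        tr = piv.track_point(fields, (100, 50), 0.5, 0.02)
        assert tr.truncated
        assert len(tr.times) < 11

    def test_start_outside_hull_rejected(self):
        fields = self._uniform_fields(0.0, 2)
        with pytest.raises(ValueError, match="hull"):
            piv.track_point(fields, (200, 50), 0.5, 0.02)

    def test_sine_movie_trace_matches_ground_truth(self, sine_movie_trace):
        spec, scene, trace, truth = sine_movie_trace
        n = len(trace.displacement)
        err = trace.displacement - truth.displacement[:n]
        assert not trace.truncated
        assert np.sqrt(np.mean(err**2)) < 0.1  # µm, at 1 µm amplitude

    def test_amplitude_recovery_within_5_percent(self):
        # 4 px amplitude movie: tracked peak within 5 % of truth
        spec = syn.WaveformSpec(kind="sine", frequency=2.0, amplitude=1.0,
                                duration=1.0, sample_interval=0.02)
        scene = syn.make_tube_scene(noise_sd=2.0)
        stack, truth = syn.generate_movie(spec, scene, seed=11)
        fields = piv.movie_to_fields(stack)
        nuc = scene.nuclei[1]
        tr = piv.track_point(
            fields,
            (nuc.center[0] / scene.pixel_size, nuc.center[1] / scene.pixel_size),
            stack.pixel_size, stack.frame_interval,
        )
        assert abs(tr.displacement.max() - 1.0) < 0.05


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(pass_windows=(32, 64)),
        dict(pass_windows=(48,)),
        dict(overlap_fraction=1.0),
        dict(subpixel="spline"),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            piv.PivConfig(**bad)

    def test_magnitude_consistency(self, speckle_frame):
        b = np.roll(np.roll(speckle_frame, 3, axis=1), 2, axis=0)
        vf = piv.correlate_pair(speckle_frame, b)
        assert np.allclose(vf.magnitude, np.hypot(vf.u, vf.v))
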