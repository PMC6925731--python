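import numpy as np
import pytest

from carostab import ultrasim
from carostab.core import ArgumentError, MotionTrajectory, RigidDisturbance

from oracles import count_local_maxima


class TestWallTrajectory:
    def test_paper_scale_sequence(self):
        traj = ultrasim.make_wall_trajectory(200, 3.2, 4)
        assert traj.n_frames == 200
        assert traj.times_s[1] == pytest.approx(0.016)
        assert traj.times_s[-1] < 3.2

    def test_zero_amplitudes_give_zero_trajectory(self):
        traj = ultrasim.make_wall_trajectory(50, 3.2, 4, 0.0, 0.0)
        assert np.allclose(traj.d_rad_mm, 0)
        assert np.allclose(traj.d_long_mm, 0)

    def test_one_radial_peak_per_cardiac_cycle(self):
        traj = ultrasim.make_wall_trajectory(200, 3.2, 4)
        assert count_local_maxima(traj.d_rad_mm) == 4

    def test_starts_at_zero_and_returns_to_baseline(self):
        traj = ultrasim.make_wall_trajectory(160, 3.2, 4, 0.4, 0.3)
        assert traj.d_rad_mm[0] == 0 and traj.d_long_mm[0] == 0
        # cycle boundaries are near baseline
        for k in (40, 80, 120):
            assert abs(traj.d_rad_mm[k]) < 0.02 * 0.4

    @pytest.mark.parametrize("bad", [
        dict(n_frames=1), dict(duration_s=0.0), dict(n_cardiac_cycles=0),
        dict(amp_rad_mm=-0.1)])
    def test_argument_errors(self, bad):
        kwargs = dict(n_frames=50, duration_s=3.2, n_cardiac_cycles=4,
                      amp_rad_mm=0.3, amp_long_mm=0.2)
        kwargs.update(bad)
        with pytest.raises(ArgumentError):
            ultrasim.make_wall_trajectory(**kwargs)


class TestDisturbance:
    def test_zero_everything_is_identically_zero(self):
        d = ultrasim.make_disturbance(64, 3.2, drift_amp=0.0, glitch_rate=0.0,
                                      seed=3)
        assert np.allclose(d.d_long_mm, 0)
        assert np.allclose(d.d_rad_mm, 0)
        assert np.allclose(d.theta_deg, 0)

    def test_deterministic_per_seed(self):
        a = ultrasim.make_disturbance(64, 3.2, seed=9)
        b = ultrasim.make_disturbance(64, 3.2, seed=9)
        assert np.array_equal(a.d_long_mm, b.d_long_mm)
        assert np.array_equal(a.theta_deg, b.theta_deg)
        c = ultrasim.make_disturbance(64, 3.2, seed=10)
        assert not np.array_equal(a.d_long_mm, c.d_long_mm)

    def test_seed_required(self):
        with pytest.raises(ArgumentError):
            ultrasim.make_disturbance(64, 3.2)

    def test_frame_one_is_zero(self):
        d = ultrasim.make_disturbance(64, 3.2, seed=4)
        assert d.d_long_mm[0] == d.d_rad_mm[0] == d.theta_deg[0] == 0.0

    def test_glitch_count_is_poisson(self):
        # mean count over 50 seeds ~ rate * duration within MC error
        rate, duration = 2.5, 3.2
        counts = [ultrasim.make_disturbance(64, duration, glitch_rate=rate,
                                            seed=s).n_glitches
                  for s in range(50)]
        expected = rate * duration
        tol = 3 * np.sqrt(expected / 50)
        assert abs(np.mean(counts) - expected) < tol


class TestPhantom:
    def test_flat_template_gives_equal_amplitudes(self):
        ph = ultrasim.make_phantom(0.7, None, 500, 1, extent_mm=(4, 4))
        assert np.allclose(ph.amplitudes, 0.7)

    def test_lumen_scatterers_are_dark(self):
        wall = ultrasim.WallModel(2.0, 0.8, undulation_amp_mm=0.0)
        ph = ultrasim.make_phantom(1.0, wall, 20000, 2, extent_mm=(4, 4))
        d = np.abs(ph.positions[:, 0] - 2.0)
        in_lumen = d < 0.7  # clear of the undulating boundary
        assert ph.amplitudes[in_lumen].max() <= wall.lumen_multiplier * 1.0 + 1e-12

    def test_bright_region_brighter_than_dark_region(self):
        template = np.full((80, 80), 0.2)
        template[:, 40:] = 0.9
        ph = ultrasim.make_phantom(template, None, 20000, 3,
                                   pixel_spacing_mm=0.05)
        cols = ph.positions[:, 1]
        bright = ph.amplitudes[(cols > 2.2) & (cols < 3.8)]
        dark = ph.amplitudes[(cols > 0.2) & (cols < 1.8)]
        assert bright.mean() > dark.mean()

    def test_empty_template_raises(self):
        with pytest.raises(ArgumentError):
            ultrasim.make_phantom(np.empty((0, 0)), None, 100, 1)

    def test_flat_template_needs_extent(self):
        with pytest.raises(ArgumentError):
            ultrasim.make_phantom(0.5, None, 100, 1)


class TestRender:
    def test_zero_amplitudes_give_uniform_minimum(self):
        rc = ultrasim.RenderConfig(shape=(64, 64))
        ph = ultrasim.ScattererSet(np.zeros((10, 3)), np.zeros(10))
        frame = ultrasim.render_bmode(ph, rc)
        assert frame.min() == frame.max() == 0

    def test_envelope_snr_is_rayleigh(self):
        # point SNR (mean/std) of fully developed speckle ~ 1.91
        rc = ultrasim.RenderConfig(shape=(192, 192))
        vals = []
        for seed in range(4):
            ph = ultrasim.make_phantom(0.6, None, 130000, seed,
                                       extent_mm=(9.6, 9.6))
            env = ultrasim.render_envelope(ph, rc)[20:-20, 20:-20]
            vals.append(env.mean() / env.std())
        assert np.mean(vals) == pytest.approx(1.91, abs=0.15)

    def test_doubling_amplitudes_shifts_db_by_constant(self):
        rc = ultrasim.RenderConfig(shape=(64, 64))
        ph = ultrasim.make_phantom(0.5, None, 20000, 7, extent_mm=(3.2, 3.2))
        ph2 = ultrasim.ScattererSet(ph.positions, 2 * ph.amplitudes)
        e1 = ultrasim.render_envelope(ph, rc)
        e2 = ultrasim.render_envelope(ph2, rc)
        db_shift = 20 * np.log10(e2 / e1)
        assert np.allclose(db_shift, 20 * np.log10(2), atol=1e-8)

    def test_output_spans_bit_depth(self, tiny_dataset):
        frames = tiny_dataset["sequence"].frames
        assert frames.dtype == np.uint8
        assert frames.max() == 255 and frames.min() == 0


class TestSimulateSequence:
    def test_ground_truth_pass_through(self, tiny_dataset):
        prof = tiny_dataset["profile"]
        motion = tiny_dataset["motion"]
        dist = tiny_dataset["disturbance"]
        assert motion.n_frames == prof.n_frames
        assert dist.n_frames == prof.n_frames
        seq = tiny_dataset["sequence"]
        assert seq.n_frames == prof.n_frames
        assert seq.frame_interval_s == pytest.approx(
            prof.duration_s / prof.n_frames)

    def test_mismatched_lengths_raise(self, tiny_dataset):
        t5 = np.arange(5) * 0.1
        t6 = np.arange(6) * 0.1
        motion = MotionTrajectory(np.zeros(5), np.zeros(5), t5)
        dist = RigidDisturbance.zeros(t6)
        with pytest.raises(ArgumentError):
            ultrasim.simulate_sequence(tiny_dataset["phantom"],
                                       tiny_dataset["wall_model"], motion,
                                       dist, tiny_dataset["render_config"],
                                       seed=1)

    def test_static_scene_frames_stay_close(self, tiny_dataset):
        # zero motion + zero disturbance: frames differ only by speckle
        # turnover, so frame-1-vs-frame-k MAD stays well below the dynamic
        # range and far tissue stays statistically stationary
        n = 4
        t = np.arange(n) * 0.1
        motion = MotionTrajectory(np.zeros(n), np.zeros(n), t)
        dist = RigidDisturbance.zeros(t)
        seq, _, _ = ultrasim.simulate_sequence(
            tiny_dataset["phantom"], tiny_dataset["wall_model"], motion,
            dist, tiny_dataset["render_config"], seed=5)
        f = seq.frames.astype(float)
        for k in range(1, n):
            assert np.abs(f[k] - f[0]).mean() < 30.0  # of 255

    def test_far_tissue_speckle_stationary_in_distribution(self, tiny_dataset):
        from scipy import stats
        n = 6
        t = np.arange(n) * 0.1
        motion = MotionTrajectory(np.zeros(n), np.zeros(n), t)
        dist = RigidDisturbance.zeros(t)
        seq, _, _ = ultrasim.simulate_sequence(
            tiny_dataset["phantom"], tiny_dataset["wall_model"], motion,
            dist, tiny_dataset["render_config"], seed=5)
        # subsample beyond the speckle correlation length so the KS test
        # sees approximately independent draws
        band0 = seq.frames[0][:20:4, ::8].ravel()
        bandk = seq.frames[-1][:20:4, ::8].ravel()
        assert stats.ks_2samp(band0, bandk).pvalue > 0.01

    def test_pure_shift_moves_cross_correlation_peak(self, tiny_dataset):
        n = 2
        t = np.arange(n) * 0.1
        shift_px = 6
        s = tiny_dataset["render_config"].pixel_spacing_mm
        motion = MotionTrajectory(np.zeros(n), np.zeros(n), t)
        dist = RigidDisturbance(np.array([0.0, shift_px * s]),
                                np.zeros(n), np.zeros(n), t)
        seq, _, _ = ultrasim.simulate_sequence(
            tiny_dataset["phantom"], tiny_dataset["wall_model"], motion,
            dist, tiny_dataset["render_config"], seed=5)
        a = seq.frames[0].astype(float)
        b = seq.frames[1].astype(float)
        a -= a.mean()
        b -= b.mean()
        xc = np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))).real
        peak = np.unravel_index(np.argmax(xc), xc.shape)
        lag_col = peak[1] if peak[1] <= a.shape[1] // 2 else peak[1] - a.shape[1]
        assert lag_col == -shift_px

    def test_rendering_deterministic(self, tiny_dataset):
        rc = tiny_dataset["render_config"]
        a = ultrasim.render_bmode(tiny_dataset["phantom"], rc)
        b = ultrasim.render_bmode(tiny_dataset["phantom"], rc)
        assert np.array_equal(a, b)
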