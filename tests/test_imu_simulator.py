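"""IMU simulation: filtering, differentiation, quantization, noise, pipeline."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from imu2seg.body_model import I2SPose, SegmentClass
from imu2seg.imu_simulator import (
    GRAVITY,
    ImuSignal,
    ImuTrajectory,
    NoiseSpec,
    QuantSpec,
    add_accel_noise,
    angular_velocity,
    butter_zero_lag,
    ideal_signal,
    quantize,
    simulate,
    specific_force,
)
from imu2seg.rotmath import rot_x, rot_z


def _static_traj(R=np.eye(3), pos=(0.0, 0.0, 1.0), n=100, rate=60.0):
    return ImuTrajectory(np.tile(R, (n, 1, 1)),
                         np.tile(np.asarray(pos, float), (n, 1)), rate)


class TestButterworth:
    def test_constant_passthrough(self):
        x = np.full((200, 3), 2.5)
        assert np.allclose(butter_zero_lag(x), x, atol=1e-9)

    def test_high_frequency_attenuated(self):
        t = np.arange(600) / 60.0
        x = np.sin(2 * np.pi * 25.0 * t)[:, None]
        y = butter_zero_lag(x, order=8, cutoff_hz=10.0, rate_hz=60.0)
        assert np.abs(y[100:-100]).max() < np.abs(x).max() / 20.0

    def test_passband_amplitude_and_zero_lag(self):
        t = np.arange(1200) / 60.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = butter_zero_lag(x[:, None], order=8, cutoff_hz=10.0,
                            rate_hz=60.0)[:, 0]
        core = slice(120, -120)
        assert abs(np.abs(y[core]).max() - 1.0) < 0.02
        # cross-correlation peak at zero lag
        lags = np.arange(-10, 11)
        xc = [np.dot(x[core], np.roll(y, k)[core]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            butter_zero_lag(np.zeros((10, 1)), order=8)
        with pytest.raises(ValueError):
            butter_zero_lag(np.zeros((200, 1)), cutoff_hz=30.0, rate_hz=60.0)


class TestAngularVelocity:
    def test_static_is_zero(self):
        assert np.allclose(angular_velocity(_static_traj()), 0.0)

    def test_constant_spin_about_global_z(self):
        """90 deg/s about z with identity start reads (0, 0, pi/2) rad/s."""
        n, rate = 120, 60.0
        R = np.stack([rot_z(90.0 * i / rate) for i in range(n)])
        traj = ImuTrajectory(R, np.zeros((n, 3)), rate)
        omega = angular_velocity(traj)
        assert np.allclose(omega, [0, 0, np.pi / 2], atol=1e-9)

    def test_spin_about_own_axis_is_attitude_invariant(self, rng):
        """A body-fixed x spin reads (r, 0, 0) regardless of global attitude."""
        rate_dps = 120.0
        for _ in range(5):
            R0 = Rotation.random(rng=rng).as_matrix()
            R = np.stack([R0 @ rot_x(rate_dps * i / 60.0) for i in range(90)])
            omega = angular_velocity(ImuTrajectory(R, np.zeros((90, 3)), 60.0))
            assert np.allclose(omega, [np.radians(rate_dps), 0, 0], atol=1e-6)

    def test_aliasing_rejected(self):
        R = np.stack([np.eye(3), rot_z(179.99), np.eye(3), rot_z(179.99)])
        with pytest.raises(ValueError):
            angular_velocity(ImuTrajectory(R, np.zeros((4, 3)), 60.0))


class TestSpecificForce:
    def test_static_identity_reads_gravity_reaction(self):
        f = specific_force(_static_traj())
        assert np.allclose(f, [0, 0, 9.81], atol=1e-9)

    def test_norm_invariant_under_attitude(self, rng):
        for _ in range(20):
            R = Rotation.random(rng=rng).as_matrix()
            f = specific_force(_static_traj(R=R))
            assert np.allclose(np.linalg.norm(f, axis=1), 9.81, atol=1e-9)

    def test_centripetal_magnitude(self):
        """1 m radius at 1 rad/s: 1.0 m/s^2 centripetal on top of gravity."""
        rate = 60.0
        t = np.arange(600) / rate
        pos = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        traj = ImuTrajectory(np.tile(np.eye(3), (600, 1, 1)), pos, rate)
        f = specific_force(traj)
        lin = f - (-GRAVITY)  # orientation fixed at identity
        mags = np.linalg.norm(lin[1:-1], axis=1)
        assert np.all(np.abs(mags - 1.0) < 1e-3)


class TestQuantize:
    def test_saturation_and_zero(self):
        sig = ImuSignal(np.array([[1000.0, -1000.0, 0.0]]).repeat(4, axis=0),
                        np.zeros((4, 3)))
        q = quantize(sig, QuantSpec())
        assert np.allclose(q.acc[:, 0], 160.0)
        assert np.allclose(q.acc[:, 1], -160.0)
        assert np.allclose(q.acc[:, 2], 0.0)

    def test_nearest_level(self):
        step = 320.0 / 65535.0  # ~4.883e-3
        sig = ImuSignal(np.full((4, 3), 0.005), np.zeros((4, 3)))
        q = quantize(sig, QuantSpec(acc_range=160.0, acc_bits=16))
        assert np.allclose(q.acc, step, atol=1e-12)

    def test_error_bounded_by_half_step(self, rng):
        x = rng.uniform(-150, 150, size=(500, 3))
        sig = ImuSignal(x, np.zeros((500, 3)))
        q = quantize(sig, QuantSpec())
        step = 320.0 / 65535.0
        assert np.max(np.abs(q.acc - x)) <= step / 2 + 1e-12


class TestAccelNoise:
    def test_zero_sigma_identity(self):
        sig = ImuSignal(np.ones((50, 3)), np.ones((50, 3)))
        out = add_accel_noise(sig, NoiseSpec(sigma_a=0.0))
        assert np.array_equal(out.acc, sig.acc)

    def test_clt_moments(self):
        """Sample mean/SD of the added noise behave like N(0, 1) draws."""
        n = 34000  # > 1e5 scalar samples over 3 channels
        sig = ImuSignal(np.zeros((n, 3)), np.zeros((n, 3)))
        out = add_accel_noise(sig, NoiseSpec(sigma_a=1.0, seed=5))
        assert abs(out.acc.mean()) < 0.02
        assert 0.98 < out.acc.std() < 1.02
        assert np.array_equal(out.gyr, sig.gyr)

    def test_seed_determinism(self):
        sig = ImuSignal(np.zeros((100, 3)), np.zeros((100, 3)))
        a = add_accel_noise(sig, NoiseSpec(sigma_a=1.0, seed=9))
        b = add_accel_noise(sig, NoiseSpec(sigma_a=1.0, seed=9))
        assert np.array_equal(a.acc, b.acc)


class TestSimulatePipeline:
    def test_static_pose_gravity_only(self, static_pose, base_i2s):
        _, _, pose = static_pose
        signals = simulate(pose, base_i2s, quant=None, noise=None)
        for seg, sig in signals.items():
            assert np.allclose(sig.gyr, 0.0, atol=1e-9)
            assert np.allclose(np.linalg.norm(sig.acc, axis=1), 9.81,
                               atol=1e-6)
            expected = base_i2s[seg].R_SI.T @ pose.rotations[seg][0].T @ (
                -GRAVITY)
            assert np.allclose(sig.acc, expected, atol=1e-6)

    def test_gyro_equivariance_under_alignment_rotation(self, short_walk,
                                                        base_i2s):
        """Rotating the mounting by R rotates the gyro output by R^T."""
        seg = SegmentClass.RightLowerLeg
        Rz = rot_z(90.0)
        i2s_a = {seg: base_i2s[seg]}
        i2s_b = {seg: I2SPose(base_i2s[seg].R_SI @ Rz, base_i2s[seg].I_S)}
        sig_a = simulate(short_walk, i2s_a, quant=None, noise=None)[seg]
        sig_b = simulate(short_walk, i2s_b, quant=None, noise=None)[seg]
        assert np.allclose(sig_b.gyr, sig_a.gyr @ Rz, atol=1e-6)

    def test_noise_fan_improves_closest_sample_error(self, short_walk,
                                                     base_i2s):
        """Closest-of-k noisy re-simulations beat the single noiseless RSE."""
        from imu2seg.evaluation import rse_opt
        seg = SegmentClass.LeftFoot
        clean = simulate(short_walk, {seg: base_i2s[seg]}, quant=None,
                         noise=None)[seg]
        rng = np.random.default_rng(3)
        # "real" signal: clean plus noise the simulator does not know
        real = clean.acc + rng.normal(0, 1.0, size=clean.acc.shape)
        sims = np.stack([
            add_accel_noise(clean, NoiseSpec(1.0, seed=k)).acc
            for k in range(100)])
        _, rmse_plain = rse_opt(real, clean.acc)
        _, rmse_opt_val = rse_opt(real, sims)
        assert rmse_opt_val < rmse_plain

    def test_simulate_determinism(self, short_walk, base_i2s):
        a = simulate(short_walk, base_i2s, quant=QuantSpec(),
                     noise=NoiseSpec(1.0, seed=4))
        b = simulate(short_walk, base_i2s, quant=QuantSpec(),
                     noise=NoiseSpec(1.0, seed=4))
        for seg in base_i2s:
            assert np.array_equal(a[seg].acc, b[seg].acc)
            assert np.array_equal(a[seg].gyr, b[seg].gyr)

    def test_signal_csv_round_trip(self, short_walk, base_i2s, tmp_path):
        seg = SegmentClass.Pelvis
        sig = simulate(short_walk, {seg: base_i2s[seg]}, quant=None,
                       noise=None)[seg]
        path = tmp_path / "sig.csv"
        sig.to_csv(path)
        back = ImuSignal.from_csv(path)
        assert np.allclose(back.acc, sig.acc, atol=1e-9)
        assert back.rate_hz == pytest.approx(60.0)
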