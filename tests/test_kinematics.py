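"""Joint-angle geometry, smoothing, angular velocity and descriptives."""

import math
import warnings

import numpy as np
import pytest

from kinemetrics.errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    SmoothingError,
    ValidationError,
)
from kinemetrics.joints import ANGLE_JOINTS, Joint
from kinemetrics.kinematics import (
    AngleSeries,
    angle_series,
    angular_velocity,
    descriptive_stats,
    joint_angle,
    smooth_interpolate,
)
from kinemetrics.keypoint_io import filter_confidence
from kinemetrics.synthetic import SynthConfig, project_skeleton

from conftest import make_series


def law_of_cosines_angle(center, a, b):
    """Independent oracle: interior angle from the three side lengths."""
    ca = math.dist(center, a)
    cb = math.dist(center, b)
    ab = math.dist(a, b)
    cosv = (ca * ca + cb * cb - ab * ab) / (2 * ca * cb)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


class TestJointAngle:
    def test_perpendicular_and_collinear(self):
        assert joint_angle((0, 0), (1, 0), (0, 1)) == pytest.approx(90.0, abs=1e-12)
        assert joint_angle((1, 1), (0, 1), (2, 1)) == pytest.approx(180.0, abs=1e-12)

    def test_matches_law_of_cosines_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            c, a, b = rng.uniform(-100, 100, (3, 2))
            assert joint_angle(c, a, b) == pytest.approx(
                law_of_cosines_angle(c, a, b), abs=1e-9
            )

    def test_similarity_invariance(self):
        """Translation, rotation and uniform scaling leave angles unchanged."""
        rng = np.random.default_rng(6)
        for _ in range(200):
            c, a, b = rng.uniform(-50, 50, (3, 2))
            base = joint_angle(c, a, b)
            shift = rng.uniform(-500, 500, 2)
            phi = rng.uniform(0, 2 * np.pi)
            scale = rng.uniform(0.1, 10)
            rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            pts = [scale * rot @ p + shift for p in (c, a, b)]
            assert joint_angle(*pts) == pytest.approx(base, abs=1e-9)

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            joint_angle((1, 1), (1, 1), (2, 2))


class TestAngleSeries:
    def test_extended_elbow_is_180(self):
        series = make_series(n_frames=2)
        for joint, xy in (
            (Joint.RIGHT_SHOULDER, (0.0, 0.0)),
            (Joint.RIGHT_ELBOW, (1.0, 0.0)),
            (Joint.RIGHT_WRIST, (2.0, 0.0)),
        ):
            c = series.column(joint)
            series.x[:, c], series.y[:, c] = xy
        ang = angle_series(series, Joint.RIGHT_ELBOW)
        np.testing.assert_allclose(ang.theta, 180.0, atol=1e-9)

    def test_filtered_wrist_makes_elbow_angle_missing(self):
        series = make_series(n_frames=3)
        series.confidence[1, series.column(Joint.RIGHT_WRIST)] = 0.2
        filtered = filter_confidence(series, 0.5)
        ang = angle_series(filtered, Joint.RIGHT_ELBOW)
        assert np.isnan(ang.theta[1])
        assert np.isfinite(ang.theta[[0, 2]]).all()

    def test_distal_joint_rejected(self):
        with pytest.raises(ValidationError):
            angle_series(make_series(), Joint.RIGHT_WRIST)

    def test_forward_kinematics_round_trip(self):
        """Scripted elbow flexion 30 -> 120 deg is recovered to 1e-6."""
        cfg = SynthConfig(duration_s=5.0, frame_rate=30.0, jitter_px=0.0, dropout=0.0)
        n = cfg.n_frames
        script = {j: np.full(n, 90.0) for j in ANGLE_JOINTS}
        script[Joint.RIGHT_ELBOW] = np.linspace(30.0, 120.0, n)
        series = project_skeleton(script, cfg, np.random.default_rng(0))
        for j in ANGLE_JOINTS:
            rec = angle_series(series, j)
            np.testing.assert_allclose(rec.theta, script[j], atol=1e-6)

    def test_mirror_symmetry(self):
        """Identical bilateral scripts give identical left/right angle series."""
        cfg = SynthConfig(duration_s=4.0, frame_rate=25.0, jitter_px=0.0, dropout=0.0)
        n = cfg.n_frames
        rng = np.random.default_rng(3)
        script = {}
        for seg in ("shoulder", "elbow", "hip", "knee"):
            tr = 90.0 + 30.0 * np.sin(np.linspace(0, 4 * np.pi, n) + rng.uniform(0, 6))
            script[Joint(f"right_{seg}")] = tr
            script[Joint(f"left_{seg}")] = tr
        series = project_skeleton(script, cfg, np.random.default_rng(0))
        cx = cfg.center_px[0]
        for j in (Joint.RIGHT_ELBOW, Joint.RIGHT_WRIST, Joint.RIGHT_KNEE, Joint.RIGHT_ANKLE):
            xr, yr = series.joint_xy(j)
            xl, yl = series.joint_xy(j.mirror)
            np.testing.assert_allclose(xl - cx, cx - xr, atol=1e-9)
            np.testing.assert_allclose(yl, yr, atol=1e-9)
        for j in (Joint.RIGHT_SHOULDER, Joint.RIGHT_ELBOW, Joint.RIGHT_HIP, Joint.RIGHT_KNEE):
            ar = angle_series(series, j).theta
            al = angle_series(series, j.mirror).theta
            np.testing.assert_allclose(al, ar, atol=1e-9)


def _angle(theta, frame_rate=30.0, joint=Joint.RIGHT_KNEE):
    return AngleSeries(joint=joint, frame_rate=frame_rate, theta=np.asarray(theta, float))


class TestSmoothing:
    def test_exact_on_linear_ramp_with_missing(self):
        rng = np.random.default_rng(9)
        n = 300
        theta = np.linspace(40.0, 140.0, n)
        for frac_missing in (0.0, 0.15, 0.30):
            t = theta.copy()
            drop = rng.choice(n, int(frac_missing * n), replace=False)
            t[drop] = np.nan
            out = smooth_interpolate(_angle(t), span=0.1)
            np.testing.assert_allclose(out.smoothed, theta, atol=1e-8)

    def test_constant_with_missing_stays_constant(self):
        rng = np.random.default_rng(10)
        t = np.full(200, 90.0)
        t[rng.choice(200, 20, replace=False)] = np.nan
        out = smooth_interpolate(_angle(t), span=0.1)
        np.testing.assert_allclose(out.smoothed, 90.0, atol=1e-8)

    def test_reduces_noise_on_sine(self):
        n = 600
        t = np.arange(n) / 30.0
        clean = 90.0 + 30.0 * np.sin(2 * np.pi * 0.2 * t)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, 2.0, n)
            sm = smooth_interpolate(_angle(noisy), span=0.05).smoothed
            assert np.sqrt(np.mean((sm - clean) ** 2)) < np.sqrt(
                np.mean((noisy - clean) ** 2)
            )

    def test_too_few_points_raises(self):
        t = np.full(100, np.nan)
        t[:3] = 90.0
        with pytest.raises(SmoothingError):
            smooth_interpolate(_angle(t), span=0.5)

    def test_output_clipped_with_warning_on_overshoot(self):
        # steep ramp into the ceiling: local extrapolation overshoots 180
        theta = np.concatenate([np.linspace(100, 179.5, 50), np.full(10, np.nan)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = smooth_interpolate(_angle(theta), span=0.3)
        assert np.nanmax(out.smoothed) <= 180.0


class TestVelocity:
    def test_linear_ramp_gives_exact_slope(self):
        ang = _angle(np.arange(5.0), frame_rate=1.0)
        ang.smoothed = ang.theta.copy()
        v = angular_velocity(ang).omega
        assert np.isnan(v[0]) and np.isnan(v[-1])
        np.testing.assert_allclose(v[1:-1], 1.0, atol=1e-12)

    def test_constant_series_zero_velocity(self):
        ang = _angle(np.full(50, 42.0))
        ang.smoothed = ang.theta.copy()
        np.testing.assert_allclose(angular_velocity(ang).omega[1:-1], 0.0, atol=1e-12)

    def test_second_order_convergence_on_sinusoid(self):
        """Halving dt shrinks the worst-case error by ~4x."""

        def max_err(fps):
            t = np.arange(int(2.0 * fps) + 1) / fps
            ang = _angle(90 + 10 * np.sin(2 * np.pi * t), frame_rate=fps)
            ang.smoothed = ang.theta.copy()
            om = angular_velocity(ang).omega[1:-1]
            exact = 10 * 2 * np.pi * np.cos(2 * np.pi * t)[1:-1]
            return np.max(np.abs(om - exact))

        ratio = max_err(40.0) / max_err(80.0)
        assert 3.0 <= ratio <= 5.0

    def test_time_reversal_negates_reversed_velocity(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 180, 40)
        fwd = _angle(theta)
        fwd.smoothed = theta.copy()
        rev = _angle(theta[::-1])
        rev.smoothed = theta[::-1].copy()
        vf = angular_velocity(fwd).omega
        vr = angular_velocity(rev).omega
        np.testing.assert_allclose(vr[1:-1], -vf[1:-1][::-1], atol=1e-12)

    def test_too_short_series_raises(self):
        ang = _angle([1.0, 2.0])
        ang.smoothed = ang.theta.copy()
        with pytest.raises(InsufficientDataError):
            angular_velocity(ang)


def test_tidy_kinematics_csv_round_trips_values(tmp_path):
    import pandas as pd

    from kinemetrics.kinematics import write_kinematics

    theta = 90 + 10 * np.sin(np.linspace(0, 6, 50))
    ang = _angle(theta)
    ang.smoothed = theta.copy()
    vel = angular_velocity(ang)
    path = tmp_path / "kin.csv"
    write_kinematics("i0", {Joint.RIGHT_KNEE: ang}, {Joint.RIGHT_KNEE: vel}, path)
    back = pd.read_csv(path)
    assert list(back.columns) == [
        "infant_id", "joint", "frame", "theta_raw", "theta_smooth", "omega",
    ]
    assert len(back) == 50
    np.testing.assert_allclose(back["theta_smooth"], theta, rtol=1e-5)
    assert back["omega"].isna().sum() == 2  # endpoint frames undefined


class TestDescriptives:
    def test_hand_computable_example(self):
        s = descriptive_stats(np.array([10.0, 20.0, 30.0]))
        assert (s.maximum, s.minimum, s.mean, s.sd) == (30.0, 10.0, 20.0, 10.0)

    def test_constant_series(self):
        s = descriptive_stats(np.full(10, 7.0))
        assert s.sd == 0.0 and s.maximum == s.minimum == s.mean == 7.0

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(50, 20, 10_000)
        s = descriptive_stats(x)
        mean = sum(x) / len(x)
        var = sum((v - mean) ** 2 for v in x) / (len(x) - 1)
        assert s.mean == pytest.approx(mean, abs=1e-9)
        assert s.sd == pytest.approx(math.sqrt(var), abs=1e-9)
        assert s.maximum == max(x) and s.minimum == min(x)

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            descriptive_stats(np.array([np.nan]))
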