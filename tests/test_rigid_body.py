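import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import suctionpower as sp
from suctionpower.rigid_body import DegenerateGeometryError

REF6 = np.array([  # six markers spread over ~3 cm
    [0.0, 0.0, 0.0], [3.0, 0.2, 0.1], [1.5, 2.5, -0.3],
    [0.5, 1.0, 1.8], [2.2, 1.8, 1.2], [1.0, 0.3, -1.5],
])


class TestFitRigidTransform:
    def test_identity(self):
        r, t, resid = sp.fit_rigid_transform(REF6, REF6)
        assert np.allclose(r, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0, atol=1e-12)
        assert resid < 1e-12

    def test_recovers_constructed_transform(self):
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        trans = np.array([1.0, 2.0, 3.0])
        obs = REF6 @ rot.T + trans
        r, t, resid = sp.fit_rigid_transform(REF6, obs)
        assert np.allclose(r, rot, atol=1e-9)
        assert np.allclose(t, trans, atol=1e-9)
        assert resid < 1e-9

    def test_nan_rows_dropped(self):
        obs = REF6 + 0.0
        obs[0, 1] = np.nan
        r, t, resid = sp.fit_rigid_transform(REF6, obs)
        assert np.allclose(r, np.eye(3), atol=1e-12)

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            sp.fit_rigid_transform(REF6[:2], REF6[:2])

    def test_collinear_points(self):
        line = np.outer(np.arange(4.0), [1.0, 0.5, -0.2])
        with pytest.raises(DegenerateGeometryError):
            sp.fit_rigid_transform(line, line)

    def test_matches_independent_solver_and_noise_statistics(self, rng):
        """Dual route: on noisy draws the fit agrees with scipy's
        align_vectors optimum, and the mean residual matches the chi
        distribution expectation for 3m - 6 residual degrees of freedom."""
        sigma = 0.008  # cm, i.e. 0.08 mm
        rot_true = Rotation.from_euler("zyx", [25, -10, 5], degrees=True)
        trans_true = np.array([0.4, -0.2, 1.0])
        residuals = []
        for _ in range(2000):
            obs = REF6 @ rot_true.as_matrix().T + trans_true
            obs = obs + rng.normal(0, sigma, obs.shape)
            r, t, resid = sp.fit_rigid_transform(REF6, obs)
            residuals.append(resid)
            rot_ref, _ = Rotation.align_vectors(obs - obs.mean(0),
                                                REF6 - REF6.mean(0))
            assert (Rotation.from_matrix(r) * rot_ref.inv()).magnitude() < 1e-8
        from scipy.special import gamma
        m = len(REF6)
        k = 3 * m - 6
        # E[sqrt(chi2_k / m)] * sigma
        expected = sigma * np.sqrt(2.0 / m) * gamma((k + 1) / 2) / gamma(k / 2)
        assert np.mean(residuals) == pytest.approx(expected, rel=0.02)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_never_returns_reflection(self, seed):
        """det(R) = +1 even for noisy near-planar marker sets."""
        g = np.random.default_rng(seed)
        ref = g.normal(size=(4, 3)) * [1.0, 1.0, 1e-4]  # nearly planar
        obs = g.normal(size=(4, 3))
        try:
            r, _, _ = sp.fit_rigid_transform(ref, obs)
        except DegenerateGeometryError:
            return
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-6)


class TestPoseSequence:
    def test_noiseless_round_trip(self, rng):
        """Poses recovered from noiseless synthetic markers reproduce the
        generating transforms to <=1e-8."""
        bone = sp.BoneDefinition("b", [f"m{i}" for i in range(6)], REF6)
        n = 40
        rots = Rotation.from_euler(
            "zyx", rng.uniform(-40, 40, size=(n, 3)), degrees=True)
        trans = rng.normal(size=(n, 3))
        coords = np.einsum("fij,nj->fni", rots.as_matrix(), REF6) + trans[:, None, :]
        ts = sp.TrajectorySet(bone.marker_names, coords, 300.0)
        pose = sp.fit_pose_sequence(bone, ts)
        ang_err = (Rotation.from_matrix(pose.rotations) * rots.inv()).magnitude()
        assert np.max(ang_err) < 1e-8
        assert np.max(np.abs(pose.translations - trans)) < 1e-8
        assert np.allclose(np.linalg.det(pose.rotations), 1.0, atol=1e-6)

    def test_missing_frames_flagged(self):
        bone = sp.BoneDefinition("b", [f"m{i}" for i in range(6)], REF6)
        coords = np.broadcast_to(REF6, (5, 6, 3)).copy()
        coords[2, :4, :] = np.nan  # only 2 markers left -> invalid
        ts = sp.TrajectorySet(bone.marker_names, coords, 300.0)
        pose = sp.fit_pose_sequence(bone, ts)
        assert not pose.valid[2] and pose.valid[[0, 1, 3, 4]].all()
        assert np.isnan(pose.transform_points(REF6[:1])[2]).all()


class TestTrackingPrecision:
    def test_noiseless_rigid_motion_is_zero(self, rng):
        rots = Rotation.random(100, rng).as_matrix()
        coords = np.einsum("fij,nj->fni", rots, REF6)
        ts = sp.TrajectorySet([f"m{i}" for i in range(6)], coords, 300.0)
        assert sp.tracking_precision(ts, [("m0", "m1"), ("m2", "m3")]) < 1e-12

    def test_matches_closed_form_for_isotropic_noise(self, rng):
        """Distance between two markers with i.i.d. isotropic noise sigma on
        each has standard deviation ~ sigma*sqrt(2) when separation >> sigma."""
        sigma = 0.008
        n = 20000
        a = np.zeros((n, 3)) + rng.normal(0, sigma, (n, 3))
        b = np.tile([3.0, 0, 0], (n, 1)) + rng.normal(0, sigma, (n, 3))
        ts = sp.TrajectorySet(["a", "b"], np.stack([a, b], 1), 300.0)
        assert sp.tracking_precision(ts, [("a", "b")]) == pytest.approx(
            sigma * np.sqrt(2), rel=0.03)

    def test_mean_over_pairs(self, rng):
        n = 5000
        mk = {"a": (0.0, 0.004), "b": (3.0, 0.004), "c": (6.0, 0.012), "d": (9.0, 0.012)}
        coords = np.stack([np.tile([x, 0, 0], (n, 1)) + rng.normal(0, s, (n, 3))
                           for x, s in mk.values()], axis=1)
        ts = sp.TrajectorySet(list(mk), coords, 300.0)
        p1 = sp.tracking_precision(ts, [("a", "b")])
        p2 = sp.tracking_precision(ts, [("c", "d")])
        both = sp.tracking_precision(ts, [("a", "b"), ("c", "d")])
        assert both == pytest.approx((p1 + p2) / 2, rel=1e-12)

    def test_all_pairs_skipped_raises(self):
        coords = np.full((10, 2, 3), np.nan)
        ts = sp.TrajectorySet(["a", "b"], coords, 300.0)
        with pytest.raises(ValueError):
            sp.tracking_precision(ts, [("a", "b")])


class TestLowpassFilter:
    def test_constant_unchanged(self):
        x = np.full(500, 3.7)
        assert np.allclose(sp.lowpass_filter(x, 40, 300), 3.7, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(1500) / 300.0
        x = np.sin(2 * np.pi * 5 * t)
        y = sp.lowpass_filter(x, 40, 300)
        mid = slice(300, 1200)
        amp = np.max(np.abs(y[mid]))
        assert amp == pytest.approx(1.0, rel=0.01)
        # zero phase: cross-correlation peak at zero lag
        lag = np.argmax(np.correlate(y[mid], x[mid], "full")) - (len(x[mid]) - 1)
        assert abs(lag) * 2 * np.pi * 5 / 300 < 0.1

    def test_stopband_attenuation_matches_butterworth(self):
        """Forward-backward 2nd-order Butterworth attenuates at |H(f)|^2."""
        f, fc, fs = 120.0, 40.0, 300.0
        t = np.arange(3000) / fs
        y = sp.lowpass_filter(np.sin(2 * np.pi * f * t), fc, fs)
        h2 = 1.0 / (1.0 + (f / fc) ** 4)  # |H|^2 of order-2 Butterworth
        assert np.max(np.abs(y[500:2500])) < h2 + 0.01

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            sp.lowpass_filter(np.zeros(100), 150, 300)

    def test_idempotent_in_passband(self):
        t = np.arange(1500) / 300.0
        x = np.sin(2 * np.pi * 3 * t)
        y1 = sp.lowpass_filter(x, 40, 300)
        y2 = sp.lowpass_filter(y1, 40, 300)
        mid = slice(300, 1200)
        assert np.max(np.abs(y2[mid] - y1[mid])) < 0.005 * np.max(np.abs(y1[mid]))

    def test_short_gaps_interpolated_long_gaps_kept(self):
        x = np.arange(40.0)
        x[10:13] = np.nan   # 3-frame gap -> filled
        x[20:30] = np.nan   # 10-frame gap -> stays missing
        y = sp.interpolate_gaps(x, max_gap=5)
        assert np.allclose(y[10:13], [10, 11, 12])
        assert np.isnan(y[20:30]).all()


class TestAnimateLandmarks:
    BONE = sp.BoneDefinition("b", ["m0", "m1", "m2"],
                             np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0]]),
                             landmarks={"p": np.array([2., 1, 0]),
                                        "q": np.array([0., 0, 3])})

    @staticmethod
    def _pose(rots, trans):
        n = len(trans)
        return sp.PoseSequence("b", rots, np.asarray(trans, float),
                               np.zeros(n), np.ones(n, bool), 300.0)

    def test_identity_pose(self):
        pose = self._pose(np.tile(np.eye(3), (3, 1, 1)), np.zeros((3, 3)))
        out = sp.animate_landmarks(pose, self.BONE, ["p"])
        assert np.allclose(out.get("p"), [2, 1, 0], atol=1e-12)

    def test_pure_translation(self):
        pose = self._pose(np.tile(np.eye(3), (2, 1, 1)),
                          [[1.0, 0, 0], [1.0, 0, 0]])
        out = sp.animate_landmarks(pose, self.BONE, ["p"])
        assert np.allclose(out.get("p"), [3, 1, 0], atol=1e-12)

    def test_rigidity_invariant(self, rng):
        rots = Rotation.random(200, rng).as_matrix()
        pose = self._pose(rots, rng.normal(size=(200, 3)))
        out = sp.animate_landmarks(pose, self.BONE, ["p", "q"])
        d = np.linalg.norm(out.get("p") - out.get("q"), axis=1)
        assert np.ptp(d) < 1e-9

    def test_unknown_landmark(self):
        pose = self._pose(np.tile(np.eye(3), (1, 1, 1)), np.zeros((1, 3)))
        with pytest.raises(KeyError):
            sp.animate_landmarks(pose, self.BONE, ["nope"])
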