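import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import suctionpower as sp


def _static_pose(n=1, rot=None, trans=None, name="b"):
    rots = np.tile(np.eye(3) if rot is None else rot, (n, 1, 1))
    tr = np.tile(np.zeros(3) if trans is None else trans, (n, 1))
    return sp.PoseSequence(name, rots, tr, np.zeros(n), np.ones(n, bool), 300.0)


def _jcs(origin=(0, 0, 0)):
    return sp.JointCS("j", sp.AnatomicalCS(np.asarray(origin, float)),
                      "prox", "dist")


class TestEulerZyx:
    def test_identity(self):
        ang, flag = sp.euler_zyx_from_matrix(np.eye(3))
        assert np.allclose(ang, 0, atol=1e-12) and not flag

    def test_constructed_angles_recovered(self):
        m = sp.matrix_from_euler_zyx(20, 10, 5)
        brute = (Rotation.from_euler("z", 20, degrees=True)
                 * Rotation.from_euler("y", 10, degrees=True)
                 * Rotation.from_euler("x", 5, degrees=True)).as_matrix()
        assert np.allclose(m, brute, atol=1e-12)
        ang, _ = sp.euler_zyx_from_matrix(m)
        assert np.allclose(ang, [20, 10, 5], atol=1e-9)

    def test_round_trip_property(self, rng):
        """Compose(decompose(R)) = R to 1e-9 away from gimbal lock."""
        rz = rng.uniform(-180, 180, 2000)
        ry = rng.uniform(-80, 80, 2000)
        rx = rng.uniform(-180, 180, 2000)
        mats = Rotation.from_euler("ZYX", np.column_stack([rz, ry, rx]),
                                   degrees=True).as_matrix()
        ang, flags = sp.euler_zyx_from_matrix(mats)
        back = Rotation.from_euler("ZYX", ang, degrees=True).as_matrix()
        assert np.max(np.abs(back - mats)) < 1e-9
        assert not flags.any()

    def test_gimbal_lock_flagged(self):
        m = sp.matrix_from_euler_zyx(30, 90, 0)
        _, flag = sp.euler_zyx_from_matrix(m)
        assert flag


class TestJcsDecompose:
    def test_identical_poses_zero(self):
        prox = _static_pose(5)
        trace = sp.jcs_decompose(_static_pose(5), prox, _jcs())
        assert np.allclose(trace.rotations_deg, 0, atol=1e-9)
        assert np.allclose(trace.translations, 0, atol=1e-9)

    @staticmethod
    def _moving_pose(rot, trans=None):
        """Two-frame pose: identity at the setup frame, then the motion."""
        rots = np.stack([np.eye(3), rot])
        tr = np.stack([np.zeros(3), np.zeros(3) if trans is None else trans])
        return sp.PoseSequence("dist", rots, tr, np.zeros(2), np.ones(2, bool), 300.0)

    def test_pure_z_rotation_about_acs(self):
        origin = np.array([1.0, -2.0, 0.5])
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        trans = origin - rot @ origin  # rotation about the ACS origin
        trace = sp.jcs_decompose(self._moving_pose(rot, trans), _static_pose(2),
                                 _jcs(origin))
        assert np.allclose(trace.rotations_deg[1], [30, 0, 0], atol=1e-9)
        assert np.allclose(trace.translations[1], 0, atol=1e-9)

    def test_zyx_composition_recovered(self):
        rot = sp.matrix_from_euler_zyx(20, 10, 5)
        trace = sp.jcs_decompose(self._moving_pose(rot), _static_pose(2), _jcs())
        assert np.allclose(trace.rotations_deg[1], [20, 10, 5], atol=1e-9)

    def test_elevation_and_retraction_signs(self, clean_bundle, clean_analysis):
        """Dorsal neurocranium rotation reads positive (elevation);
        caudoventral cleithrum rotation reads negative (retraction)."""
        elev = clean_analysis.kinematics["craniovertebral"].rz_deg
        retr = clean_analysis.kinematics["cleithrum_posttemporal"].rz_deg
        t = clean_bundle.truth
        assert np.nanmax(elev) == pytest.approx(t.elevation_amp_deg, abs=1e-9)
        assert np.nanmin(retr) == pytest.approx(-t.retraction_amp_deg, abs=1e-9)

    def test_global_frame_invariance(self, clean_bundle):
        """Re-expressing the whole scene in another world frame (one rigid
        transform applied to all marker data and to the scene-space joint
        definitions) leaves every joint trace unchanged."""
        import dataclasses
        b = clean_bundle
        g_rot = Rotation.from_euler("zyx", [17, -23, 40], degrees=True).as_matrix()
        g_tr = np.array([5.0, -3.0, 2.0])
        moved = b.trajectories.with_coords(
            np.einsum("ij,fmj->fmi", g_rot, b.trajectories.coords) + g_tr)
        joints_moved = [
            dataclasses.replace(j, origin=tuple(g_rot @ np.asarray(j.origin) + g_tr),
                                axes=tuple(map(tuple, g_rot @ j.axes_matrix())))
            for j in b.config.joints]
        cfg0 = dataclasses.replace(b.config, filters=sp.FilterSettings(None, None),
                                   endocast=None)
        cfg1 = dataclasses.replace(cfg0, joints=joints_moved)
        a0 = sp.analyze_strike(cfg0, b.bones, b.trajectories)
        a1 = sp.analyze_strike(cfg1, b.bones, moved)
        for name in a0.kinematics:
            assert np.allclose(a1.kinematics[name].rotations_deg,
                               a0.kinematics[name].rotations_deg, atol=1e-8)
            assert np.allclose(a1.kinematics[name].translations,
                               a0.kinematics[name].translations, atol=1e-8)

    def test_noisy_amplitude_recovery(self, noisy_bundle, noisy_analysis):
        """At 0.08 mm marker noise the prescribed joint amplitudes are
        recovered within 0.2 deg."""
        t = noisy_bundle.truth
        elev = np.nanmax(noisy_analysis.kinematics["craniovertebral"].rz_deg)
        retr = np.nanmin(noisy_analysis.kinematics["cleithrum_posttemporal"].rz_deg)
        assert elev == pytest.approx(t.elevation_amp_deg, abs=0.2)
        assert retr == pytest.approx(-t.retraction_amp_deg, abs=0.2)


class TestGape:
    def test_coincident_points(self):
        a = np.zeros((4, 3))
        assert np.allclose(sp.gape_trace(a, a), 0)

    def test_pythagorean_distance(self):
        a = np.zeros((1, 3))
        b = np.array([[3.0, 4.0, 0.0]])
        assert sp.gape_trace(a, b)[0] == pytest.approx(5.0)

    def test_translation_invariance(self, rng):
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 3))
        shift = np.array([10.0, -4.0, 2.0])
        assert np.allclose(sp.gape_trace(a + shift, b + shift),
                           sp.gape_trace(a, b), atol=1e-9)

    def test_peak_gape_unimodal(self):
        g = np.sin(np.linspace(0, np.pi, 301))
        idx, t = sp.find_peak_gape(g, 300.0)
        assert idx == 150 and t == pytest.approx(0.5)

    def test_peak_gape_tie_breaks_earliest(self):
        idx, _ = sp.find_peak_gape(np.ones(10), 300.0)
        assert idx == 0

    def test_generator_peak_gape_recovered(self, clean_bundle, clean_analysis):
        assert abs(clean_analysis.peak_gape_frame
                   - clean_bundle.truth_tables["peak_gape_frame"]) <= 1

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            sp.find_peak_gape(np.full(5, np.nan), 300.0)


class TestRezero:
    def _trace(self, rz):
        n = len(rz)
        rot = np.column_stack([rz, np.zeros(n), np.zeros(n)])
        return sp.KinematicTrace("j", rot, np.zeros((n, 3)),
                                 np.zeros(n, bool), np.ones(n, bool), 300.0)

    def test_constant_becomes_zero(self):
        out = sp.rezero_trace(self._trace(np.full(50, 7.0)), slice(0, 10))
        assert np.allclose(out.rz_deg, 0, atol=1e-12)

    def test_baseline_subtracted(self):
        rz = np.concatenate([np.full(10, 2.0), np.full(10, 9.0)])
        out = sp.rezero_trace(self._trace(rz), slice(0, 10))
        assert np.max(out.rz_deg) == pytest.approx(7.0)

    def test_idempotent(self):
        rz = np.sin(np.linspace(0, 3, 60)) + 2.0
        t1 = sp.rezero_trace(self._trace(rz), slice(0, 10))
        t2 = sp.rezero_trace(t1, slice(0, 10))
        assert np.allclose(t1.rz_deg, t2.rz_deg, atol=1e-12)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            sp.baseline_slice(peak_frame=5, frame_rate_hz=300.0, n_frames=100)
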