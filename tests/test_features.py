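"""Geometric features: articular angles, pitch/roll, scaling, selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from skelpose import (DEFAULT_SELECTION, FEATURE_NAMES, JointId, N_FEATURES,
                      RigidTransform, assemble_features, build_dataset,
                      compute_relative_angles, relative_angle, scale_vertical,
                      segment_pitch_roll, select_features, to_room_frame,
                      untracked_frame)
from skelpose.errors import ConfigurationError, DegenerateGeometryError
from skelpose.features import RELATIVE_ANGLE_NAMES, split_by_subject
from skelpose.joints import SENTINEL

from conftest import frame_from_joints, random_tracked_frame


class TestRelativeAngle:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 1, 0), (1, 0, 0), 90.0),
        ((0, 0, 1), (0, 0, -1), 180.0),
        ((1, 1, 0), (1, 0, 0), 45.0),
        ((2, 0, 0), (3, 0, 0), 0.0),
    ])
    def test_analytic_angles(self, a, b, expected):
        assert relative_angle(a, (0, 0, 0), b) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_segment_raises(self):
        with pytest.raises(DegenerateGeometryError):
            relative_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))


class TestComputeRelativeAngles:
    def test_t_pose_arms_are_collinear(self, standing_frame):
        J = standing_frame.joints.copy()
        for side, sign in (("L", 1), ("R", -1)):
            acr = J[int(getattr(JointId, f"ACROMION_{side}")) - 1]
            J[int(getattr(JointId, f"ELBOW_{side}")) - 1] = acr + (0, sign * 0.3, 0)
            J[int(getattr(JointId, f"WRIST_{side}")) - 1] = acr + (0, sign * 0.55, 0)
        angles = compute_relative_angles(frame_from_joints(J))
        assert angles["theta1"] == pytest.approx(180.0, abs=1e-6)
        assert angles["theta2"] == pytest.approx(180.0, abs=1e-6)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        frame = random_tracked_frame(rng)
        calib = RigidTransform(Rotation.random(random_state=seed).as_matrix(),
                               rng.uniform(-3, 3, 3))
        before = compute_relative_angles(frame)
        after = compute_relative_angles(to_room_frame(frame, calib))
        for symbol in RELATIVE_ANGLE_NAMES:
            assert abs(before[symbol] - after[symbol]) < 1e-9

    def test_flexed_knee_matches_arccos_oracle(self, standing_frame):
        # flex the left knee to 90 deg: thigh down, shank forward
        J = standing_frame.joints.copy()
        knee = J[int(JointId.KNEE_L) - 1]
        shank = np.linalg.norm(J[int(JointId.MALLEOLUS_L) - 1] - knee)
        J[int(JointId.MALLEOLUS_L) - 1] = knee + np.array([shank, 0, 0])
        frame = frame_from_joints(J)
        angles = compute_relative_angles(frame)
        u = frame.joint(JointId.ILIAC_L) - knee
        v = frame.joint(JointId.MALLEOLUS_L) - knee
        oracle = np.degrees(np.arccos(u @ v / (np.linalg.norm(u) * np.linalg.norm(v))))
        assert angles["beta1"] == pytest.approx(oracle, abs=1e-9)
        assert angles["beta1"] == pytest.approx(90.0, abs=1e-6)


def _tilted_trunk_frame(standing_frame, angle_deg, axis="pitch"):
    """Rotate the trunk segment about the shoulder (or forward) axis."""
    J = standing_frame.joints.copy()
    hc = J[int(JointId.HC) - 1]
    c7 = J[int(JointId.C7) - 1]
    m = J[int(JointId.ACROMION_R) - 1] - J[int(JointId.ACROMION_L) - 1]
    m = np.array([m[0], m[1], 0.0])
    m /= np.linalg.norm(m)
    f = np.cross([0, 0, 1], m)
    v = c7 - hc
    length = np.linalg.norm(v)
    rad = np.radians(angle_deg)
    direction = f if axis == "pitch" else m
    J[int(JointId.C7) - 1] = hc + length * (np.sin(rad) * direction +
                                            np.cos(rad) * np.array([0, 0, 1.0]))
    return frame_from_joints(J)


class TestSegmentPitchRoll:
    def test_upright_trunk_is_zero(self, standing_frame):
        # rebuild an exactly-upright trunk over Hc
        J = standing_frame.joints.copy()
        hc = J[int(JointId.HC) - 1]
        length = np.linalg.norm(J[int(JointId.C7) - 1] - hc)
        J[int(JointId.C7) - 1] = hc + [0, 0, length]
        pitch, roll = segment_pitch_roll(frame_from_joints(J), "trunk")
        assert pitch == pytest.approx(0.0, abs=1e-9)
        assert roll == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [30.0, 90.0, -25.0])
    def test_constructed_pitch_recovered(self, standing_frame, angle):
        frame = _tilted_trunk_frame(standing_frame, angle, "pitch")
        pitch, roll = segment_pitch_roll(frame, "trunk")
        assert pitch == pytest.approx(angle, abs=1e-9)
        assert roll == pytest.approx(0.0, abs=1e-9)

    def test_constructed_roll_recovered(self, standing_frame):
        frame = _tilted_trunk_frame(standing_frame, 20.0, "roll")
        pitch, roll = segment_pitch_roll(frame, "trunk")
        assert roll == pytest.approx(20.0, abs=1e-9)
        assert pitch == pytest.approx(0.0, abs=1e-9)

    def test_vertical_shoulder_axis_falls_back_to_iliac(self, standing_frame):
        J = standing_frame.joints.copy()
        c7 = J[int(JointId.C7) - 1]
        # stack the acromions vertically: shoulder axis loses its heading
        J[int(JointId.ACROMION_L) - 1] = c7 + [0, 0, 0.1]
        J[int(JointId.ACROMION_R) - 1] = c7 - [0, 0, 0.1]
        pitch, roll = segment_pitch_roll(frame_from_joints(J), "trunk")
        assert np.isfinite(pitch) and np.isfinite(roll)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_vertical_rotation_and_translation(self, seed):
        rng = np.random.default_rng(seed)
        frame = random_tracked_frame(rng)
        yaw = Rotation.from_euler("z", rng.uniform(0, 360), degrees=True)
        calib = RigidTransform(yaw.as_matrix(), rng.uniform(-2, 2, 3))
        for segment in ("trunk", "head"):
            before = segment_pitch_roll(frame, segment)
            after = segment_pitch_roll(to_room_frame(frame, calib), segment)
            assert before == pytest.approx(after, abs=1e-9)


class TestScaleAndAssemble:
    def test_z_scaled_by_height(self, standing_frame):
        z = scale_vertical(standing_frame, 1.8)
        assert np.allclose(z, standing_frame.joints[:, 2] / 1.8)

    def test_untracked_propagates_sentinel(self):
        assert np.all(scale_vertical(untracked_frame(), 1.8) == SENTINEL)
        assert np.all(assemble_features(untracked_frame(), 1.8) == SENTINEL)

    def test_nonpositive_height_rejected(self, standing_frame):
        with pytest.raises(ConfigurationError):
            scale_vertical(standing_frame, 0.0)

    def test_descriptor_has_37_finite_fields(self, standing_frame):
        fv = assemble_features(standing_frame, 1.8)
        assert fv.shape == (N_FEATURES,) == (37,)
        assert np.all(np.isfinite(fv))

    def test_angles_normalized_by_180(self, standing_frame):
        fv = assemble_features(standing_frame, 1.8)
        angles = compute_relative_angles(standing_frame)
        for i, name in enumerate(RELATIVE_ANGLE_NAMES):
            assert fv[17 + i] == pytest.approx(angles[name] / 180.0, abs=1e-12)
            assert 0.0 <= fv[17 + i] <= 1.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_normalized_ranges_hold_for_any_pose(self, seed):
        rng = np.random.default_rng(seed)
        fv = assemble_features(random_tracked_frame(rng), 1.8)
        assert np.all(fv[17:33] >= 0.0) and np.all(fv[17:33] <= 1.0)
        assert np.all(fv[33:] > -1.0 - 1e-12) and np.all(fv[33:] <= 1.0)

    def test_uniform_scaling_covariance(self, standing_frame):
        """Scaling the body about Hc together with the height leaves the
        descriptor's Z and angle features unchanged."""
        s = 1.15
        hc = standing_frame.joints[int(JointId.HC) - 1]
        scaled = frame_from_joints(hc + s * (standing_frame.joints - hc))
        fv0 = assemble_features(standing_frame, 1.8)
        # Z features shift by the Hc offset unless the scaling is about
        # the origin; scale about origin for the Z comparison
        scaled_o = frame_from_joints(s * standing_frame.joints)
        fv_o = assemble_features(scaled_o, 1.8 * s)
        assert np.allclose(fv_o[:17], fv0[:17], atol=1e-12)
        fv_hc = assemble_features(scaled, 1.8)
        assert np.allclose(fv_hc[17:33], fv0[17:33], atol=1e-12)


class TestSelection:
    def test_default_spec_order(self, standing_frame):
        fv = assemble_features(standing_frame, 1.8)
        sel = select_features(fv)
        expected = [fv[FEATURE_NAMES.index(n)] for n in DEFAULT_SELECTION]
        assert sel.tolist() == expected
        assert len(sel) == 10

    def test_full_spec_is_identity(self, standing_frame):
        fv = assemble_features(standing_frame, 1.8)
        assert np.array_equal(select_features(fv, FEATURE_NAMES), fv)

    def test_sentinel_propagates(self):
        fv = np.full(37, SENTINEL)
        assert np.all(select_features(fv) == SENTINEL)

    def test_unknown_field_rejected(self, standing_frame):
        fv = assemble_features(standing_frame, 1.8)
        with pytest.raises(ConfigurationError, match="Z_99"):
            select_features(fv, ("Z_99",))


class TestBuildDataset:
    def _stack(self, n, label, rng):
        X = rng.uniform(0, 1, size=(n, 37))
        return X, np.full(n, label)

    def test_transition_and_untracked_removed(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(100, 37))
        y = np.array([1] * 85 + [0] * 10 + [-1] * 5)
        X[y == -1] = SENTINEL
        subj = np.array(["a"] * 100)
        Xd, yd, sd = build_dataset(X, y, subj)
        assert len(Xd) == 85
        assert set(yd) == {1}

    def test_split_is_by_whole_subject(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, size=(120, 37))
        y = rng.integers(1, 5, size=120)
        subj = np.repeat([f"s{i:02d}" for i in range(12)], 10)
        Xd, yd, sd = build_dataset(X, y, subj)
        test_ids = {"s10", "s11"}
        Xtr, ytr, Xte, yte = split_by_subject(Xd, yd, sd, test_ids)
        assert len(Xtr) + len(Xte) == len(Xd)
        assert set(sd[np.isin(sd, sorted(test_ids))]) == test_ids

    def test_all_transition_warns_and_empties(self):
        X = np.zeros((5, 37))
        y = np.zeros(5, dtype=int)
        with pytest.warns(UserWarning, match="empty"):
            Xd, yd, _ = build_dataset(X, y, np.array(["a"] * 5))
        assert len(Xd) == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown labels"):
            build_dataset(np.zeros((1, 37)), [7], ["a"])
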