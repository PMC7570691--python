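import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import limotrack.kinematics as kin
from limotrack.errors import (AlreadyAlignedError, InvalidArgumentError,
                              MissingSensorError)
from limotrack.skeleton import (JOINT_INDEX, SEGMENT_NAMES, SENSED_SEGMENTS,
                                attention_pose, build_skeleton,
                                standing_pelvis_height)
from limotrack.types import QuaternionStream

from conftest import random_unit_quaternions


def to_scipy(q):
    """Scalar-first -> scipy's scalar-last."""
    q = np.asarray(q)
    return Rotation.from_quat(np.concatenate([q[..., 1:], q[..., :1]], axis=-1))


def identity_frame():
    return {name: kin.IDENTITY.copy() for name in SEGMENT_NAMES}


def stream_of(quats_per_segment, rate=60.0, aligned=False):
    n = len(next(iter(quats_per_segment.values())))
    return kin.make_stream(np.arange(n) / rate, quats_per_segment,
                           rate=rate, aligned=aligned)


class TestQuaternionPrimitives:
    def test_qmul_matches_rotation_composition(self, rng):
        a = random_unit_quaternions(rng, 200)
        b = random_unit_quaternions(rng, 200)
        ours = to_scipy(kin.qmul(a, b)).as_matrix()
        oracle = (to_scipy(a) * to_scipy(b)).as_matrix()
        np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_qinv(self, rng):
        q = random_unit_quaternions(rng, 50)
        prod = kin.qmul(q, kin.qinv(q))
        np.testing.assert_allclose(prod, np.tile(kin.IDENTITY, (50, 1)),
                                   atol=1e-12)

    def test_continuize_signs(self):
        q = np.array([[1, 0, 0, 0], [-0.999, 0.01, 0, 0], [0.998, -0.02, 0, 0]],
                     dtype=float)
        out = kin.continuize_signs(q)
        dots = np.sum(out[1:] * out[:-1], axis=-1)
        assert np.all(dots > 0)


class TestAlignQuaternions:
    def test_frame0_identity(self, rng):
        q = {s: random_unit_quaternions(rng, 5) for s in SENSED_SEGMENTS}
        out = kin.align_quaternions(stream_of(q))
        np.testing.assert_allclose(np.abs(out.quats[0, :, 0]), 1.0, atol=1e-9)
        assert out.aligned

    def test_constant_stream_all_identity(self, rng):
        q0 = random_unit_quaternions(rng, 1)[0]
        q = {s: np.tile(q0, (4, 1)) for s in SENSED_SEGMENTS}
        out = kin.align_quaternions(stream_of(q))
        np.testing.assert_allclose(np.abs(out.quats[..., 0]), 1.0, atol=1e-9)

    def test_z_rotation_oracle(self):
        # q0 = 90 deg about z, q1 = 180 deg about z -> Aq1 = 90 deg about z
        q0 = kin.quat_from_axis_angle([0, 0, 1], np.pi / 2)
        q1 = kin.quat_from_axis_angle([0, 0, 1], np.pi)
        q = {s: np.stack([q0, q1]) for s in SENSED_SEGMENTS}
        out = kin.align_quaternions(stream_of(q))
        expected = to_scipy(q1).as_matrix() @ to_scipy(q0).as_matrix().T
        np.testing.assert_allclose(to_scipy(out.quats[1, 0]).as_matrix(),
                                   expected, atol=1e-12)

    def test_double_alignment_refused(self, rng):
        q = {s: random_unit_quaternions(rng, 3) for s in SENSED_SEGMENTS}
        out = kin.align_quaternions(stream_of(q))
        with pytest.raises(AlreadyAlignedError):
            kin.align_quaternions(out)

    def test_right_invariance_to_mounting_offsets(self, rng):
        base = {s: random_unit_quaternions(rng, 20) for s in SENSED_SEGMENTS}
        offsets = {s: random_unit_quaternions(rng, 1)[0] for s in SENSED_SEGMENTS}
        shifted = {s: kin.qmul(base[s], offsets[s]) for s in SENSED_SEGMENTS}
        a = kin.align_quaternions(stream_of(base))
        b = kin.align_quaternions(stream_of(shifted))
        ra = to_scipy(a.quats.reshape(-1, 4)).as_matrix()
        rb = to_scipy(b.quats.reshape(-1, 4)).as_matrix()
        np.testing.assert_allclose(ra, rb, atol=1e-9)

    def test_left_inverse_mode(self, rng):
        q = {s: random_unit_quaternions(rng, 4) for s in SENSED_SEGMENTS}
        st = stream_of(q)
        out = kin.align_quaternions(st, left_inverse=True)
        cont = kin.continuize_signs(kin.qnormalize(st.quats))
        expected = kin.qmul(kin.qinv(cont[0])[None], cont)
        ra = to_scipy(out.quats.reshape(-1, 4)).as_matrix()
        rb = to_scipy(expected.reshape(-1, 4)).as_matrix()
        np.testing.assert_allclose(ra, rb, atol=1e-9)


class TestRotateBoneVector:
    def test_identity(self):
        np.testing.assert_allclose(
            kin.rotate_bone_vector(kin.IDENTITY, [0, 0, 1]), [0, 0, 1],
            atol=1e-15)

    def test_90deg_about_x(self):
        q = kin.quat_from_axis_angle([1, 0, 0], np.pi / 2)
        np.testing.assert_allclose(kin.rotate_bone_vector(q, [0, 0, 1]),
                                   [0, -1, 0], atol=1e-12)

    def test_matches_rotation_matrices(self, rng):
        q = random_unit_quaternions(rng, 1000)
        v = rng.normal(size=(1000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        ours = np.stack([kin.rotate_bone_vector(qi, vi) for qi, vi in zip(q, v)])
        oracle = np.stack([to_scipy(qi).as_matrix() @ vi for qi, vi in zip(q, v)])
        assert np.abs(ours - oracle).max() <= 1e-9

    def test_unit_norm_preserved(self, rng):
        q = random_unit_quaternions(rng, 100)
        out = np.stack([kin.rotate_bone_vector(qi, [0, 0, 1]) for qi in q])
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kin.rotate_bone_vector(kin.IDENTITY, [0, 0, 0])


class TestUpdateJointPosition:
    def test_basic(self):
        np.testing.assert_allclose(
            kin.update_joint_position([0, 0, 0], [0, 0, 1], 0.4), [0, 0, 0.4])

    def test_zero_length(self):
        np.testing.assert_allclose(
            kin.update_joint_position([1, 2, 3], [0, 1, 0], 0.0), [1, 2, 3])

    def test_distance_equals_length(self, rng):
        p = rng.normal(size=3)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        out = kin.update_joint_position(p, v, 0.37)
        assert np.linalg.norm(out - p) == pytest.approx(0.37, abs=1e-12)

    def test_chained_segments_match_matrix_fk(self, rng):
        q1 = random_unit_quaternions(rng, 1)[0]
        q2 = random_unit_quaternions(rng, 1)[0]
        v = np.array([0.0, 0.0, 1.0])
        p1 = kin.update_joint_position([0, 0, 0],
                                       kin.rotate_bone_vector(q1, v), 0.4)
        p2 = kin.update_joint_position(p1, kin.rotate_bone_vector(q2, v), 0.4)
        oracle = (to_scipy(q1).as_matrix() @ v) * 0.4 + \
                 (to_scipy(q2).as_matrix() @ v) * 0.4
        np.testing.assert_allclose(p2, oracle, atol=1e-9)

    def test_negative_length_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kin.update_joint_position([0, 0, 0], [0, 0, 1], -0.1)


class TestDeriveUnsensed:
    def test_identity_everywhere(self):
        sensed = {s: kin.IDENTITY.copy() for s in SENSED_SEGMENTS}
        out = kin.derive_unsensed_orientations(sensed)
        assert set(out) == set(SEGMENT_NAMES)
        for q in out.values():
            np.testing.assert_allclose(q, kin.IDENTITY)

    def test_copy_semantics(self):
        q30 = kin.quat_from_axis_angle([0, 0, 1], np.radians(30))
        sensed = {s: kin.IDENTITY.copy() for s in SENSED_SEGMENTS}
        sensed["head"] = q30
        out = kin.derive_unsensed_orientations(sensed)
        for seg in ("r_shoulder", "l_shoulder", "upper_spine"):
            np.testing.assert_array_equal(out[seg], q30)
        for seg in ("r_hip", "l_hip"):
            np.testing.assert_array_equal(out[seg], kin.IDENTITY)

    def test_bit_for_bit_copies_random(self, rng):
        for _ in range(100):
            sensed = {s: random_unit_quaternions(rng, 1)[0]
                      for s in SENSED_SEGMENTS}
            out = kin.derive_unsensed_orientations(sensed)
            for seg, src in (("r_shoulder", "head"), ("l_shoulder", "head"),
                             ("upper_spine", "head"), ("r_hip", "lower_spine"),
                             ("l_hip", "lower_spine")):
                assert out[seg].tobytes() == sensed[src].tobytes()

    def test_missing_sensor_named(self):
        sensed = {s: kin.IDENTITY.copy() for s in SENSED_SEGMENTS}
        del sensed["lower_spine"]
        with pytest.raises(MissingSensorError, match="lower_spine"):
            kin.derive_unsensed_orientations(sensed)


class TestChainUpdates:
    def test_bottom_up_identity_geometry(self, skeleton):
        orient = identity_frame()
        foot = np.array([0.5, -skeleton.segment("r_hip").length, 0.0])
        out = kin.bottom_up_update(orient, "RFoot", foot, skeleton)
        np.testing.assert_allclose(out["RFoot"], foot)
        leg = skeleton.segment("r_shin").length + skeleton.segment("r_thigh").length
        np.testing.assert_allclose(out["Pelvis"], [0.5, 0.0, leg], atol=1e-12)

    def test_bottom_up_knee_flexion_drops_pelvis(self, skeleton):
        orient = identity_frame()
        orient["r_shin"] = kin.quat_from_axis_angle([0, 1, 0], np.pi / 2)
        out = kin.bottom_up_update(orient, "RFoot", [0, 0, 0], skeleton)
        # shin horizontal: pelvis height is thigh length only
        assert out["Pelvis"][2] == pytest.approx(
            skeleton.segment("r_thigh").length, abs=1e-12)

    def test_bottom_up_fixed_foot_exact(self, skeleton, rng):
        orient = {s: random_unit_quaternions(rng, 1)[0] for s in SEGMENT_NAMES}
        foot = rng.normal(size=3)
        out = kin.bottom_up_update(orient, "LFoot", foot, skeleton)
        np.testing.assert_array_equal(out["LFoot"], foot)

    def test_top_down_identity_is_attention(self, skeleton):
        pose = kin.top_down_update(identity_frame(), [0, 0, 0], skeleton)
        expected = attention_pose(skeleton, (0, 0, 0))
        np.testing.assert_allclose(pose.positions, expected.positions, atol=1e-12)

    def test_top_down_rotation_equivariance(self, skeleton, rng):
        r = random_unit_quaternions(rng, 1)[0]
        base = {s: random_unit_quaternions(rng, 1)[0] for s in SEGMENT_NAMES}
        rotated = {s: kin.qmul(r, q) for s, q in base.items()}
        a = kin.top_down_update(base, [0, 0, 0], skeleton)
        b = kin.top_down_update(rotated, [0, 0, 0], skeleton)
        R = to_scipy(r).as_matrix()
        np.testing.assert_allclose(b.positions, a.positions @ R.T, atol=1e-9)

    def test_top_down_translation_equivariance(self, skeleton, rng):
        orient = {s: random_unit_quaternions(rng, 1)[0] for s in SEGMENT_NAMES}
        t = rng.normal(size=3)
        a = kin.top_down_update(orient, [0, 0, 0], skeleton)
        b = kin.top_down_update(orient, t, skeleton)
        np.testing.assert_allclose(b.positions, a.positions + t, atol=1e-12)

    def test_segment_lengths_preserved(self, skeleton, rng):
        orient = {s: random_unit_quaternions(rng, 1)[0] for s in SEGMENT_NAMES}
        pose = kin.top_down_update(orient, rng.normal(size=3), skeleton)
        for seg in skeleton.segments:
            d = np.linalg.norm(pose.positions[JOINT_INDEX[seg.distal]]
                               - pose.positions[JOINT_INDEX[seg.proximal]])
            assert d == pytest.approx(seg.length, abs=1e-9)


class TestSolvePose:
    def test_identity_anchored_attention(self, skeleton):
        foot = np.array([1.0, 2.0, 0.0])
        pose = kin.solve_pose(identity_frame(), skeleton, "RFoot", foot)
        np.testing.assert_allclose(pose.positions[JOINT_INDEX["RFoot"]], foot,
                                   atol=1e-12)
        expected = attention_pose(
            skeleton, foot + [0, skeleton.segment("r_hip").length,
                              standing_pelvis_height(skeleton)])
        np.testing.assert_allclose(pose.positions, expected.positions,
                                   atol=1e-12)

    def test_round_trip_stance_foot(self, skeleton, rng):
        orient = {s: random_unit_quaternions(rng, 1)[0] for s in SEGMENT_NAMES}
        foot = np.array([0.3, -0.1, 0.0])
        partial = kin.bottom_up_update(orient, "RFoot", foot, skeleton)
        pose = kin.top_down_update(orient, partial["Pelvis"], skeleton)
        np.testing.assert_allclose(pose.positions[JOINT_INDEX["RFoot"]], foot,
                                   atol=1e-9)

    def test_squat_monotone_head_height(self, skeleton):
        heads = []
        for deg in (0, 15, 30, 45, 60):
            orient = identity_frame()
            half = np.radians(deg)
            orient["r_thigh"] = kin.quat_from_axis_angle([0, 1, 0], half)
            orient["r_shin"] = kin.quat_from_axis_angle([0, 1, 0], -half)
            orient["l_thigh"] = orient["r_thigh"]
            orient["l_shin"] = orient["r_shin"]
            pose = kin.solve_pose(orient, skeleton, "RFoot", [0, 0, 0])
            heads.append(pose.positions[JOINT_INDEX["Head"], 2])
        assert all(a > b for a, b in zip(heads, heads[1:]))

    def test_stance_foot_grounded(self, skeleton, rng):
        orient = {s: random_unit_quaternions(rng, 1)[0] for s in SEGMENT_NAMES}
        pose = kin.solve_pose(orient, skeleton, "LFoot", [0, 0, 0.5])
        assert pose.positions[JOINT_INDEX["LFoot"], 2] == pytest.approx(0, abs=1e-12)
        assert pose.stance_foot == "LFoot"
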