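import numpy as np
import pytest

import limotrack as lt
import limotrack.kinematics as kin
from limotrack import clouds, fusion, simulate as sim
from limotrack.errors import InvalidArgumentError
from limotrack.skeleton import JOINT_INDEX, SEGMENT_NAMES


def point_on_scene(p, capsules, room, tol=1e-9):
    """Distance of p to the nearest capsule surface or room box face."""
    best = np.inf
    for p0, p1, r in capsules:
        ba = np.asarray(p1) - np.asarray(p0)
        L = np.linalg.norm(ba)
        if L > 1e-12:
            t = np.clip(np.dot(p - p0, ba) / L ** 2, 0, 1)
        else:
            t = 0.0
        d = abs(np.linalg.norm(p - (p0 + t * ba)) - r)
        best = min(best, d)
    b = room.bounds
    for ax in range(3):
        for edge in b[ax]:
            inside = all(b[o, 0] - 1e-6 <= p[o] <= b[o, 1] + 1e-6
                         for o in range(3) if o != ax)
            if inside:
                best = min(best, abs(p[ax] - edge))
    return best


class TestGenerateMotion:
    def test_attention_identity(self, skeleton_175):
        tr = sim.generate_motion("attention", 1.0, 60.0, skeleton_175)
        np.testing.assert_allclose(np.abs(tr.segment_orientations[..., 0]),
                                   1.0, atol=1e-12)

    def test_squat_feet_fixed(self, skeleton_175):
        tr = sim.generate_motion("squat", 4.0, 60.0, skeleton_175)
        for name in ("RFoot", "LFoot"):
            feet = tr.joints[:, JOINT_INDEX[name]]
            assert np.abs(feet - feet[0]).max() == pytest.approx(0, abs=1e-9)

    def test_walk_frame_count_and_monotone_pelvis(self, skeleton_175):
        tr = sim.generate_motion("walk", 10.0, 60.0, skeleton_175)
        assert len(tr) == 600
        pelvis_x = tr.joints[:, JOINT_INDEX["Pelvis"], 0]
        # monotone once the amplitude ramp (1 s) has finished, up to
        # sub-millimeter discretization dips at the stance swaps
        assert np.all(np.diff(pelvis_x[60:]) >= -1e-3)
        assert pelvis_x[-1] > pelvis_x[0] + 0.5

    def test_key_poses_distinct_and_held(self, skeleton_175):
        tr = sim.generate_motion("key_poses_14", 28.0, 30.0, skeleton_175)
        slot = len(tr) // 14
        # sample the settled end of each slot; poses must be distinct
        samples = [tr.segment_orientations[(k + 1) * slot - 1] for k in range(14)]
        for a in range(14):
            for b in range(a + 1, 14):
                assert np.abs(samples[a] - samples[b]).max() > 1e-3, (a, b)
        # held: orientation static over the last third of each slot
        for k in range(14):
            seg = tr.segment_orientations[k * slot + 2 * slot // 3:(k + 1) * slot]
            assert np.abs(np.diff(seg, axis=0)).max() < 1e-9

    def test_unknown_kind_rejected(self, skeleton_175):
        with pytest.raises(InvalidArgumentError):
            sim.generate_motion("moonwalk", 1.0, 60.0, skeleton_175)

    def test_reproducible(self, skeleton_175):
        a = sim.generate_motion("walk", 2.0, 60.0, skeleton_175, seed=5)
        b = sim.generate_motion("walk", 2.0, 60.0, skeleton_175, seed=5)
        assert a.joints.tobytes() == b.joints.tobytes()

    def test_segment_lengths_preserved_every_frame(self, skeleton_175):
        tr = sim.generate_motion("key_poses_14", 7.0, 30.0, skeleton_175)
        for i in range(0, len(tr), 13):
            for seg in skeleton_175.segments:
                d = np.linalg.norm(tr.joints[i, JOINT_INDEX[seg.distal]]
                                   - tr.joints[i, JOINT_INDEX[seg.proximal]])
                assert d == pytest.approx(seg.length, abs=1e-9)

    def test_starts_in_attention(self, skeleton_175):
        for kind in ("walk", "squat", "key_poses_14"):
            tr = sim.generate_motion(kind, 2.0, 60.0, skeleton_175)
            np.testing.assert_allclose(
                np.abs(tr.segment_orientations[0, :, 0]), 1.0, atol=1e-9)


class TestSampleLidarCloud:
    def test_noiseless_points_on_surfaces(self, skeleton_175):
        room = sim.RoomModel()
        sensor = sim.front_lidar(room, range_noise_std=0.0,
                                 azimuth_step_deg=2.0)
        tr = sim.generate_motion("attention", 0.1, 60.0, skeleton_175)
        frame = sim.sample_lidar_cloud(tr, skeleton_175, sensor, 0, seed=0,
                                       room=room)
        head_q = tr.segment_orientations[0, SEGMENT_NAMES.index("head")]
        capsules = sim.body_capsules(tr.joints[0], skeleton_175, head_q)
        for p in frame.points[::7]:
            assert point_on_scene(p, capsules, room) <= 1e-9

    def test_body_outside_fov_gives_no_body_returns(self, skeleton_175):
        room = sim.RoomModel()
        # sensor high on a wall: at the user's distance the +/-15 deg fan
        # passes far above the body
        sensor = sim.LidarModel("H", [0.0, -1.9, 2.9], np.eye(3),
                                range_noise_std=0.0, azimuth_step_deg=2.0)
        tr = sim.generate_motion("attention", 0.1, 60.0, skeleton_175)
        with_body = sim.sample_lidar_cloud(tr, skeleton_175, sensor, 0,
                                           seed=0, room=room)
        without = sim.sample_lidar_cloud(tr, skeleton_175, sensor, 0,
                                         seed=0, room=room, include_body=False)
        np.testing.assert_allclose(np.sort(with_body.points, axis=0),
                                   np.sort(without.points, axis=0), atol=1e-9)

    def test_ceiling_floor_has_max_y_in_l1_frame(self, skeleton_175):
        room = sim.RoomModel()
        sensor = sim.ceiling_lidar(room, range_noise_std=0.0)
        tr = sim.generate_motion("attention", 0.1, 60.0, skeleton_175)
        frame = sim.sample_lidar_cloud(tr, skeleton_175, sensor, 0, seed=0,
                                       room=room)
        l1 = sensor.to_sensor_frame(frame.points)
        idx = np.argmax(l1[:, 1])
        assert frame.points[idx, 2] < 0.02  # the max-y point is on the floor

    def test_height_closure_noiseless(self, skeleton_175):
        room = sim.RoomModel()
        sensor = sim.ceiling_lidar(room, tilt_deg=1.0, range_noise_std=0.0)
        tr = sim.generate_motion("attention", 0.1, 60.0, skeleton_175,
                                 start=(-1.0, 0.0))
        ref = sim.sample_lidar_cloud(tr, skeleton_175, sensor, 0, seed=0,
                                     room=room, include_body=False)
        full = sim.sample_lidar_cloud(tr, skeleton_175, sensor, 0, seed=1,
                                      room=room)
        refs = lt.PointCloudFrame(sensor.to_sensor_frame(ref.points), frame="l1")
        fulls = lt.PointCloudFrame(sensor.to_sensor_frame(full.points),
                                   frame="l1", variant="full_body")
        ah = clouds.calibrate_height(refs, [fulls], slope_source="floor")
        # vertical ray spacing at the head: channel step over head distance
        dist = np.linalg.norm(sensor.position - tr.joints[0, JOINT_INDEX["Head"]])
        spacing = dist * np.tan(np.radians(2.0))
        assert abs(ah - skeleton_175.actual_height) <= spacing


class TestSampleImuStream:
    def test_zero_noise_closure(self, skeleton_175):
        tr = sim.generate_motion("squat", 2.0, 60.0, skeleton_175)
        stream = sim.sample_imu_stream(tr, sim.ImuModel(), seed=0)
        out = fusion.track_sequence(
            stream, None, skeleton_175, seed=0,
            initial_stance=tr.stance[0],
            initial_stance_position=tr.joints[0, JOINT_INDEX[tr.stance[0]]],
            stance_schedule=list(tr.stance))
        assert np.abs(out.positions - tr.joints).max() <= 1e-6

    def test_mounting_offsets_cancelled(self, skeleton_175):
        tr = sim.generate_motion("squat", 2.0, 60.0, skeleton_175)
        plain = sim.sample_imu_stream(tr, sim.ImuModel(), seed=0)
        offset = sim.sample_imu_stream(
            tr, sim.ImuModel(random_offsets=True), seed=0)
        kwargs = dict(initial_stance=tr.stance[0],
                      initial_stance_position=tr.joints[0, JOINT_INDEX[tr.stance[0]]],
                      stance_schedule=list(tr.stance))
        a = fusion.track_sequence(plain, None, skeleton_175, seed=0, **kwargs)
        b = fusion.track_sequence(offset, None, skeleton_175, seed=0, **kwargs)
        assert np.abs(a.positions - b.positions).max() <= 1e-9

    def test_noise_error_grows_with_chain_depth(self, skeleton_175):
        tr = sim.generate_motion("attention", 4.0, 60.0, skeleton_175)
        stream = sim.sample_imu_stream(
            tr, sim.ImuModel(orientation_noise_deg=1.0), seed=2)
        out = fusion.track_sequence(
            stream, None, skeleton_175, seed=0,
            initial_stance=tr.stance[0],
            initial_stance_position=tr.joints[0, JOINT_INDEX[tr.stance[0]]],
            stance_schedule=list(tr.stance))
        err = np.linalg.norm(out.positions - tr.joints, axis=2).mean(axis=0)
        assert err[JOINT_INDEX["RWrist"]] > err[JOINT_INDEX["RShoulder"]]

    def test_frame0_is_attention_reading(self, skeleton_175):
        tr = sim.generate_motion("walk", 1.0, 60.0, skeleton_175)
        offsets = sim.random_mounting_offsets(7)
        stream = sim.sample_imu_stream(
            tr, sim.ImuModel(mounting_offsets=offsets), seed=0)
        for j, name in enumerate(stream.segments):
            np.testing.assert_allclose(stream.quats[0, j], offsets[name],
                                       atol=1e-12)


class TestInjectDrift:
    def test_zero_rate_identity(self, walk_session):
        out = sim.inject_drift(walk_session.imu_stream, 0.0, seed=1)
        assert np.abs(out.base_offsets).max() == 0.0
        np.testing.assert_array_equal(out.quats, walk_session.imu_stream.quats)

    def test_linear_growth(self, walk_session):
        out = sim.inject_drift(walk_session.imu_stream, 0.05, seed=1)
        t = out.timestamps - out.timestamps[0]
        norms = np.linalg.norm(out.base_offsets, axis=1)
        np.testing.assert_allclose(norms, 0.05 * t, atol=1e-12)

    def test_imu_only_error_matches_rate(self, walk_session, skeleton_175):
        tr = walk_session.track
        rate, T = 0.05, tr.timestamps[-1]
        drifted = sim.inject_drift(walk_session.imu_stream, rate, seed=2)
        out = fusion.track_sequence(
            drifted, None, skeleton_175, seed=0,
            initial_stance=tr.stance[0],
            initial_stance_position=tr.joints[0, JOINT_INDEX[tr.stance[0]]],
            stance_schedule=list(tr.stance))
        final_err = np.linalg.norm(
            out.positions[-1, JOINT_INDEX[tr.stance[-1]]]
            - tr.joints[-1, JOINT_INDEX[tr.stance[-1]]])
        assert final_err == pytest.approx(rate * T, rel=0.1)

    def test_track_variant(self, skeleton_175):
        tr = sim.generate_motion("attention", 1.0, 60.0, skeleton_175)
        out = sim.inject_drift(tr, 0.1, seed=3)
        shift = out.joints[-1] - tr.joints[-1]
        np.testing.assert_allclose(np.linalg.norm(shift, axis=1),
                                   0.1 * tr.timestamps[-1], atol=1e-9)

    def test_negative_rate_rejected(self, walk_session):
        with pytest.raises(InvalidArgumentError):
            sim.inject_drift(walk_session.imu_stream, -0.1, seed=0)


class TestMakeRoomReference:
    def test_points_within_box(self):
        room = sim.RoomModel()
        sensors = sim.default_sensors(room, range_noise_std=0.0)
        ref = sim.make_room_reference(sensors, seed=0)
        b = room.bounds
        for ax in range(3):
            assert ref.points[:, ax].min() >= b[ax, 0] - 1e-6
            assert ref.points[:, ax].max() <= b[ax, 1] + 1e-6

    def test_same_seed_identical(self):
        a = sim.make_room_reference(seed=4)
        b = sim.make_room_reference(seed=4)
        assert a.points.tobytes() == b.points.tobytes()

    def test_self_difference_empty(self):
        ref = sim.make_room_reference(seed=0)
        out = clouds.extract_user_cloud(ref, ref)
        assert len(out) == 0

    def test_invalid_extent(self):
        with pytest.raises(InvalidArgumentError):
            sim.make_room_reference(extent=(0, 4, 3))


class TestSessionReproducibility:
    def test_sessions_bit_identical(self, skeleton_175):
        a = sim.simulate_session("squat", 1.0, skeleton_175, seed=9)
        b = sim.simulate_session("squat", 1.0, skeleton_175, seed=9)
        assert a.imu_stream.quats.tobytes() == b.imu_stream.quats.tobytes()
        for fa, fb in zip(a.cloud_frames, b.cloud_frames):
            assert fa.points.tobytes() == fb.points.tobytes()
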