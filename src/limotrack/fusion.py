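"""Lidar/IMU fusion: timeline alignment, stance-foot selection, and drift
correction of the dead-reckoned pose with lidar foot positions.

Corrections are whole-body rigid translations, so the kinematic solution
(and every inter-joint distance) is preserved.  Beyond the threshold
distance the pose snaps onto the lidar foot; inside it a proportional
blend removes residual error without visible jumps.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import kinematics as kin
from . import legtrack
from .clouds import extract_user_cloud
from .errors import InsufficientTrackError, InvalidArgumentError
from .skeleton import JOINT_INDEX, Skeleton, attention_pose, standing_pelvis_height
from .types import PointCloudFrame, PoseFrame, PoseTrack, QuaternionStream

log = logging.getLogger(__name__)


@dataclass
class FusionConfig:
    """Tunable parameters of the fusion stage (defaults per design)."""

    drift_threshold: float = 0.10        # delta, meters
    blend: float = 0.2                   # in (0, 1]
    stance_window: int = 15              # frames (~0.25 s at 60 Hz)
    imu_rate: float = 60.0
    lidar_rate: float = 15.0
    correction_mode: str = "gate"        # "gate" (default) or "bound"
    floor_z: float = 0.0
    stance_height_threshold: float = 0.05  # lifted feet cannot be stance
    # real-time cloud processing
    voxel_resolution: float = 0.10
    cluster_distance: float = 0.25
    leg_cluster_distance: float = 0.10
    leg_radius: float = 0.06
    # particle filter
    n_particles: int = 200
    process_noise: float = 0.5
    likelihood_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.drift_threshold <= 0:
            raise InvalidArgumentError("drift threshold must be positive")
        if not 0.0 < self.blend <= 1.0:
            raise InvalidArgumentError("blend must lie in (0, 1]")


@dataclass
class FootTrack:
    """Per-lidar-frame foot estimates with occlusion/merge flags."""

    timestamps: np.ndarray        # (m,)
    left: np.ndarray              # (m, 3)
    right: np.ndarray             # (m, 3)
    occluded: np.ndarray          # (m,) bool
    merged: np.ndarray            # (m,) bool


def resample_lidar_positions(timestamps: np.ndarray, positions: np.ndarray,
                             imu_timestamps: np.ndarray):
    """Componentwise linear interpolation onto the IMU grid.

    Returns ``(resampled, clamped)``; queries outside the lidar span are
    clamped to the nearest endpoint and flagged.
    """
    timestamps = np.asarray(timestamps, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.float64)
    imu_timestamps = np.asarray(imu_timestamps, dtype=np.float64)
    if len(timestamps) < 2:
        raise InsufficientTrackError("need at least two lidar samples")
    if not np.all(np.diff(timestamps) > 0):
        raise InvalidArgumentError("lidar timestamps must be strictly increasing")
    out = np.stack([np.interp(imu_timestamps, timestamps, positions[:, c])
                    for c in range(positions.shape[1])], axis=1)
    clamped = (imu_timestamps < timestamps[0]) | (imu_timestamps > timestamps[-1])
    return out, clamped


def select_stance_foot(recent_poses: list[PoseFrame],
                       previous: str = "RFoot",
                       lidar_window: dict | None = None,
                       tie_tolerance: float = 1e-3) -> str:
    """The foot with the smaller mean displacement over the window.

    Displacements are measured on the lidar foot track when one is
    supplied (``lidar_window`` maps foot name -> (k, 3) recent positions);
    otherwise on the solved poses.  Ties (within ``tie_tolerance`` meters
    per frame) keep the previous stance foot; an empty or single-frame
    window returns the default (right foot on the very first frame).
    """
    if lidar_window is not None:
        r_pos = np.asarray(lidar_window["RFoot"], dtype=np.float64)
        l_pos = np.asarray(lidar_window["LFoot"], dtype=np.float64)
        if len(r_pos) < 2:
            return previous
    else:
        if len(recent_poses) < 2:
            return previous
        r_idx, l_idx = JOINT_INDEX["RFoot"], JOINT_INDEX["LFoot"]
        r_pos = np.array([p.positions[r_idx] for p in recent_poses])
        l_pos = np.array([p.positions[l_idx] for p in recent_poses])
    # net displacement per frame; robust to per-frame estimator jitter
    k = len(r_pos) - 1
    r_disp = np.linalg.norm(r_pos[-1] - r_pos[0]) / k
    l_disp = np.linalg.norm(l_pos[-1] - l_pos[0]) / k
    if abs(r_disp - l_disp) <= tie_tolerance:
        return previous
    return "RFoot" if r_disp < l_disp else "LFoot"


def drift_correct(pose: PoseFrame, lidar_feet: dict,
                  config: FusionConfig, occluded: bool = False) -> PoseFrame:
    """Rigidly translate the pose onto the lidar stance-foot position.

    ``lidar_feet`` maps ``"LFoot"``/``"RFoot"`` to world positions.  With
    the default gate mode the pose snaps when the discrepancy exceeds the
    threshold and blends proportionally inside it; afterwards the
    stance-foot discrepancy never exceeds the threshold.
    """
    if pose.stance_foot is None:
        raise InvalidArgumentError("pose has no stance annotation")
    if occluded:
        log.debug("drift_correct: occluded frame, pose unchanged")
        return pose
    target = np.asarray(lidar_feet[pose.stance_foot], dtype=np.float64)
    e = target - pose.positions[JOINT_INDEX[pose.stance_foot]]
    norm = np.linalg.norm(e)
    if norm == 0:
        return pose
    if config.correction_mode == "bound":
        step = e if norm <= config.drift_threshold else e * (config.drift_threshold / norm)
    elif norm > config.drift_threshold:
        step = e                                   # snap
    else:
        step = config.blend * e                    # smooth
    out = pose.translated(step)
    out.stance_foot = pose.stance_foot
    return out


# ---------------------------------------------------------------------------
# lidar leg-tracking pre-pass

def build_foot_track(cloud_frames: list[PointCloudFrame],
                     reference: PointCloudFrame,
                     skeleton: Skeleton,
                     config: FusionConfig,
                     seed: int,
                     initial_pose: PoseFrame | None = None,
                     shin_axes: dict | None = None) -> FootTrack:
    """Run change detection + leg clustering + particle filters per frame.

    When no initial pose is supplied, the user's starting position is
    bootstrapped from the first frame's user-cloud centroid (the
    calibration stance): an attention pose is placed there, which seeds
    the particle filters and the left/right assignment priors.

    ``shin_axes`` optionally maps ``"LFoot"``/``"RFoot"`` to per-cloud-
    frame (m, 3) shin direction vectors (from the IMU orientations); when
    present they anchor the ankle extrapolation of each leg cluster.
    """
    if initial_pose is None:
        xy = np.zeros(2)
        if cloud_frames:
            first_user = extract_user_cloud(reference, cloud_frames[0],
                                            config.voxel_resolution,
                                            config.cluster_distance,
                                            realtime=True)
            if len(first_user):
                xy = first_user.points[:, :2].mean(axis=0)
        pelvis = np.array([xy[0], xy[1], standing_pelvis_height(skeleton)])
        initial_pose = attention_pose(skeleton, pelvis)
    prior = initial_pose
    l_init = prior.positions[JOINT_INDEX["LFoot"], :2]
    r_init = prior.positions[JOINT_INDEX["RFoot"], :2]
    if cloud_frames:
        # seed the filters at the first frame's ankle observations; the
        # attention-pose guess only disambiguates left from right
        user0 = extract_user_cloud(reference, cloud_frames[0],
                                   config.voxel_resolution,
                                   config.cluster_distance, realtime=True)
        obs0 = legtrack.cluster_leg_points(
            user0, skeleton, prior,
            cluster_distance=config.leg_cluster_distance,
            floor_z=config.floor_z)
        if not obs0.occluded and not obs0.merged:
            l_axis0 = shin_axes["LFoot"][0] if shin_axes is not None else None
            r_axis0 = shin_axes["RFoot"][0] if shin_axes is not None else None
            l_init = legtrack.ankle_from_cluster(
                obs0.left.points, config.floor_z, axis=l_axis0,
                origins=obs0.left.origins, radius=config.leg_radius)
            r_init = legtrack.ankle_from_cluster(
                obs0.right.points, config.floor_z, axis=r_axis0,
                origins=obs0.right.origins, radius=config.leg_radius)
    lstate = legtrack.init_state(l_init,
                                 n_particles=config.n_particles, seed=seed,
                                 process_noise=config.process_noise,
                                 likelihood_sigma=config.likelihood_sigma)
    rstate = legtrack.init_state(r_init,
                                 n_particles=config.n_particles, seed=seed + 1,
                                 process_noise=config.process_noise,
                                 likelihood_sigma=config.likelihood_sigma)
    m = len(cloud_frames)
    ts = np.empty(m)
    left = np.empty((m, 3))
    right = np.empty((m, 3))
    occluded = np.zeros(m, dtype=bool)
    merged = np.zeros(m, dtype=bool)
    prev_t = None
    for i, frame in enumerate(cloud_frames):
        ts[i] = frame.timestamp
        dt = (frame.timestamp - prev_t) if prev_t is not None else None
        prev_t = frame.timestamp
        if dt is not None and dt > 0:
            lstate = legtrack.pf_predict(lstate, dt, seed=seed + 1000 + 2 * i)
            rstate = legtrack.pf_predict(rstate, dt, seed=seed + 1000 + 2 * i + 1)
        user = extract_user_cloud(reference, frame, config.voxel_resolution,
                                  config.cluster_distance, realtime=True)
        # a prior pose whose knees sit above the current filter estimates
        knee_z = skeleton.segment("r_shin").length
        prior_positions = prior.positions.copy()
        prior_positions[JOINT_INDEX["LKnee"], :2] = lstate.estimate
        prior_positions[JOINT_INDEX["RKnee"], :2] = rstate.estimate
        prior_positions[JOINT_INDEX["LKnee"], 2] = knee_z
        prior_positions[JOINT_INDEX["RKnee"], 2] = knee_z
        prior = PoseFrame(prior_positions, timestamp=frame.timestamp)
        obs = legtrack.cluster_leg_points(
            user, skeleton, prior,
            cluster_distance=config.leg_cluster_distance,
            floor_z=config.floor_z)
        occluded[i] = obs.occluded
        merged[i] = obs.merged
        if not obs.occluded and not obs.merged:
            l_axis = shin_axes["LFoot"][i] if shin_axes is not None else None
            r_axis = shin_axes["RFoot"][i] if shin_axes is not None else None
            l_tgt = legtrack.ankle_from_cluster(obs.left.points, config.floor_z,
                                                axis=l_axis,
                                                origins=obs.left.origins,
                                                radius=config.leg_radius,
                                                prior_ankle=lstate.estimate)
            r_tgt = legtrack.ankle_from_cluster(obs.right.points, config.floor_z,
                                                axis=r_axis,
                                                origins=obs.right.origins,
                                                radius=config.leg_radius,
                                                prior_ankle=rstate.estimate)
            lstate = legtrack.pf_update(lstate, obs.left,
                                        seed=seed + 5000 + i, target=l_tgt)
            rstate = legtrack.pf_update(rstate, obs.right,
                                        seed=seed + 6000 + i, target=r_tgt)
        left[i], right[i] = legtrack.foot_positions(lstate, rstate,
                                                    floor_z=config.floor_z)
    return FootTrack(ts, left, right, occluded, merged)


def _shin_axes_for_frames(aligned: QuaternionStream, skeleton: Skeleton,
                          cloud_frames: list[PointCloudFrame]) -> dict:
    """World shin directions from the IMU stream at each cloud timestamp."""
    axes = {"LFoot": np.empty((len(cloud_frames), 3)),
            "RFoot": np.empty((len(cloud_frames), 3))}
    for foot, seg_name in (("LFoot", "l_shin"), ("RFoot", "r_shin")):
        seg = skeleton.segment(seg_name)
        j = aligned.index_of(seg_name)
        for i, frame in enumerate(cloud_frames):
            k = int(np.argmin(np.abs(aligned.timestamps - frame.timestamp)))
            axes[foot][i] = kin.rotate_bone_vector(aligned.quats[k, j],
                                                   seg.rest_direction)
    return axes


# ---------------------------------------------------------------------------
# main loop

def track_sequence(imu_stream: QuaternionStream,
                   cloud_frames: list[PointCloudFrame] | None,
                   skeleton: Skeleton,
                   config: FusionConfig | None = None,
                   seed: int = 0,
                   reference: PointCloudFrame | None = None,
                   initial_stance: str = "RFoot",
                   initial_stance_position: np.ndarray | None = None,
                   stance_schedule: list[str] | None = None) -> PoseTrack:
    """Fuse an IMU stream with lidar foot tracking into a pose track.

    Per IMU frame: align -> derive unsensed orientations -> solve the
    pose from the current stance foot -> correct drift against the
    resampled lidar feet.  Any frame-level lidar failure degrades to the
    IMU-only pose for that frame (logged), never aborting mid-sequence.

    ``stance_schedule`` optionally overrides the displacement-based
    stance rule with an externally supplied per-frame schedule.
    """
    config = config or FusionConfig()
    if len(imu_stream) == 0:
        raise InvalidArgumentError("empty IMU stream")
    aligned = imu_stream if imu_stream.aligned else kin.align_quaternions(imu_stream)
    n = len(aligned)

    foot_track = None
    if cloud_frames:
        if reference is None:
            raise InvalidArgumentError("cloud frames supplied without a reference cloud")
        shin_axes = _shin_axes_for_frames(aligned, skeleton, cloud_frames)
        foot_track = build_foot_track(cloud_frames, reference, skeleton,
                                      config, seed, shin_axes=shin_axes)
    lidar_feet = clamped = None
    if foot_track is not None and len(foot_track.timestamps) >= 2:
        lfeet, lcl = resample_lidar_positions(foot_track.timestamps,
                                              foot_track.left,
                                              aligned.timestamps)
        rfeet, rcl = resample_lidar_positions(foot_track.timestamps,
                                              foot_track.right,
                                              aligned.timestamps)
        lidar_feet = {"LFoot": lfeet, "RFoot": rfeet}
        clamped = lcl | rcl
        bad = foot_track.occluded | foot_track.merged
        nearest = np.clip(np.searchsorted(foot_track.timestamps,
                                          aligned.timestamps), 0,
                          len(foot_track.timestamps) - 1)
        frame_bad = bad[nearest]
    else:
        frame_bad = np.ones(n, dtype=bool)

    if initial_stance_position is None:
        if lidar_feet is not None and not frame_bad[0]:
            base = lidar_feet[initial_stance][0].copy()
        else:
            pelvis = np.array([0.0, 0.0, standing_pelvis_height(skeleton)])
            base = attention_pose(skeleton, pelvis).positions[
                JOINT_INDEX[initial_stance]].copy()
    else:
        base = np.asarray(initial_stance_position, dtype=np.float64).copy()
    base[2] = config.floor_z

    offsets = aligned.base_offsets
    stance = initial_stance
    positions = np.empty((n, 16, 3))
    quat_log = np.empty((n, 15, 4))
    stances: list[str | None] = []
    diagnostics: list[dict] = []
    recent: list[PoseFrame] = []
    corrected_any = False

    from .skeleton import SEGMENT_NAMES

    for i, (t, orientations) in enumerate(kin.orientation_frames(aligned)):
        if offsets is not None and i > 0:
            base = base + (offsets[i] - offsets[i - 1])
        if stance_schedule is not None:
            wanted = stance_schedule[i]
        else:
            lidar_window = None
            if lidar_feet is not None and not frame_bad[i]:
                lo = max(0, i - config.stance_window)
                lidar_window = {k: v[lo:i + 1] for k, v in lidar_feet.items()}
            wanted = select_stance_foot(recent[-config.stance_window:], stance,
                                        lidar_window=lidar_window)
            # never anchor on a foot that is clearly off the floor
            if (wanted != stance and i > 0
                    and positions[i - 1, JOINT_INDEX[wanted], 2]
                    > config.floor_z + config.stance_height_threshold):
                wanted = stance
        if wanted != stance and i > 0:
            base = positions[i - 1, JOINT_INDEX[wanted]].copy()
            base[2] = config.floor_z
            stance = wanted

        pose = kin.solve_pose(orientations, skeleton, stance, base,
                              timestamp=t, floor_z=config.floor_z)
        correction = 0.0
        residual = None
        used_lidar = False
        if lidar_feet is not None and not frame_bad[i] and not clamped[i]:
            feet_i = {k: v[i] for k, v in lidar_feet.items()}
            before = pose.positions[JOINT_INDEX[stance]].copy()
            pose = drift_correct(pose, feet_i, config)
            correction = float(np.linalg.norm(
                pose.positions[JOINT_INDEX[stance]] - before))
            residual = float(np.linalg.norm(
                feet_i[stance] - pose.positions[JOINT_INDEX[stance]]))
            used_lidar = True
            corrected_any = corrected_any or correction > 0
        base = pose.positions[JOINT_INDEX[stance]].copy()
        base[2] = config.floor_z

        positions[i] = pose.positions
        quat_log[i] = np.stack([orientations[name] for name in SEGMENT_NAMES])
        stances.append(stance)
        diagnostics.append({"t": float(t), "stance": stance,
                            "correction": correction,
                            "stance_residual": residual,
                            "lidar": used_lidar,
                            "occluded": bool(frame_bad[i])})
        recent.append(pose)
        if len(recent) > config.stance_window + 1:
            recent.pop(0)

    return PoseTrack(timestamps=aligned.timestamps, positions=positions,
                     stance=stances, segment_orientations=quat_log,
                     diagnostics=diagnostics)
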