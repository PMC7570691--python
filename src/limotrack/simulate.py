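"""Synthetic capture sessions: ground-truth motion, lidar clouds and IMU
quaternion streams emulating the hardware setup.

Sensor emulation
----------------
* 16-channel spinning lidar, 360 deg horizontal x +/-15 deg vertical FoV,
  configurable range noise, 10-20 Hz.  The ceiling unit (L1) is mounted
  near one end of the room with its spin axis horizontal so its sweep
  plane contains the vertical; a small mounting tilt produces the floor
  slope the height equations correct for.  A second low-mounted unit
  covers the legs from the side.
* IMU quaternions at 60 Hz with an arbitrary constant mounting offset per
  sensor and optional orientation noise; displacement drift is emulated
  as an offset schedule on the dead-reckoned stance base.

The body surface is a set of capsules around the skeleton segments plus a
head capsule whose crown sits exactly at the body height.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import kinematics as kin
from .errors import InvalidArgumentError
from .skeleton import (DERIVED_SOURCE, JOINT_INDEX, SEGMENT_NAMES,
                       SENSED_SEGMENTS, Skeleton, attention_pose,
                       standing_pelvis_height)
from .types import GroundTruthTrack, PointCloudFrame, QuaternionStream

# ---------------------------------------------------------------------------
# sensor models

VLP16_ELEVATIONS_DEG = np.arange(-15.0, 16.0, 2.0)  # 16 channels, no 0 deg


@dataclass
class LidarModel:
    """One spinning lidar: pose, ray grid and noise."""

    sensor_id: str
    position: np.ndarray
    rotation: np.ndarray                  # 3x3, columns = sensor axes in world
    rate: float = 15.0
    azimuth_step_deg: float = 0.4
    range_noise_std: float = 0.01         # gaussian std, meters
    noise_model: str = "gaussian"         # or "uniform" (+/- range_noise_std)
    max_range: float = 100.0
    _ray_dirs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        if self.rate <= 0:
            raise InvalidArgumentError("lidar rate must be positive")
        if self.range_noise_std < 0:
            raise InvalidArgumentError("range noise must be non-negative")

    def ray_directions(self) -> np.ndarray:
        """World-frame unit ray directions of the full scan grid."""
        if self._ray_dirs is None:
            az = np.radians(np.arange(0.0, 360.0, self.azimuth_step_deg))
            el = np.radians(VLP16_ELEVATIONS_DEG)
            azg, elg = np.meshgrid(az, el)
            d = np.stack([np.cos(elg) * np.cos(azg),
                          np.cos(elg) * np.sin(azg),
                          np.sin(elg)], axis=-1).reshape(-1, 3)
            self._ray_dirs = d @ self.rotation.T
        return self._ray_dirs

    def to_sensor_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.position) @ self.rotation

    def from_sensor_frame(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.position


@dataclass
class ImuModel:
    rate: float = 60.0
    orientation_noise_deg: float = 0.0     # per-axis rotation-vector std
    mounting_offsets: dict | None = None   # segment -> quat; None = random
    random_offsets: bool = False
    drift_rate: float = 0.0                # m/s, used by inject_drift defaults


@dataclass
class RoomModel:
    """Axis-aligned box: x in [-ex/2, ex/2], y in [-ey/2, ey/2], z in [0, ez]."""

    extent: tuple = (8.0, 4.0, 3.0)

    @property
    def bounds(self) -> np.ndarray:
        ex, ey, ez = self.extent
        return np.array([[-ex / 2, ex / 2], [-ey / 2, ey / 2], [0.0, ez]])


def ceiling_lidar(room: RoomModel = RoomModel(), tilt_deg: float = 1.0,
                  **kw) -> LidarModel:
    """L1: mounted high near the -x end, sweep plane vertical (x-z).

    The mounting tilt tips the down axis toward -x so the floor reads
    highest (max y in the L1 frame) directly beneath the sensor; the
    ground point then sits near the L1 x origin, as the height equations
    assume.
    """
    ex, _, ez = room.extent
    a = -math.radians(tilt_deg)
    x_s = np.array([math.cos(a), 0.0, math.sin(a)])
    y_s = np.array([math.sin(a), 0.0, -math.cos(a)])   # points at the floor
    z_s = np.cross(x_s, y_s)                            # world +y
    rotation = np.column_stack([x_s, y_s, z_s])
    position = np.array([-ex / 2 + 0.1, 0.0, ez - 0.05])
    return LidarModel("L1", position, rotation, **kw)


def front_lidar(room: RoomModel = RoomModel(), height: float = 0.5,
                **kw) -> LidarModel:
    """L2: low side mount, horizontal sweep covering the legs.

    Mounted off the room's y mid-line so the view of the legs is oblique:
    a sensor dead ahead of the user would see one leg fully shadow the
    other.
    """
    _, ey, _ = room.extent
    position = np.array([-1.2, -ey / 2 + 0.1, height])
    return LidarModel("L2", position, np.eye(3), **kw)


def default_sensors(room: RoomModel = RoomModel(), **kw) -> list[LidarModel]:
    return [ceiling_lidar(room, **kw), front_lidar(room, **kw)]


# ---------------------------------------------------------------------------
# raycasting

#: Capsule radii per segment (meters); limbs default to LIMB_RADIUS.
LIMB_RADIUS = 0.06
CAPSULE_RADII = {
    "lower_spine": 0.14,
    "upper_spine": 0.14,
    "head": 0.07,
}
HEAD_RADIUS = 0.11


def _ray_box_hits(origin: np.ndarray, dirs: np.ndarray,
                  bounds: np.ndarray) -> np.ndarray:
    """Distance along each ray to the *far* wall of an axis-aligned box
    (the sensor sits inside, so the relevant hit is the exit point)."""
    t_hit = np.full(len(dirs), np.inf)
    for axis in range(3):
        for b in bounds[axis]:
            denom = dirs[:, axis]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (b - origin[axis]) / denom
            valid = np.isfinite(t) & (t > 1e-6)
            with np.errstate(invalid="ignore"):
                p = origin + np.where(valid, t, 0.0)[:, None] * dirs
            for other in range(3):
                if other == axis:
                    continue
                valid &= (p[:, other] >= bounds[other, 0] - 1e-9)
                valid &= (p[:, other] <= bounds[other, 1] + 1e-9)
            t_hit = np.where(valid & (t < t_hit), t, t_hit)
    return t_hit


def _ray_capsule_hits(origin: np.ndarray, dirs: np.ndarray, p0: np.ndarray,
                      p1: np.ndarray, radius: float) -> np.ndarray:
    """Distance along each ray to a capsule (inf when missed)."""
    n = len(dirs)
    t_hit = np.full(n, np.inf)
    ba = p1 - p0
    length = np.linalg.norm(ba)
    axis = ba / length if length > 1e-12 else np.array([0.0, 0.0, 1.0])

    oa = origin - p0
    d_ax = dirs @ axis
    oa_ax = oa @ axis
    m = dirs - d_ax[:, None] * axis
    nvec = oa - oa_ax * axis
    a2 = np.einsum("ij,ij->i", m, m)
    b2 = 2.0 * (m @ nvec)
    c2 = nvec @ nvec - radius * radius

    # infinite-cylinder intersection where the ray is not axis-parallel
    cyl = a2 > 1e-12
    disc = b2 * b2 - 4.0 * a2 * c2
    ok = cyl & (disc >= 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t = np.where(ok, (-b2 - sq) / (2.0 * np.where(cyl, a2, 1.0)), np.inf)
    with np.errstate(invalid="ignore"):
        s = oa_ax + np.where(ok, t, 0.0) * d_ax   # axial coordinate of the hit
    cyl_hit = ok & (t > 1e-6) & (s >= 0.0) & (s <= length)
    t_hit = np.where(cyl_hit, t, t_hit)

    # spherical caps
    for center in (p0, p1):
        oc = origin - center
        b = 2.0 * dirs @ oc
        c = oc @ oc - radius * radius
        disc = b * b - 4.0 * c
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t = np.where(ok, (-b - sq) / 2.0, np.inf)
        cap_hit = ok & (t > 1e-6)
        t_hit = np.where(cap_hit & (t < t_hit), t, t_hit)
    return t_hit


def body_capsules(joints: np.ndarray, skeleton: Skeleton,
                  head_orientation: np.ndarray | None = None) -> list:
    """(p0, p1, radius) capsules for one pose; includes the head capsule."""
    capsules = []
    for seg in skeleton.segments:
        p0 = joints[JOINT_INDEX[seg.proximal]]
        p1 = joints[JOINT_INDEX[seg.distal]]
        r = CAPSULE_RADII.get(seg.name, LIMB_RADIUS)
        capsules.append((p0, p1, r))
    head = joints[JOINT_INDEX["Head"]]
    if head_orientation is None:
        crown_dir = np.array([0.0, 0.0, 1.0])
    else:
        crown_dir = kin.rotate_bone_vector(head_orientation, [0.0, 0.0, 1.0])
    p1 = head + crown_dir * max(skeleton.head_top_offset - HEAD_RADIUS, 0.0)
    capsules.append((head, p1, HEAD_RADIUS))
    return capsules


def _apply_range_noise(t_hit: np.ndarray, sensor: LidarModel,
                       rng: np.random.Generator) -> np.ndarray:
    if sensor.range_noise_std <= 0:
        return t_hit
    if sensor.noise_model == "uniform":
        noise = rng.uniform(-sensor.range_noise_std, sensor.range_noise_std,
                            size=t_hit.shape)
    else:
        noise = rng.normal(0.0, sensor.range_noise_std, size=t_hit.shape)
    return t_hit + noise


def raycast_scene(sensor: LidarModel, capsules: list,
                  room: RoomModel | None, rng: np.random.Generator,
                  floor_clip: float = 0.0) -> np.ndarray:
    """Nearest-hit points of the full scan grid against capsules + room."""
    dirs = sensor.ray_directions()
    origin = sensor.position
    t_room = (_ray_box_hits(origin, dirs, room.bounds)
              if room is not None else np.full(len(dirs), np.inf))
    t_best = t_room.copy()
    for p0, p1, r in capsules:
        t_c = _ray_capsule_hits(origin, dirs, np.asarray(p0, dtype=np.float64),
                                np.asarray(p1, dtype=np.float64), r)
        # body hits below the floor are clipped away (capsule feet)
        with np.errstate(invalid="ignore"):
            z = origin[2] + np.where(np.isfinite(t_c), t_c, 0.0) * dirs[:, 2]
        t_c = np.where(np.isfinite(t_c) & (z < floor_clip - 1e-9), np.inf, t_c)
        t_best = np.minimum(t_best, t_c)
    valid = np.isfinite(t_best) & (t_best < sensor.max_range)
    t_best = _apply_range_noise(t_best, sensor, rng)
    return origin + t_best[valid, None] * dirs[valid]


def sample_lidar_cloud(track: GroundTruthTrack, skeleton: Skeleton,
                       sensor: LidarModel, frame_index: int, seed: int,
                       room: RoomModel | None = RoomModel(),
                       include_body: bool = True,
                       timestamp: float | None = None) -> PointCloudFrame:
    """One noisy scan of the scene at a ground-truth frame."""
    if include_body and not 0 <= frame_index < len(track):
        raise InvalidArgumentError(f"frame index {frame_index} out of range")
    rng = np.random.default_rng(np.random.SeedSequence([seed, frame_index,
                                                        hash(sensor.sensor_id) & 0xFFFF]))
    capsules = []
    if include_body:
        joints = track.joints[frame_index]
        head_q = track.segment_orientations[frame_index,
                                            SEGMENT_NAMES.index("head")]
        capsules = body_capsules(joints, skeleton, head_q)
    pts = raycast_scene(sensor, capsules, room, rng)
    ts = (timestamp if timestamp is not None
          else float(track.timestamps[frame_index]) if include_body else 0.0)
    origins = np.broadcast_to(sensor.position, pts.shape).copy()
    return PointCloudFrame(pts, timestamp=ts,
                           variant="realtime" if include_body else "reference",
                           frame="world", sensor_id=sensor.sensor_id,
                           origins=origins)


def make_room_reference(sensors: list[LidarModel] | None = None,
                        extent: tuple = (8.0, 4.0, 3.0),
                        seed: int = 0) -> PointCloudFrame:
    """User-free scene cloud sampled on the sensors' ray grids."""
    if min(extent) <= 0:
        raise InvalidArgumentError("room extents must be positive")
    room = RoomModel(extent)
    if sensors is None:
        sensors = default_sensors(room)
    clouds = []
    origins = []
    for k, sensor in enumerate(sensors):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        pts = raycast_scene(sensor, [], room, rng)
        clouds.append(pts)
        origins.append(np.broadcast_to(sensor.position, pts.shape).copy())
    pts = np.vstack(clouds)
    return PointCloudFrame(pts, timestamp=0.0, variant="reference",
                           frame="world", origins=np.vstack(origins))


# ---------------------------------------------------------------------------
# motion generation

def _slerp(q0: np.ndarray, q1: np.ndarray, u: float) -> np.ndarray:
    d = float(np.dot(q0, q1))
    if d < 0:
        q1 = -q1
        d = -d
    if d > 1.0 - 1e-10:
        return kin.qnormalize(q0 + u * (q1 - q0))
    theta = math.acos(min(d, 1.0))
    s = math.sin(theta)
    return (math.sin((1 - u) * theta) / s) * q0 + (math.sin(u * theta) / s) * q1


def _ease(u: np.ndarray | float):
    """Smoothstep easing on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


_AXIS = {"x": np.array([1.0, 0.0, 0.0]),
         "y": np.array([0.0, 1.0, 0.0]),
         "z": np.array([0.0, 0.0, 1.0])}


def _pose_quats(spec: dict) -> np.ndarray:
    """(15, 4) target orientations from {segment: (axis, degrees)}."""
    quats = np.tile(kin.IDENTITY, (len(SEGMENT_NAMES), 1))
    for seg, (axis, deg) in spec.items():
        quats[SEGMENT_NAMES.index(seg)] = kin.quat_from_axis_angle(
            _AXIS[axis], math.radians(deg))
    # derived segments mirror their source sensor, as on the real body
    for seg, source in DERIVED_SOURCE.items():
        if seg not in spec:
            quats[SEGMENT_NAMES.index(seg)] = quats[SEGMENT_NAMES.index(source)]
    return quats


_ARMS = ("r_upper_arm", "l_upper_arm", "r_forearm", "l_forearm")
_TRUNK = ("lower_spine", "upper_spine", "head")

#: The 14 key poses: (name, {segment: (axis, deg)}, stance foot).
KEY_POSES_14 = [
    ("attention", {}, "RFoot"),
    ("arms_forward", {s: ("y", -90.0) for s in _ARMS}, "RFoot"),
    ("t_pose", {"r_upper_arm": ("x", -90.0), "r_forearm": ("x", -90.0),
                "l_upper_arm": ("x", 90.0), "l_forearm": ("x", 90.0)}, "RFoot"),
    ("arms_up", {s: ("x", 180.0) for s in _ARMS}, "RFoot"),
    ("elbow_flexion", {"r_forearm": ("y", -90.0), "l_forearm": ("y", -90.0)},
     "RFoot"),
    ("trunk_forward", {s: ("y", 30.0) for s in _TRUNK}, "RFoot"),
    ("trunk_side", {s: ("x", 20.0) for s in _TRUNK}, "RFoot"),
    ("r_leg_forward", {"r_thigh": ("y", -45.0), "r_shin": ("y", -45.0)},
     "LFoot"),
    ("r_knee_flexion", {"r_shin": ("y", 60.0)}, "LFoot"),
    ("r_leg_lateral", {"r_thigh": ("x", -30.0), "r_shin": ("x", -30.0)},
     "LFoot"),
    ("arms_diagonal", {"r_upper_arm": ("x", -45.0), "r_forearm": ("x", -45.0),
                       "l_upper_arm": ("y", -45.0), "l_forearm": ("y", -45.0),
                       "head": ("z", 30.0)}, "LFoot"),
    ("l_leg_forward", {"l_thigh": ("y", -45.0), "l_shin": ("y", -45.0)},
     "RFoot"),
    ("l_knee_flexion", {"l_shin": ("y", 60.0)}, "RFoot"),
    ("squat", {"r_thigh": ("y", 40.0), "r_shin": ("y", -40.0),
               "l_thigh": ("y", 40.0), "l_shin": ("y", -40.0)}, "RFoot"),
]

MOTION_KINDS = ("attention", "walk", "squat", "key_poses_14",
                "walk_squat_pattern")


def _walk_orientations(t: np.ndarray, amplitude: float = 0.09,
                       stride_hz: float = 0.5):
    """Compass-gait hip angles; stance = the leg rotating rearward."""
    ramp = _ease(t / 1.0)
    theta = amplitude * ramp * np.sin(2.0 * np.pi * stride_hz * t)
    stance_right = np.cos(2.0 * np.pi * stride_hz * t) >= 0.0
    n = len(t)
    quats = np.tile(kin.IDENTITY, (n, len(SEGMENT_NAMES), 1))
    for name, sign in (("r_thigh", 1.0), ("r_shin", 1.0),
                       ("l_thigh", -1.0), ("l_shin", -1.0)):
        j = SEGMENT_NAMES.index(name)
        half = sign * theta / 2.0
        quats[:, j, 0] = np.cos(half)
        quats[:, j, 2] = np.sin(half)     # rotation about +y
    stance = ["RFoot" if s else "LFoot" for s in stance_right]
    return quats, stance


def _squat_orientations(t: np.ndarray, amplitude_deg: float = 40.0,
                        period: float = 4.0):
    n = len(t)
    ang = math.radians(amplitude_deg) * np.sin(np.pi * (t % period) / period) ** 2
    quats = np.tile(kin.IDENTITY, (n, len(SEGMENT_NAMES), 1))
    for name, sign in (("r_thigh", 1.0), ("r_shin", -1.0),
                       ("l_thigh", 1.0), ("l_shin", -1.0)):
        j = SEGMENT_NAMES.index(name)
        half = sign * ang / 2.0
        quats[:, j, 0] = np.cos(half)
        quats[:, j, 2] = np.sin(half)
    return quats, ["RFoot"] * n


def _key_pose_orientations(t: np.ndarray, poses=KEY_POSES_14,
                           transition_fraction: float = 0.3):
    n = len(t)
    duration = t[-1] - t[0] + (t[1] - t[0] if n > 1 else 1.0)
    slot = duration / len(poses)
    targets = [_pose_quats(spec) for _, spec, _ in poses]
    quats = np.empty((n, len(SEGMENT_NAMES), 4))
    stance = []
    prev = np.tile(kin.IDENTITY, (len(SEGMENT_NAMES), 1))
    for i, ti in enumerate(t - t[0]):
        k = min(int(ti // slot), len(poses) - 1)
        u = (ti - k * slot) / slot
        prev_q = targets[k - 1] if k > 0 else prev
        blend = _ease(u / transition_fraction) if u < transition_fraction else 1.0
        for j in range(len(SEGMENT_NAMES)):
            quats[i, j] = _slerp(prev_q[j], targets[k][j], float(blend))
        stance.append(poses[k][2])
    return quats, stance


def generate_motion(kind: str, duration: float, rate: float,
                    skeleton: Skeleton, seed: int = 0,
                    start: tuple | None = None,
                    n_frames: int | None = None) -> GroundTruthTrack:
    """Ground-truth motion of a named kind.

    All motions begin in the attention pose at frame 0 (the calibration
    contract) and every frame preserves the skeleton's segment lengths by
    construction (pure forward kinematics).
    """
    if kind not in MOTION_KINDS:
        raise InvalidArgumentError(f"unknown motion kind {kind!r}")
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be positive")
    n = n_frames if n_frames is not None else max(int(round(duration * rate)), 1)
    t = np.arange(n) / rate

    if kind == "attention":
        quats = np.tile(kin.IDENTITY, (n, len(SEGMENT_NAMES), 1))
        stance = ["RFoot"] * n
    elif kind == "walk":
        quats, stance = _walk_orientations(t)
    elif kind == "squat":
        quats, stance = _squat_orientations(t)
    elif kind == "key_poses_14":
        quats, stance = _key_pose_orientations(t)
    else:  # walk_squat_pattern
        n1 = int(n * 0.4)
        n2 = int(n * 0.2)
        qa, sa = _walk_orientations(t[:n1])
        qb, sb = _squat_orientations(t[:n2])
        qc, sc = _walk_orientations(t[:n - n1 - n2])
        quats = np.vstack([qa, qb, qc])
        stance = sa + ["RFoot"] * n2 + sc

    if start is None:
        start = (-2.3, 0.0) if kind in ("walk", "walk_squat_pattern") else (0.0, 0.0)

    pelvis0 = np.array([start[0], start[1], standing_pelvis_height(skeleton)])
    rest = attention_pose(skeleton, pelvis0)
    joints = np.empty((n, 16, 3))
    stance_pos = rest.positions[JOINT_INDEX[stance[0]]].copy()
    stance_pos[2] = 0.0
    prev_stance = stance[0]
    for i in range(n):
        if stance[i] != prev_stance:
            stance_pos = joints[i - 1, JOINT_INDEX[stance[i]]].copy()
            stance_pos[2] = 0.0
            prev_stance = stance[i]
        orient = {name: quats[i, j] for j, name in enumerate(SEGMENT_NAMES)}
        pose = kin.solve_pose(orient, skeleton, stance[i], stance_pos,
                              timestamp=t[i])
        joints[i] = pose.positions
    return GroundTruthTrack(timestamps=t, joints=joints,
                            segment_orientations=quats, stance=stance,
                            height=skeleton.actual_height)


# ---------------------------------------------------------------------------
# IMU sampling and drift injection

def random_mounting_offsets(seed: int) -> dict:
    """An arbitrary constant unit quaternion per sensed segment."""
    rng = np.random.default_rng(seed)
    offsets = {}
    for name in SENSED_SEGMENTS:
        q = rng.normal(size=4)
        offsets[name] = q / np.linalg.norm(q)
    return offsets


def sample_imu_stream(track: GroundTruthTrack, imu: ImuModel,
                      seed: int = 0) -> QuaternionStream:
    """Raw (unaligned) sensor quaternions for the 10 sensed segments.

    Per frame: q = noise * q_true * mounting_offset.  Frame 0 is the
    attention-pose reading, so right-inverse alignment cancels the
    mounting offsets exactly.
    """
    rng = np.random.default_rng(seed)
    if imu.mounting_offsets is not None:
        offsets = imu.mounting_offsets
    elif imu.random_offsets:
        offsets = random_mounting_offsets(seed + 1)
    else:
        offsets = {name: kin.IDENTITY for name in SENSED_SEGMENTS}

    n = len(track)
    std = math.radians(imu.orientation_noise_deg)
    per_segment = {}
    for name in SENSED_SEGMENTS:
        j = SEGMENT_NAMES.index(name)
        true_q = track.segment_orientations[:, j, :]
        q = kin.qmul(true_q, np.asarray(offsets[name], dtype=np.float64))
        if std > 0:
            rotvec = rng.normal(0.0, std, size=(n, 3))
            angle = np.linalg.norm(rotvec, axis=1)
            half = angle / 2.0
            axis = np.where(angle[:, None] > 1e-12,
                            rotvec / np.maximum(angle[:, None], 1e-12),
                            [0.0, 0.0, 1.0])
            noise = np.concatenate([np.cos(half)[:, None],
                                    np.sin(half)[:, None] * axis], axis=1)
            q = kin.qmul(noise, q)
        per_segment[name] = kin.qnormalize(q)
    return kin.make_stream(track.timestamps, per_segment, rate=imu.rate)


def inject_drift(target, drift_rate: float, seed: int = 0,
                 random_walk_std: float = 0.0):
    """Emulate displacement drift of the dead-reckoned stance base.

    For a :class:`QuaternionStream`, attaches a per-frame base-position
    offset schedule (linear in a random horizontal direction plus an
    optional random walk); orientations are untouched.  For a
    :class:`GroundTruthTrack`, shifts all joints by the same schedule.
    """
    if drift_rate < 0:
        raise InvalidArgumentError("drift rate must be non-negative")
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0.0, 2.0 * np.pi)
    direction = np.array([np.cos(angle), np.sin(angle), 0.0])

    if isinstance(target, QuaternionStream):
        t = target.timestamps - target.timestamps[0]
        offsets = direction[None, :] * (drift_rate * t)[:, None]
        if random_walk_std > 0:
            dt = np.diff(t, prepend=t[0])
            steps = rng.normal(0.0, random_walk_std, size=(len(t), 3))
            steps[:, 2] = 0.0
            offsets = offsets + np.cumsum(steps * np.sqrt(dt)[:, None], axis=0)
        out = target.copy()
        out.base_offsets = offsets
        return out
    if isinstance(target, GroundTruthTrack):
        t = target.timestamps - target.timestamps[0]
        offsets = direction[None, :] * (drift_rate * t)[:, None]
        return replace(target, joints=target.joints + offsets[:, None, :])
    raise InvalidArgumentError(f"cannot inject drift into {type(target).__name__}")


# ---------------------------------------------------------------------------
# whole sessions

@dataclass
class Session:
    """A complete synthetic capture: truth, reference, clouds, IMU."""

    track: GroundTruthTrack
    reference: PointCloudFrame
    cloud_frames: list
    imu_stream: QuaternionStream
    sensors: list
    room: RoomModel


def simulate_session(kind: str, duration: float, skeleton: Skeleton,
                     seed: int = 0, imu: ImuModel | None = None,
                     sensors: list | None = None,
                     room: RoomModel | None = None,
                     lidar: bool = True,
                     n_frames: int | None = None) -> Session:
    """Generate motion + reference cloud + lidar frames + IMU stream."""
    room = room or RoomModel()
    sensors = sensors if sensors is not None else default_sensors(room)
    imu = imu or ImuModel()
    track = generate_motion(kind, duration, imu.rate, skeleton, seed=seed,
                            n_frames=n_frames)
    stream = sample_imu_stream(track, imu, seed=seed + 17)
    reference = make_room_reference(sensors, room.extent, seed=seed + 29)
    cloud_frames = []
    if lidar and sensors:
        lidar_rate = sensors[0].rate
        t_end = track.timestamps[-1]
        times = np.arange(0.0, t_end + 1e-9, 1.0 / lidar_rate)
        for t in times:
            idx = int(np.argmin(np.abs(track.timestamps - t)))
            parts = [sample_lidar_cloud(track, skeleton, s, idx,
                                        seed=seed + 41, room=room,
                                        timestamp=float(t))
                     for s in sensors]
            pts = np.vstack([p.points for p in parts])
            origins = np.vstack([p.origins for p in parts])
            cloud_frames.append(PointCloudFrame(
                pts, timestamp=float(t), variant="realtime", frame="world",
                origins=origins))
    return Session(track=track, reference=reference,
                   cloud_frames=cloud_frames, imu_stream=stream,
                   sensors=sensors, room=room)
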