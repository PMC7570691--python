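"""Quaternion forward kinematics: sensor alignment, bone rotation, and
bottom-up / top-down joint position updates.

Convention: Hamilton product, scalar-first (qw, qx, qy, qz), right-handed,
active rotations.  A bone's world direction is obtained by conjugating its
rest-pose unit vector with the aligned segment quaternion.
"""
from __future__ import annotations

import numpy as np

from .errors import AlreadyAlignedError, InvalidArgumentError, MissingSensorError
from .skeleton import (DERIVED_SOURCE, JOINT_INDEX, SEGMENT_NAMES,
                       SENSED_SEGMENTS, Skeleton)
from .types import PoseFrame, QuaternionStream

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# quaternion primitives (vectorized over leading axes)

def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b, scalar-first, broadcasting over leading axes."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ], axis=-1)


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qinv(q: np.ndarray) -> np.ndarray:
    """Inverse; equals the conjugate for unit quaternions."""
    q = np.asarray(q, dtype=np.float64)
    n2 = np.sum(q * q, axis=-1, keepdims=True)
    return qconj(q) / n2


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def quat_from_axis_angle(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=np.float64)
    n = np.linalg.norm(axis)
    if n == 0:
        raise InvalidArgumentError("rotation axis must be non-zero")
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def continuize_signs(quats: np.ndarray) -> np.ndarray:
    """Flip quaternion signs so consecutive frames stay on one cover sheet.

    ``quats`` has shape (n_frames, ..., 4); flips propagate along axis 0.
    """
    out = np.array(quats, dtype=np.float64)
    for i in range(1, len(out)):
        dots = np.sum(out[i] * out[i - 1], axis=-1)
        out[i][dots < 0] *= -1.0
    return out


# ---------------------------------------------------------------------------
# sensor alignment and bone rotation

def align_quaternions(stream: QuaternionStream,
                      left_inverse: bool = False) -> QuaternionStream:
    """Cancel constant mounting offsets against the frame-0 attention pose.

    Computes ``Aq_i = q_i * q_0^-1`` per segment (or ``q_0^-1 * q_i`` when
    ``left_inverse`` is set).  Frame 0 becomes the identity.  Refuses to
    align an already-aligned stream.
    """
    if stream.aligned:
        raise AlreadyAlignedError("stream is already aligned; refusing to re-align")
    if len(stream) == 0:
        raise InvalidArgumentError("cannot align an empty stream")
    q = continuize_signs(qnormalize(stream.quats))
    q0_inv = qinv(q[0])                    # (n_segments, 4)
    if left_inverse:
        aligned = qmul(q0_inv[None, :, :], q)
    else:
        aligned = qmul(q, q0_inv[None, :, :])
    out = stream.copy()
    out.quats = qnormalize(aligned)
    out.aligned = True
    return out


def rotate_bone_vector(aq: np.ndarray, rest_vector: np.ndarray) -> np.ndarray:
    """Rotate a rest-pose bone direction by conjugation: Rv = aq * qv * aq^-1.

    ``rest_vector`` is embedded as the pure quaternion (0, v); the vector
    part of the product is the world-frame bone direction.
    Broadcasts over leading axes of ``aq``.
    """
    v = np.asarray(rest_vector, dtype=np.float64)
    if np.linalg.norm(v, axis=-1).min() == 0:
        raise InvalidArgumentError("rest_vector must be non-zero")
    qv = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    rv = qmul(qmul(aq, qv), qinv(aq))
    return rv[..., 1:]


def update_joint_position(neighbor_position: np.ndarray,
                          jv: np.ndarray,
                          s_length: float) -> np.ndarray:
    """PcJoint = PnJoint + Jv * Slength."""
    if s_length < 0:
        raise InvalidArgumentError("segment length must be non-negative")
    return np.asarray(neighbor_position, dtype=np.float64) + np.asarray(jv) * s_length


# ---------------------------------------------------------------------------
# per-frame orientation completion and chain updates

def derive_unsensed_orientations(frame_orientations: dict) -> dict:
    """Fill the five derived segments from the trunk sensors.

    ``frame_orientations`` maps sensed segment name -> quaternion (4,).
    Returns a dict covering all 15 segments; sensed entries are unchanged
    and each derived segment copies its source quaternion verbatim.
    """
    out = dict(frame_orientations)
    for segment, source in DERIVED_SOURCE.items():
        if source not in frame_orientations:
            raise MissingSensorError(source)
        out[segment] = np.asarray(frame_orientations[source], dtype=np.float64)
    missing = [s for s in SEGMENT_NAMES if s not in out]
    if missing:
        raise MissingSensorError(missing[0])
    return out


def _orientation_matrix(orientations: dict) -> np.ndarray:
    """Stack a name->quat dict into a (15, 4) array in canonical order."""
    return np.stack([np.asarray(orientations[name], dtype=np.float64)
                     for name in SEGMENT_NAMES])


def bottom_up_update(orientations: dict, fixed_foot: str,
                     foot_position: np.ndarray,
                     skeleton: Skeleton) -> dict:
    """Walk the leg chain from a fixed foot up to the pelvis.

    Traversal is proximal-ward, so each rotated rest direction is negated
    before the position update.  Returns a partial mapping of joint name
    -> position containing the leg joints and the pelvis; the fixed foot's
    position is returned exactly as given.
    """
    if fixed_foot not in ("RFoot", "LFoot"):
        raise InvalidArgumentError(f"fixed_foot must be a foot joint, got {fixed_foot!r}")
    positions = {fixed_foot: np.asarray(foot_position, dtype=np.float64)}
    current = fixed_foot
    for seg in skeleton.chain_to_pelvis(fixed_foot):
        jv = rotate_bone_vector(orientations[seg.name], seg.rest_direction)
        positions[seg.proximal] = update_joint_position(
            positions[current], -jv, seg.length)
        current = seg.proximal
    return positions


def top_down_update(orientations: dict, pelvis_position: np.ndarray,
                    skeleton: Skeleton, timestamp: float = 0.0) -> PoseFrame:
    """Traverse the tree from the pelvis outward and place all 16 joints."""
    positions = np.zeros((16, 3))
    positions[JOINT_INDEX["Pelvis"]] = np.asarray(pelvis_position, dtype=np.float64)
    frontier = ["Pelvis"]
    while frontier:
        joint = frontier.pop()
        base = positions[JOINT_INDEX[joint]]
        for seg in skeleton.segments_from(joint):
            jv = rotate_bone_vector(orientations[seg.name], seg.rest_direction)
            positions[JOINT_INDEX[seg.distal]] = update_joint_position(
                base, jv, seg.length)
            frontier.append(seg.distal)
    return PoseFrame(positions, timestamp=timestamp)


def solve_pose(orientations: dict, skeleton: Skeleton, stance_foot: str,
               stance_position: np.ndarray, timestamp: float = 0.0,
               floor_z: float = 0.0) -> PoseFrame:
    """Bottom-up from the stance foot, then top-down from the pelvis.

    Afterwards the whole body is shifted vertically so the stance foot
    lies on the floor plane (legs are grounded before reporting).
    """
    partial = bottom_up_update(orientations, stance_foot,
                               stance_position, skeleton)
    pose = top_down_update(orientations, partial["Pelvis"], skeleton,
                           timestamp=timestamp)
    stance_idx = JOINT_INDEX[stance_foot]
    dz = floor_z - pose.positions[stance_idx, 2]
    pose = pose.translated([0.0, 0.0, dz])
    pose.stance_foot = stance_foot
    return pose


def orientation_frames(stream: QuaternionStream):
    """Yield (timestamp, completed name->quat dict) per frame of an aligned stream."""
    if not stream.aligned:
        raise InvalidArgumentError("stream must be aligned before solving poses")
    for i in range(len(stream)):
        frame = {name: stream.quats[i, stream.index_of(name)]
                 for name in stream.segments}
        yield stream.timestamps[i], derive_unsensed_orientations(frame)


def make_stream(timestamps: np.ndarray, per_segment: dict,
                rate: float = 60.0, aligned: bool = False) -> QuaternionStream:
    """Build a QuaternionStream from a name -> (n, 4) mapping (sensed order)."""
    segments = [s for s in SENSED_SEGMENTS if s in per_segment]
    extra = sorted(set(per_segment) - set(segments))
    segments += extra
    quats = np.stack([np.asarray(per_segment[s], dtype=np.float64)
                      for s in segments], axis=1)
    return QuaternionStream(timestamps=np.asarray(timestamps, dtype=np.float64),
                            segments=segments, quats=quats, rate=rate,
                            aligned=aligned)
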