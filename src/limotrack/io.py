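"""File formats: PCD/PLY point clouds, quaternion and track CSVs, session
config YAML, skeleton JSON and BVH motion export."""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError, UnsupportedFormatError
from .fusion import FootTrack, FusionConfig
from .kinematics import continuize_signs, qinv, qmul, qnormalize
from .skeleton import JOINT_NAMES, SEGMENT_NAMES, SENSED_SEGMENTS, Skeleton
from .types import PointCloudFrame, PoseTrack, QuaternionStream

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# point clouds

def write_pcd(cloud: PointCloudFrame, path: str, binary: bool = False) -> None:
    n = len(cloud)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\n"
        f"DATA {'binary' if binary else 'ascii'}\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode())
        if binary:
            fh.write(cloud.points.astype("<f4").tobytes())
        else:
            np.savetxt(fh, cloud.points, fmt="%.6f")


def read_pcd(path: str) -> PointCloudFrame:
    with open(path, "rb") as fh:
        raw = fh.read()
    lines = raw.split(b"\n")
    meta = {}
    data_start = None
    offset = 0
    for i, line in enumerate(lines):
        offset += len(line) + 1
        text = line.decode("ascii", errors="replace").strip()
        if text.startswith("#") or not text:
            continue
        parts = text.split()
        key = parts[0].upper()
        meta[key] = parts[1:]
        if key == "DATA":
            data_start = offset
            break
    if data_start is None or "POINTS" not in meta or "FIELDS" not in meta:
        raise ParseError("PCD header missing DATA/POINTS/FIELDS",
                         line=len(meta) + 1)
    n = int(meta["POINTS"][0])
    fields = meta["FIELDS"]
    if fields[:3] != ["x", "y", "z"]:
        raise ParseError(f"expected fields x y z, got {fields}")
    mode = meta["DATA"][0].lower()
    if mode == "binary":
        count = n * len(fields)
        data = np.frombuffer(raw[data_start:data_start + 4 * count],
                             dtype="<f4").reshape(n, len(fields))
        pts = data[:, :3].astype(np.float64)
    elif mode == "ascii":
        body = raw[data_start:].decode("ascii")
        pts = (np.loadtxt(body.splitlines(), ndmin=2)[:, :3]
               if n > 0 else np.zeros((0, 3)))
    else:
        raise ParseError(f"unsupported PCD data mode {mode!r}")
    if len(pts) != n:
        raise ParseError(f"expected {n} points, found {len(pts)}")
    return PointCloudFrame(pts)


def write_ply(cloud: PointCloudFrame, path: str) -> None:
    n = len(cloud)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n"
                 f"element vertex {n}\n"
                 "property float x\nproperty float y\nproperty float z\n"
                 "end_header\n")
        np.savetxt(fh, cloud.points, fmt="%.6f")


def read_ply(path: str) -> PointCloudFrame:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParseError("not a PLY file", line=1)
    n = None
    header_end = None
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n = int(parts[2])
        if line.strip() == "end_header":
            header_end = i
            break
    if n is None or header_end is None:
        raise ParseError("PLY header missing vertex element or end_header")
    body = lines[header_end:header_end + n]
    pts = np.loadtxt(body, ndmin=2)[:, :3] if n > 0 else np.zeros((0, 3))
    return PointCloudFrame(pts)


def read_point_cloud(path: str) -> PointCloudFrame:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".pcd":
        return read_pcd(path)
    if ext == ".ply":
        return read_ply(path)
    raise UnsupportedFormatError(f"unsupported point-cloud format {ext!r}")


def write_point_cloud(cloud: PointCloudFrame, path: str, **kw) -> None:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".pcd":
        write_pcd(cloud, path, **kw)
    elif ext == ".ply":
        write_ply(cloud, path)
    else:
        raise UnsupportedFormatError(f"unsupported point-cloud format {ext!r}")


# ---------------------------------------------------------------------------
# quaternion CSV

QUAT_COLUMNS = ["timestamp", "segment_name", "qw", "qx", "qy", "qz"]


def write_quaternion_csv(stream: QuaternionStream, path: str) -> None:
    rows = []
    for i, t in enumerate(stream.timestamps):
        for j, name in enumerate(stream.segments):
            qw, qx, qy, qz = stream.quats[i, j]
            rows.append((t, name, qw, qx, qy, qz))
    pd.DataFrame(rows, columns=QUAT_COLUMNS).to_csv(path, index=False,
                                                    float_format="%.12g")


def read_quaternion_csv(path: str, rate: float = 60.0,
                        norm_tolerance: float = 1e-3) -> QuaternionStream:
    """Load, validate, renormalize and sign-continuize a quaternion CSV."""
    df = pd.read_csv(path)
    missing = set(QUAT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"quaternion CSV missing columns: {sorted(missing)}")
    unknown = set(df["segment_name"]) - set(SEGMENT_NAMES)
    if unknown:
        raise SchemaError(f"unknown segment names: {sorted(unknown)}")
    q = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=np.float64)
    norms = np.linalg.norm(q, axis=1)
    bad = np.flatnonzero(np.abs(norms - 1.0) > norm_tolerance)
    if len(bad):
        raise SchemaError(f"non-unit quaternions at rows {bad[:20].tolist()}"
                          + ("..." if len(bad) > 20 else ""))
    df = df.sort_values(["timestamp", "segment_name"], kind="stable")
    timestamps = np.sort(df["timestamp"].unique())
    segments = [s for s in SENSED_SEGMENTS if s in set(df["segment_name"])]
    segments += sorted(set(df["segment_name"]) - set(segments))
    quats = np.empty((len(timestamps), len(segments), 4))
    pivot = {name: grp for name, grp in df.groupby("segment_name")}
    for j, name in enumerate(segments):
        grp = pivot[name]
        if len(grp) != len(timestamps):
            raise SchemaError(f"segment {name!r} missing frames")
        quats[:, j, :] = grp[["qw", "qx", "qy", "qz"]].to_numpy()
    quats = continuize_signs(qnormalize(quats))
    return QuaternionStream(timestamps=timestamps, segments=segments,
                            quats=quats, rate=rate)


# ---------------------------------------------------------------------------
# track CSVs

def write_pose_track_csv(track: PoseTrack, path: str) -> None:
    cols = {"timestamp": track.timestamps}
    for i, name in enumerate(JOINT_NAMES):
        for c, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = track.positions[:, i, c]
    if track.stance:
        cols["stance_foot"] = track.stance
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def read_pose_track_csv(path: str) -> PoseTrack:
    df = pd.read_csv(path)
    positions = np.empty((len(df), 16, 3))
    for i, name in enumerate(JOINT_NAMES):
        for c, ax in enumerate("xyz"):
            positions[:, i, c] = df[f"{name}_{ax}"]
    stance = list(df["stance_foot"]) if "stance_foot" in df.columns else []
    return PoseTrack(timestamps=df["timestamp"].to_numpy(),
                     positions=positions, stance=stance)


def write_foot_track_csv(track: FootTrack, path: str) -> None:
    pd.DataFrame({
        "timestamp": track.timestamps,
        "left_x": track.left[:, 0], "left_y": track.left[:, 1],
        "left_z": track.left[:, 2],
        "right_x": track.right[:, 0], "right_y": track.right[:, 1],
        "right_z": track.right[:, 2],
        "merged": track.merged.astype(int),
        "occluded": track.occluded.astype(int),
    }).to_csv(path, index=False, float_format="%.9g")


def write_session_index(rows: list[tuple], path: str) -> None:
    """CSV of (frame path, timestamp, sensor id)."""
    pd.DataFrame(rows, columns=["path", "timestamp", "sensor_id"]).to_csv(
        path, index=False)


def read_session_index(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"path", "timestamp", "sensor_id"} - set(df.columns)
    if missing:
        raise SchemaError(f"session index missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# config

@dataclass
class SessionConfig:
    """Paths + parameters for a tracking run, loaded from YAML."""

    reference_cloud: str | None = None
    frame_index: str | None = None
    imu_csv: str | None = None
    output_dir: str = "out"
    seed: int = 0
    height: float | None = None
    proportions: dict | None = None
    fusion: FusionConfig = field(default_factory=FusionConfig)
    extras: dict = field(default_factory=dict)


def load_config(path: str) -> SessionConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fusion_kw = raw.pop("fusion", {}) or {}
    known = {k: raw.pop(k) for k in list(raw)
             if k in ("reference_cloud", "frame_index", "imu_csv",
                      "output_dir", "seed", "height", "proportions")}
    cfg = SessionConfig(fusion=FusionConfig(**fusion_kw), extras=raw, **known)
    log.info("loaded config: %s (fusion=%s)", known, fusion_kw)
    return cfg


def save_config(cfg: SessionConfig, path: str) -> None:
    payload = {
        "reference_cloud": cfg.reference_cloud,
        "frame_index": cfg.frame_index,
        "imu_csv": cfg.imu_csv,
        "output_dir": cfg.output_dir,
        "seed": cfg.seed,
        "height": cfg.height,
        "proportions": cfg.proportions,
        "fusion": {k: getattr(cfg.fusion, k) for k in
                   ("drift_threshold", "blend", "stance_window", "imu_rate",
                    "lidar_rate", "correction_mode", "voxel_resolution",
                    "cluster_distance", "leg_cluster_distance", "leg_radius",
                    "n_particles", "process_noise", "likelihood_sigma")},
    }
    payload.update(cfg.extras)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# BVH export

def _bvh_children(skeleton: Skeleton):
    """Map proximal joint -> outgoing segments, in canonical order."""
    children = {}
    for seg in skeleton.segments:
        children.setdefault(seg.proximal, []).append(seg)
    return children


def _segment_parent(skeleton: Skeleton, seg):
    return skeleton.segment_into(seg.proximal)


def _local_rotations(track: PoseTrack, skeleton: Skeleton) -> np.ndarray:
    """(n, 15, 4) local rotations: parent-segment-relative world quats."""
    from .kinematics import IDENTITY
    if track.segment_orientations is not None:
        world = track.segment_orientations
    else:
        world = _orientations_from_positions(track, skeleton)
    n = len(track)
    local = np.empty_like(world)
    for j, seg in enumerate(skeleton.segments):
        parent = _segment_parent(skeleton, seg)
        if parent is None:
            parent_world = np.tile(IDENTITY, (n, 1))
        else:
            parent_world = world[:, SEGMENT_NAMES.index(parent.name)]
        local[:, j] = qmul(qinv(parent_world), world[:, j])
    return local


def _orientations_from_positions(track: PoseTrack,
                                 skeleton: Skeleton) -> np.ndarray:
    """Minimal rotations carrying each rest direction onto the observed bone."""
    from .skeleton import JOINT_INDEX
    n = len(track)
    world = np.empty((n, 15, 4))
    for j, seg in enumerate(skeleton.segments):
        vec = (track.positions[:, JOINT_INDEX[seg.distal]]
               - track.positions[:, JOINT_INDEX[seg.proximal]])
        vec = vec / np.maximum(np.linalg.norm(vec, axis=1, keepdims=True), 1e-12)
        rest = seg.rest_direction
        dots = np.clip(vec @ rest, -1.0, 1.0)
        axes = np.cross(np.broadcast_to(rest, vec.shape), vec)
        norms = np.linalg.norm(axes, axis=1, keepdims=True)
        fallback = np.array([1.0, 0.0, 0.0])
        if abs(rest[0]) > 0.9:
            fallback = np.array([0.0, 1.0, 0.0])
        axes = np.where(norms > 1e-9, axes / np.maximum(norms, 1e-12), fallback)
        angles = np.arccos(dots)
        world[:, j, 0] = np.cos(angles / 2)
        world[:, j, 1:] = axes * np.sin(angles / 2)[:, None]
    return world


def write_bvh(track: PoseTrack, skeleton: Skeleton, path: str) -> None:
    """Export a pose track as BVH.

    One BVH node per segment (its joint is the segment's proximal joint);
    node offsets are the parent segment's rest offset, channels are ZXY
    rotations, and the root carries the pelvis translation.  Re-parsing
    the file and running plain forward kinematics reproduces the joint
    positions.
    """
    from scipy.spatial.transform import Rotation

    if len(track) == 0:
        raise SchemaError("cannot export an empty track")
    children = _bvh_children(skeleton)
    lines: list[str] = []
    order: list = []   # segments in hierarchy order, for channel layout

    def emit(seg, depth: int) -> None:
        indent = "  " * depth
        parent = _segment_parent(skeleton, seg)
        if parent is None:
            offset = np.zeros(3)
        else:
            offset = parent.rest_direction * parent.length
        lines.append(f"{indent}JOINT {seg.name}")
        lines.append(f"{indent}{{")
        lines.append(f"{indent}  OFFSET {offset[0]:.6f} {offset[1]:.6f} {offset[2]:.6f}")
        lines.append(f"{indent}  CHANNELS 3 Zrotation Xrotation Yrotation")
        order.append(seg)
        kids = children.get(seg.distal, [])
        if kids:
            for kid in kids:
                emit(kid, depth + 1)
        else:
            end = seg.rest_direction * seg.length
            lines.append(f"{indent}  End Site")
            lines.append(f"{indent}  {{")
            lines.append(f"{indent}    OFFSET {end[0]:.6f} {end[1]:.6f} {end[2]:.6f}")
            lines.append(f"{indent}  }}")
        lines.append(f"{indent}}}")

    lines.append("HIERARCHY")
    lines.append("ROOT Pelvis")
    lines.append("{")
    lines.append("  OFFSET 0.000000 0.000000 0.000000")
    lines.append("  CHANNELS 6 Xposition Yposition Zposition "
                 "Zrotation Xrotation Yrotation")
    for seg in children["Pelvis"]:
        emit(seg, 1)
    lines.append("}")

    n = len(track)
    dt = (float(np.mean(np.diff(track.timestamps))) if n > 1 else 1.0 / 60.0)
    local = _local_rotations(track, skeleton)

    lines.append("MOTION")
    lines.append(f"Frames: {n}")
    lines.append(f"Frame Time: {dt:.8f}")
    from .skeleton import JOINT_INDEX
    for i in range(n):
        row = list(track.positions[i, JOINT_INDEX["Pelvis"]])
        row += [0.0, 0.0, 0.0]  # root rotation held at identity
        for seg in order:
            q = local[i, SEGMENT_NAMES.index(seg.name)]
            # scalar-last for scipy
            eul = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_euler(
                "ZXY", degrees=True)
            row += list(eul)
        lines.append(" ".join(f"{v:.6f}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
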