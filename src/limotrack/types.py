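"""Shared data containers used across the pipeline.

All coordinates are meters.  Kinematics runs in the world frame (+z up,
+x forward); ceiling-lidar height estimation runs in the L1 sensor frame
(+y pointing down toward the floor).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Valid variant tags for point-cloud frames.
CLOUD_VARIANTS = ("reference", "full_body", "user", "realtime", "leg")


@dataclass
class PointCloudFrame:
    """A timestamped set of 3D points from one (or both) lidars.

    ``origins`` optionally stores, per point, the position of the sensor
    that produced it (needed for range-to-axis compensation of thin
    limbs); it is carried through filtering operations.
    """

    points: np.ndarray           # (n, 3) float64
    timestamp: float = 0.0
    variant: str = "reference"
    frame: str = "world"         # "world" or "l1"
    sensor_id: str | None = None
    origins: np.ndarray | None = None  # (n, 3) or None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.variant not in CLOUD_VARIANTS:
            raise ValueError(f"unknown cloud variant {self.variant!r}")
        if self.origins is not None:
            self.origins = np.asarray(self.origins, dtype=np.float64).reshape(-1, 3)
            if len(self.origins) != len(self.points):
                raise ValueError("origins must match points in length")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_index, variant: str | None = None) -> "PointCloudFrame":
        """Return a copy restricted to a boolean mask / index array."""
        return PointCloudFrame(
            points=self.points[mask_or_index],
            timestamp=self.timestamp,
            variant=variant or self.variant,
            frame=self.frame,
            sensor_id=self.sensor_id,
            origins=None if self.origins is None else self.origins[mask_or_index],
        )


@dataclass
class QuaternionStream:
    """Per-segment unit-quaternion time series on a shared timestamp grid.

    ``quats`` has shape (n_frames, n_segments, 4), scalar-first
    (qw, qx, qy, qz).  ``base_offsets`` optionally carries an injected
    per-frame displacement of the dead-reckoned stance base (drift
    emulation); orientations are never touched by drift injection.
    """

    timestamps: np.ndarray        # (n,)
    segments: list[str]           # length n_segments
    quats: np.ndarray             # (n, n_segments, 4)
    rate: float = 60.0
    aligned: bool = False
    base_offsets: np.ndarray | None = None  # (n, 3) or None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.quats = np.asarray(self.quats, dtype=np.float64)
        if self.quats.shape != (len(self.timestamps), len(self.segments), 4):
            raise ValueError("quats shape must be (n_frames, n_segments, 4)")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    def index_of(self, segment: str) -> int:
        return self.segments.index(segment)

    def copy(self) -> "QuaternionStream":
        return QuaternionStream(
            timestamps=self.timestamps.copy(),
            segments=list(self.segments),
            quats=self.quats.copy(),
            rate=self.rate,
            aligned=self.aligned,
            base_offsets=None if self.base_offsets is None else self.base_offsets.copy(),
        )


@dataclass
class PoseFrame:
    """World-frame positions of all 16 joints at one instant."""

    positions: np.ndarray          # (16, 3)
    timestamp: float = 0.0
    stance_foot: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.shape != (16, 3):
            raise ValueError("PoseFrame needs exactly 16 joint positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("joint positions must be finite")

    def translated(self, t: np.ndarray) -> "PoseFrame":
        return PoseFrame(self.positions + np.asarray(t, dtype=np.float64),
                         timestamp=self.timestamp, stance_foot=self.stance_foot)


@dataclass
class PoseTrack:
    """Ordered pose frames plus optional per-frame segment orientations."""

    timestamps: np.ndarray          # (n,)
    positions: np.ndarray           # (n, 16, 3)
    stance: list[str | None] = field(default_factory=list)
    segment_orientations: np.ndarray | None = None  # (n, 15, 4)
    diagnostics: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.shape[1:] != (16, 3):
            raise ValueError("positions must have shape (n, 16, 3)")
        if len(self.timestamps) != len(self.positions):
            raise ValueError("timestamps and positions disagree in length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    def frame(self, i: int) -> PoseFrame:
        stance = self.stance[i] if self.stance else None
        return PoseFrame(self.positions[i], timestamp=self.timestamps[i],
                         stance_foot=stance)


@dataclass
class GroundTruthTrack:
    """Simulator output: the true motion every estimate is scored against."""

    timestamps: np.ndarray            # (n,)
    joints: np.ndarray                # (n, 16, 3)
    segment_orientations: np.ndarray  # (n, 15, 4) world-frame, scalar-first
    stance: list[str]                 # per-frame stance foot joint name
    height: float                     # body height Ah in meters

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.joints = np.asarray(self.joints, dtype=np.float64)
        self.segment_orientations = np.asarray(self.segment_orientations,
                                               dtype=np.float64)

    def __len__(self) -> int:
        return len(self.timestamps)

    def as_pose_track(self) -> PoseTrack:
        return PoseTrack(timestamps=self.timestamps, positions=self.joints,
                         stance=list(self.stance),
                         segment_orientations=self.segment_orientations)
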