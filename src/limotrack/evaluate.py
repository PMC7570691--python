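"""Accuracy metrics: per-joint position error, inter-segment angles, and
per-motion window summaries.

Position statistics are reported in centimeters; angles in degrees.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InvalidWindowError
from .skeleton import JOINT_NAMES
from .types import GroundTruthTrack, PoseTrack

M_TO_CM = 100.0


@dataclass
class ErrorReport:
    """Per-joint and per-frame position-error statistics (centimeters)."""

    joint_names: list[str]
    per_joint_mean: np.ndarray       # (16,) cm
    per_joint_sd: np.ndarray         # (16,) cm
    per_joint_se: np.ndarray         # (16,) cm, sd / sqrt(n)
    per_frame_mean: np.ndarray       # (n,) cm, averaged over joints
    errors: np.ndarray               # (n, 16) cm

    @property
    def overall_mean(self) -> float:
        return float(self.errors.mean())

    def to_dict(self) -> dict:
        return {
            "overall_mean_cm": self.overall_mean,
            "per_joint": {
                name: {"mean_cm": float(self.per_joint_mean[i]),
                       "sd_cm": float(self.per_joint_sd[i]),
                       "se_cm": float(self.per_joint_se[i])}
                for i, name in enumerate(self.joint_names)
            },
        }


def _truth_positions(truth, timestamps: np.ndarray,
                     tolerance: float) -> np.ndarray:
    """Truth joints resampled (linearly) onto the estimate's timestamps."""
    tt = truth.timestamps
    if len(tt) == len(timestamps) and np.allclose(tt, timestamps, atol=tolerance):
        return truth.joints if hasattr(truth, "joints") else truth.positions
    if timestamps[0] < tt[0] - tolerance or timestamps[-1] > tt[-1] + tolerance:
        raise AlignmentError("estimated track extends beyond the ground truth")
    src = truth.joints if hasattr(truth, "joints") else truth.positions
    flat = src.reshape(len(tt), -1)
    out = np.stack([np.interp(timestamps, tt, flat[:, c])
                    for c in range(flat.shape[1])], axis=1)
    return out.reshape(len(timestamps), 16, 3)


def joint_position_error(estimated: PoseTrack,
                         truth: GroundTruthTrack | PoseTrack,
                         tolerance: float = 1e-6) -> ErrorReport:
    """Euclidean per-joint error of an estimated track vs ground truth."""
    truth_pos = _truth_positions(truth, estimated.timestamps, tolerance)
    err_m = np.linalg.norm(estimated.positions - truth_pos, axis=2)  # (n, 16)
    err = err_m * M_TO_CM
    n = len(err)
    return ErrorReport(
        joint_names=list(JOINT_NAMES),
        per_joint_mean=err.mean(axis=0),
        per_joint_sd=err.std(axis=0, ddof=0),
        per_joint_se=err.std(axis=0, ddof=0) / np.sqrt(n),
        per_frame_mean=err.mean(axis=1),
        errors=err,
    )


def segment_angle(q1: np.ndarray, q2: np.ndarray, mode: str = "quaternion_dot",
                  v1=(0.0, 0.0, 1.0), v2=(0.0, 0.0, 1.0)) -> float:
    """Angle between two bone segments, in degrees.

    ``"quaternion_dot"`` (default) is the literal inverse cosine of the
    4-D quaternion dot product (absolute value taken, so both covers of a
    rotation give the same answer); it equals *half* the relative
    rotation angle.  ``"geometric"`` returns the angle between the two
    rotated bone direction vectors instead.
    """
    q1 = np.asarray(q1, dtype=np.float64)
    q2 = np.asarray(q2, dtype=np.float64)
    if mode == "quaternion_dot":
        d = abs(float(np.dot(q1, q2)))
        return float(np.degrees(np.arccos(np.clip(d, -1.0, 1.0))))
    if mode == "geometric":
        from .kinematics import rotate_bone_vector
        d1 = rotate_bone_vector(q1, np.asarray(v1, dtype=np.float64))
        d2 = rotate_bone_vector(q2, np.asarray(v2, dtype=np.float64))
        c = float(np.dot(d1, d2) / (np.linalg.norm(d1) * np.linalg.norm(d2)))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class WindowSummary:
    """Per-window statistics of the Euclidean joint errors (cm)."""

    windows: list[dict]
    average_sd: float
    average_mean_difference: float


def cross_window_average(values) -> float:
    """Unweighted average across windows (used for summary rows)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise InvalidWindowError("no windows to average")
    return float(values.mean())


def summarize_motion_windows(errors_cm: np.ndarray,
                             windows: list) -> WindowSummary:
    """Summarize per-joint errors over frame windows and joint subsets.

    ``windows`` is a list of ``(start, stop, joint_indices_or_None)``
    (half-open frame range; ``None`` selects all joints).  Mean
    difference is the mean Euclidean error over the observed joints and
    frames; the standard deviation is taken over the same set.
    """
    errors_cm = np.asarray(errors_cm, dtype=np.float64)
    rows = []
    for start, stop, joints in windows:
        if not (0 <= start < stop <= len(errors_cm)):
            raise InvalidWindowError(f"window ({start}, {stop}) out of range")
        sub = errors_cm[start:stop]
        if joints is not None:
            sub = sub[:, list(joints)]
        if sub.size == 0:
            raise InvalidWindowError("window selects no samples")
        rows.append({
            "start": start, "stop": stop,
            "joints": None if joints is None else list(joints),
            "mean_difference": float(sub.mean()),
            "standard_deviation": float(sub.std(ddof=0)),
        })
    return WindowSummary(
        windows=rows,
        average_sd=cross_window_average([r["standard_deviation"] for r in rows]),
        average_mean_difference=cross_window_average(
            [r["mean_difference"] for r in rows]),
    )
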