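"""16-joint / 15-segment kinematic tree parameterized by body height.

Segment lengths are expressed in *head units*: the body height divided by
7.5 (the classical artist's proportion).  The default proportion table is
a documented stand-in for published anthropometric tables and can be
overridden through the config file.

b-index map (derived segments take their orientation from a trunk sensor):

====  ============  =========  =======  ======
b     name          proximal   distal   sensed
====  ============  =========  =======  ======
b1    head          Torso      Head     yes (torso-top / neck IMU)
b2    r_upper_arm   RShoulder  RElbow   yes
b3    r_shoulder    Torso      RShoulder  no (from b1)
b4    l_shoulder    Torso      LShoulder  no (from b1)
b5    l_upper_arm   LShoulder  LElbow   yes
b6    r_forearm     RElbow     RWrist   yes
b7    upper_spine   Spine      Torso    no (from b1)
b8    l_forearm     LElbow     LWrist   yes
b9    lower_spine   Pelvis     Spine    yes (pelvis / sacrum IMU)
b10   r_hip         Pelvis     RHip     no (from b9)
b11   r_thigh       RHip       RKnee    yes
b12   r_shin        RKnee      RFoot    yes
b13   l_hip         Pelvis     LHip     no (from b9)
b14   l_thigh       LHip       LKnee    yes
b15   l_shin        LKnee      LFoot    yes
====  ============  =========  =======  ======
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InconsistentProportionsError, InvalidArgumentError
from .types import PoseFrame

#: Ratio of body height to head height.
HEAD_UNITS_PER_BODY = 7.5

JOINT_NAMES = [
    "Pelvis", "Spine", "Torso", "Head",
    "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist",
    "RHip", "RKnee", "RFoot",
    "LHip", "LKnee", "LFoot",
]
JOINT_INDEX = {name: i for i, name in enumerate(JOINT_NAMES)}

_UP = (0.0, 0.0, 1.0)
_DOWN = (0.0, 0.0, -1.0)
_LEFT = (0.0, 1.0, 0.0)
_RIGHT = (0.0, -1.0, 0.0)

# (b-index, name, proximal, distal, sensed, rest direction)
_SEGMENT_SPEC = [
    (1, "head", "Torso", "Head", True, _UP),
    (2, "r_upper_arm", "RShoulder", "RElbow", True, _DOWN),
    (3, "r_shoulder", "Torso", "RShoulder", False, _RIGHT),
    (4, "l_shoulder", "Torso", "LShoulder", False, _LEFT),
    (5, "l_upper_arm", "LShoulder", "LElbow", True, _DOWN),
    (6, "r_forearm", "RElbow", "RWrist", True, _DOWN),
    (7, "upper_spine", "Spine", "Torso", False, _UP),
    (8, "l_forearm", "LElbow", "LWrist", True, _DOWN),
    (9, "lower_spine", "Pelvis", "Spine", True, _UP),
    (10, "r_hip", "Pelvis", "RHip", False, _RIGHT),
    (11, "r_thigh", "RHip", "RKnee", True, _DOWN),
    (12, "r_shin", "RKnee", "RFoot", True, _DOWN),
    (13, "l_hip", "Pelvis", "LHip", False, _LEFT),
    (14, "l_thigh", "LHip", "LKnee", True, _DOWN),
    (15, "l_shin", "LKnee", "LFoot", True, _DOWN),
]

SEGMENT_NAMES = [s[1] for s in _SEGMENT_SPEC]
SENSED_SEGMENTS = [s[1] for s in _SEGMENT_SPEC if s[4]]
DERIVED_SEGMENTS = [s[1] for s in _SEGMENT_SPEC if not s[4]]

#: Orientation source for each derived segment (trunk sensors).
DERIVED_SOURCE = {
    "r_shoulder": "head",
    "l_shoulder": "head",
    "upper_spine": "head",
    "r_hip": "lower_spine",
    "l_hip": "lower_spine",
}

#: Default proportion table, lengths in head units.  "head_top" is the
#: crown offset above the Head joint (part of the height, not a segment).
DEFAULT_PROPORTIONS = {
    "head": 0.5,
    "upper_spine": 1.0,
    "lower_spine": 1.0,
    "r_shoulder": 0.75,
    "l_shoulder": 0.75,
    "r_upper_arm": 1.5,
    "l_upper_arm": 1.5,
    "r_forearm": 1.25,
    "l_forearm": 1.25,
    "r_hip": 0.5,
    "l_hip": 0.5,
    "r_thigh": 2.0,
    "l_thigh": 2.0,
    "r_shin": 2.0,
    "l_shin": 2.0,
    "head_top": 1.0,
}

# Vertical-chain entries (foot -> crown); hip offsets are purely lateral
# so they contribute zero vertical extent.
_VERTICAL_CHAIN = ("r_shin", "r_thigh", "lower_spine", "upper_spine",
                   "head", "head_top")
_VERTICAL_CHAIN_LEFT = ("l_shin", "l_thigh", "lower_spine", "upper_spine",
                        "head", "head_top")


@dataclass(frozen=True)
class Segment:
    b_index: int
    name: str
    proximal: str
    distal: str
    sensed: bool
    length: float                 # meters
    rest_direction: np.ndarray    # unit 3-vector, world frame, rest pose


@dataclass
class Skeleton:
    """Kinematic tree rooted at the pelvis with per-segment lengths."""

    actual_height: float          # Ah, meters
    head_unit: float              # Hh = Ah / 7.5, meters
    segments: list[Segment]
    head_top_offset: float        # crown above Head joint, meters
    proportions: dict = field(default_factory=dict, repr=False)

    @property
    def joints(self) -> list[str]:
        return list(JOINT_NAMES)

    def segment(self, name: str) -> Segment:
        return self._by_name[name]

    @property
    def _by_name(self) -> dict:
        return {s.name: s for s in self.segments}

    def segments_from(self, joint: str) -> list[Segment]:
        """Segments whose proximal joint is ``joint`` (tree children)."""
        return [s for s in self.segments if s.proximal == joint]

    def segment_into(self, joint: str) -> Segment | None:
        """The unique segment whose distal joint is ``joint``."""
        for s in self.segments:
            if s.distal == joint:
                return s
        return None

    def chain_to_pelvis(self, joint: str) -> list[Segment]:
        """Segments walked distal->proximal from ``joint`` up to the Pelvis."""
        chain = []
        current = joint
        while current != "Pelvis":
            seg = self.segment_into(current)
            if seg is None:
                raise InvalidArgumentError(f"joint {current!r} has no parent segment")
            chain.append(seg)
            current = seg.proximal
        return chain

    def to_json(self) -> str:
        payload = {
            "actual_height_m": self.actual_height,
            "head_unit_m": self.head_unit,
            "head_top_offset_m": self.head_top_offset,
            "joints": [{"name": n, "id": i} for i, n in enumerate(JOINT_NAMES)],
            "segments": [
                {
                    "id": f"b{s.b_index}",
                    "name": s.name,
                    "proximal": s.proximal,
                    "distal": s.distal,
                    "length_m": s.length,
                    "rest_direction": list(s.rest_direction),
                    "sensed": s.sensed,
                }
                for s in self.segments
            ],
        }
        return json.dumps(payload, indent=2)

    @staticmethod
    def from_json(text: str) -> "Skeleton":
        payload = json.loads(text)
        segments = [
            Segment(
                b_index=int(d["id"][1:]),
                name=d["name"],
                proximal=d["proximal"],
                distal=d["distal"],
                sensed=bool(d["sensed"]),
                length=float(d["length_m"]),
                rest_direction=np.asarray(d["rest_direction"], dtype=np.float64),
            )
            for d in payload["segments"]
        ]
        return Skeleton(
            actual_height=float(payload["actual_height_m"]),
            head_unit=float(payload["head_unit_m"]),
            segments=segments,
            head_top_offset=float(payload["head_top_offset_m"]),
        )


def _validate_proportions(table: dict) -> None:
    missing = set(DEFAULT_PROPORTIONS) - set(table)
    if missing:
        raise InvalidArgumentError(f"proportion table missing entries: {sorted(missing)}")
    for chain in (_VERTICAL_CHAIN, _VERTICAL_CHAIN_LEFT):
        total = sum(table[name] for name in chain)
        if abs(total - HEAD_UNITS_PER_BODY) > 1e-9:
            raise InconsistentProportionsError(
                f"vertical chain {chain} sums to {total}, expected {HEAD_UNITS_PER_BODY}")


def build_skeleton(actual_height: float, proportions: dict | None = None) -> Skeleton:
    """Construct a skeleton whose segment lengths scale with body height.

    Parameters
    ----------
    actual_height:
        Estimated body height Ah in meters (must be positive).
    proportions:
        Optional per-segment table in head units; the vertical chain must
        sum to 7.5.  Defaults to :data:`DEFAULT_PROPORTIONS`.
    """
    if not np.isfinite(actual_height) or actual_height <= 0:
        raise InvalidArgumentError(f"actual_height must be positive, got {actual_height}")
    table = dict(DEFAULT_PROPORTIONS if proportions is None else proportions)
    _validate_proportions(table)

    hh = actual_height / HEAD_UNITS_PER_BODY
    segments = [
        Segment(
            b_index=b,
            name=name,
            proximal=prox,
            distal=dist,
            sensed=sensed,
            length=table[name] * hh,
            rest_direction=np.asarray(direction, dtype=np.float64),
        )
        for b, name, prox, dist, sensed, direction in _SEGMENT_SPEC
    ]
    return Skeleton(
        actual_height=actual_height,
        head_unit=hh,
        segments=segments,
        head_top_offset=table["head_top"] * hh,
        proportions=table,
    )


def attention_pose(skeleton: Skeleton,
                   pelvis_position: np.ndarray = (0.0, 0.0, 0.0)) -> PoseFrame:
    """Joint positions of the upright calibration stance (arms down).

    The pelvis is placed at ``pelvis_position``; every other joint follows
    the rest-pose direction vectors.  With the pelvis at its natural
    standing height (4 head units) both feet land on the floor plane.
    """
    pelvis = np.asarray(pelvis_position, dtype=np.float64)
    positions = np.zeros((16, 3))
    positions[JOINT_INDEX["Pelvis"]] = pelvis

    # breadth-first from the pelvis; tree structure guarantees each distal
    # joint is set exactly once
    frontier = ["Pelvis"]
    while frontier:
        joint = frontier.pop()
        base = positions[JOINT_INDEX[joint]]
        for seg in skeleton.segments_from(joint):
            positions[JOINT_INDEX[seg.distal]] = base + seg.rest_direction * seg.length
            frontier.append(seg.distal)
    return PoseFrame(positions, timestamp=0.0)


def standing_pelvis_height(skeleton: Skeleton) -> float:
    """Pelvis height above the floor when standing (feet at z = 0)."""
    return (skeleton.segment("r_shin").length + skeleton.segment("r_thigh").length
            - skeleton.segment("r_hip").rest_direction[2] * skeleton.segment("r_hip").length)
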