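"""The twelve tracked limb joints and their COCO-17 keypoint indices.

The pipeline tracks bilateral shoulders, elbows, wrists, hips, knees and
ankles.  Face keypoints (COCO indices 0-4) are never ingested.  Eight of the
twelve joints carry an interior angle, defined by the joint itself and two
adjacent joints; wrists and ankles are distal endpoints only.
"""

from __future__ import annotations

from enum import Enum


class Joint(str, Enum):
    """One of the 12 tracked limb joints, named ``<side>_<segment>``."""

    LEFT_SHOULDER = "left_shoulder"
    RIGHT_SHOULDER = "right_shoulder"
    LEFT_ELBOW = "left_elbow"
    RIGHT_ELBOW = "right_elbow"
    LEFT_WRIST = "left_wrist"
    RIGHT_WRIST = "right_wrist"
    LEFT_HIP = "left_hip"
    RIGHT_HIP = "right_hip"
    LEFT_KNEE = "left_knee"
    RIGHT_KNEE = "right_knee"
    LEFT_ANKLE = "left_ankle"
    RIGHT_ANKLE = "right_ankle"

    @property
    def side(self) -> str:
        return self.value.split("_", 1)[0]

    @property
    def segment(self) -> str:
        return self.value.split("_", 1)[1]

    @property
    def mirror(self) -> "Joint":
        """The contralateral joint (left <-> right)."""
        other = "right" if self.side == "left" else "left"
        return Joint(f"{other}_{self.segment}")


#: COCO-17 keypoint index for each tracked joint (bijective on indices 5-16).
COCO_INDEX: dict[Joint, int] = {
    Joint.LEFT_SHOULDER: 5,
    Joint.RIGHT_SHOULDER: 6,
    Joint.LEFT_ELBOW: 7,
    Joint.RIGHT_ELBOW: 8,
    Joint.LEFT_WRIST: 9,
    Joint.RIGHT_WRIST: 10,
    Joint.LEFT_HIP: 11,
    Joint.RIGHT_HIP: 12,
    Joint.LEFT_KNEE: 13,
    Joint.RIGHT_KNEE: 14,
    Joint.LEFT_ANKLE: 15,
    Joint.RIGHT_ANKLE: 16,
}

#: Joints that carry an interior angle.
ANGLE_JOINTS: tuple[Joint, ...] = (
    Joint.RIGHT_SHOULDER,
    Joint.LEFT_SHOULDER,
    Joint.RIGHT_ELBOW,
    Joint.LEFT_ELBOW,
    Joint.RIGHT_HIP,
    Joint.LEFT_HIP,
    Joint.RIGHT_KNEE,
    Joint.LEFT_KNEE,
)

#: For each angle-bearing joint, the two adjacent joints whose rays define
#: its interior angle: shoulder = (contralateral shoulder, ipsilateral elbow);
#: elbow = (ipsilateral shoulder, ipsilateral wrist); hip = (contralateral
#: hip, ipsilateral knee); knee = (ipsilateral hip, ipsilateral ankle).
ANGLE_TRIPLES: dict[Joint, tuple[Joint, Joint]] = {
    Joint.RIGHT_SHOULDER: (Joint.LEFT_SHOULDER, Joint.RIGHT_ELBOW),
    Joint.LEFT_SHOULDER: (Joint.RIGHT_SHOULDER, Joint.LEFT_ELBOW),
    Joint.RIGHT_ELBOW: (Joint.RIGHT_SHOULDER, Joint.RIGHT_WRIST),
    Joint.LEFT_ELBOW: (Joint.LEFT_SHOULDER, Joint.LEFT_WRIST),
    Joint.RIGHT_HIP: (Joint.LEFT_HIP, Joint.RIGHT_KNEE),
    Joint.LEFT_HIP: (Joint.RIGHT_HIP, Joint.LEFT_KNEE),
    Joint.RIGHT_KNEE: (Joint.RIGHT_HIP, Joint.RIGHT_ANKLE),
    Joint.LEFT_KNEE: (Joint.LEFT_HIP, Joint.LEFT_ANKLE),
}

JOINTS: tuple[Joint, ...] = tuple(Joint)
JOINT_NAMES: tuple[str, ...] = tuple(j.value for j in Joint)
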