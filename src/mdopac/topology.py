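"""Canonical landmark topology.

The package uses the 33-keypoint whole-body layout emitted by common
on-device pose estimators (nose, eyes, ears, shoulders, elbows, wrists,
finger landmarks, hips, legs, feet). Coordinates are normalized to the
image (x, y in [0, 1]) with y increasing downward; "up" is decreasing y.
Adapting a different estimator means mapping its output onto these names.
"""

from __future__ import annotations

KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye_inner",
    "left_eye",
    "left_eye_outer",
    "right_eye_inner",
    "right_eye",
    "right_eye_outer",
    "left_ear",
    "right_ear",
    "mouth_left",
    "mouth_right",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_pinky",
    "right_pinky",
    "left_index",
    "right_index",
    "left_thumb",
    "right_thumb",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "left_heel",
    "right_heel",
    "left_foot_index",
    "right_foot_index",
)

KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(KEYPOINT_NAMES)}

VIEWS = ("frontal", "sagittal")
GENDERS = ("male", "female")
LEVELS = ("D2", "D3", "D4", "intern")
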