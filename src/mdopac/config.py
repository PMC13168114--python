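"""Thresholds and measurement configuration.

All angular tolerances (degrees) used by the measurement and rating layers
live here so that alternative deployments can override them from a YAML
file. The category boundaries printed on the assessment sheet (20/45 for
trunk and neck, 20 for upper-arm abduction, 60 for the forearm, 15 for the
wrist) are fixed properties of the instrument; the remaining tolerances
(how level is "level", how much abduction still counts as "parallel") are
not stated by the instrument and are documented assumptions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Union

import yaml


@dataclass
class Thresholds:
    """Angular tolerances and measurement conventions.

    Parameters
    ----------
    tau_hip
        Maximum hip-line tilt from horizontal (deg) still rated "level".
    tau_shoulder_level
        Maximum shoulder-line tilt from horizontal (deg) still rated level.
    tau_parallel
        Maximum upper-arm abduction (deg) still rated "parallel to torso".
    tau_slump
        Maximum forward-slump deviation (deg) of the ear-shoulder-hip
        chain still rated "relaxed" (20 deg corresponds to requiring the
        ear-shoulder-hip angle to stay above 160 deg).
    tau_elbow
        Maximum forearm inclination from horizontal (deg) rated
        "elbows at waist level".
    trunk_acceptable_max / trunk_harmful_min
        Trunk and neck band edges: <=20 acceptable, >=45 harmful.
    upper_arm_harmful_min
        Abduction at or beyond this (deg) is harmful.
    elbow_harmful_min
        Forearm inclination beyond this (deg) is harmful (exactly 60 is
        compromised).
    wrist_acceptable_max
        Wrist flexion/extension deviation (deg); <=15 acceptable.
    instrument_side
        Side holding the instrument; upper-arm abduction and the primary
        wrist are measured on this side.
    neck_reference
        "trunk": neck angles are measured against the trunk axis so trunk
        lean does not double-count; "vertical": against the image vertical.
    c_min
        Landmark confidence threshold for the occlusion exclusion policy
        (strict less-than; a landmark at exactly c_min is usable).
    """

    tau_hip: float = 5.0
    tau_shoulder_level: float = 5.0
    tau_parallel: float = 5.0
    tau_slump: float = 20.0
    tau_elbow: float = 15.0
    trunk_acceptable_max: float = 20.0
    trunk_harmful_min: float = 45.0
    upper_arm_harmful_min: float = 20.0
    elbow_harmful_min: float = 60.0
    wrist_acceptable_max: float = 15.0
    instrument_side: str = "right"
    neck_reference: str = "trunk"
    c_min: float = 0.5

    def __post_init__(self) -> None:
        if self.instrument_side not in ("left", "right"):
            raise ValueError(f"instrument_side must be left/right, got {self.instrument_side!r}")
        if self.neck_reference not in ("trunk", "vertical"):
            raise ValueError(f"neck_reference must be trunk/vertical, got {self.neck_reference!r}")
        if not 0.0 <= self.c_min <= 1.0:
            raise ValueError(f"c_min must be in [0,1], got {self.c_min}")

    @classmethod
    def from_yaml(cls, source: Union[str, Path, IO[str]]) -> "Thresholds":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            data = yaml.safe_load(Path(source).read_text())
        data = data or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path, None] = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


DEFAULT_THRESHOLDS = Thresholds()
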