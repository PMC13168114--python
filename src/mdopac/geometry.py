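"""Vector-geometric measurement of the ten postural components.

Each component of the assessment sheet is measured in exactly one viewing
plane from a small set of landmarks, as an absolute angular deviation in
degrees. The instrument itself names the components but not the landmark
triplets; the mapping implemented here is a declared reconstruction and
is therefore kept explicit, configurable and round-trip tested against
the synthetic skeleton generator.

Conventions: coordinates normalized to the image, y increases downward,
"up" is decreasing y. All angles are reported as non-negative deviations
so the rating layer is monotone in the measured value.

Component -> view / landmarks:

==================  ========  ====================================================
component           view      measurement
==================  ========  ====================================================
hip_level           frontal   tilt of left_hip-right_hip line from horizontal
trunk_fb            sagittal  inclination of mid_hip->mid_shoulder from vertical
trunk_ss            frontal   inclination of mid_hip->mid_shoulder from vertical
neck_front          sagittal  head-axis (mid_shoulder->ear) deviation from the
                              trunk axis: 180 - angle(mid_shoulder; mid_hip, ear)
neck_side           frontal   mid_shoulder->nose deviation from the trunk axis
shoulder_relaxed    sagittal  forward-slump deviation 180 - angle(shoulder; ear, hip)
shoulder_level      frontal   tilt of shoulder line from horizontal
upper_arm           frontal   abduction: angle(shoulder; elbow, hip), instrument side
elbow               sagittal  forearm (elbow->wrist) inclination from horizontal
wrist               frontal   180 - angle(wrist; elbow, index); worst measurable hand
==================  ========  ====================================================

Midpoints fall back to the single visible side's landmark (the sagittal
camera sees the operator's left side).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

from .config import Thresholds
from .pose_io import PoseRecord, SubjectCapture

_DEGENERATE_EPS = 1e-12


class DegenerateGeometryError(ValueError):
    """Coincident points make the requested angle undefined."""


class UnmeasurableComponentError(ValueError):
    """A required landmark is absent; drives the exclusion policy."""


class ComponentID(str, enum.Enum):
    """The ten postural components, in assessment-sheet order."""

    HIP_LEVEL = "hip_level"
    TRUNK_FB = "trunk_fb"
    TRUNK_SS = "trunk_ss"
    NECK_FRONT = "neck_front"
    NECK_SIDE = "neck_side"
    SHOULDER_RELAXED = "shoulder_relaxed"
    SHOULDER_LEVEL = "shoulder_level"
    UPPER_ARM = "upper_arm"
    ELBOW = "elbow"
    WRIST = "wrist"


#: Components that can score 3 points (harmful); the other four are capped at 2.
HARMFUL_CAPABLE = frozenset(
    {
        ComponentID.TRUNK_FB,
        ComponentID.TRUNK_SS,
        ComponentID.NECK_FRONT,
        ComponentID.NECK_SIDE,
        ComponentID.UPPER_ARM,
        ComponentID.ELBOW,
    }
)

COMPONENT_VIEW: dict[ComponentID, str] = {
    ComponentID.HIP_LEVEL: "frontal",
    ComponentID.TRUNK_FB: "sagittal",
    ComponentID.TRUNK_SS: "frontal",
    ComponentID.NECK_FRONT: "sagittal",
    ComponentID.NECK_SIDE: "frontal",
    ComponentID.SHOULDER_RELAXED: "sagittal",
    ComponentID.SHOULDER_LEVEL: "frontal",
    ComponentID.UPPER_ARM: "frontal",
    ComponentID.ELBOW: "sagittal",
    ComponentID.WRIST: "frontal",
}

Point = tuple[float, float]


@dataclass(frozen=True)
class AngleMeasurement:
    component: ComponentID
    value: float  # degrees, absolute deviation in [0, 180]
    landmarks_used: tuple[str, ...]
    view: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 180.0:
            raise ValueError(f"{self.component.value}: value {self.value} outside [0, 180]")
        if self.view != COMPONENT_VIEW[self.component]:
            raise ValueError(
                f"{self.component.value}: view {self.view!r} does not match "
                f"assigned view {COMPONENT_VIEW[self.component]!r}"
            )


def _vec(p: Point, q: Point) -> tuple[float, float]:
    return (q[0] - p[0], q[1] - p[1])


def _norm(v: tuple[float, float]) -> float:
    return math.hypot(v[0], v[1])


def angle_at(vertex: Point, a: Point, c: Point, names: Sequence[str] = ()) -> float:
    """Interior angle (degrees, in [0, 180]) at ``vertex`` between rays to a and c."""
    va, vc = _vec(vertex, a), _vec(vertex, c)
    na, nc = _norm(va), _norm(vc)
    if na <= _DEGENERATE_EPS or nc <= _DEGENERATE_EPS:
        raise DegenerateGeometryError(
            f"coincident points at angle vertex ({', '.join(names) or 'unnamed'})"
        )
    cosang = (va[0] * vc[0] + va[1] * vc[1]) / (na * nc)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def inclination_from_vertical(p: Point, q: Point, names: Sequence[str] = ()) -> float:
    """Absolute angle (degrees, [0, 90]) between segment p->q and the image vertical."""
    v = _vec(p, q)
    if _norm(v) <= _DEGENERATE_EPS:
        raise DegenerateGeometryError(
            f"degenerate segment ({', '.join(names) or 'unnamed'})"
        )
    return math.degrees(math.atan2(abs(v[0]), abs(v[1])))


def inclination_from_horizontal(p: Point, q: Point, names: Sequence[str] = ()) -> float:
    """Absolute angle (degrees, [0, 90]) between segment p->q and the image horizontal."""
    v = _vec(p, q)
    if _norm(v) <= _DEGENERATE_EPS:
        raise DegenerateGeometryError(
            f"degenerate segment ({', '.join(names) or 'unnamed'})"
        )
    return math.degrees(math.atan2(abs(v[1]), abs(v[0])))


def _angle_between(v1: tuple[float, float], v2: tuple[float, float]) -> float:
    n1, n2 = _norm(v1), _norm(v2)
    if n1 <= _DEGENERATE_EPS or n2 <= _DEGENERATE_EPS:
        raise DegenerateGeometryError("zero-length axis vector")
    cosang = (v1[0] * v2[0] + v1[1] * v2[1]) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _require(record: PoseRecord, component: ComponentID, *names: str) -> list[Point]:
    pts = []
    missing = []
    for n in names:
        lm = record.get(n)
        if lm is None:
            missing.append(n)
        else:
            pts.append(lm.xy)
    if missing:
        raise UnmeasurableComponentError(
            f"{record.subject_id}/{component.value}: missing landmarks {missing}"
        )
    return pts


def _mid(record: PoseRecord, left: str, right: str, component: ComponentID) -> tuple[Point, tuple[str, ...]]:
    """Midpoint of a left/right landmark pair, falling back to the visible side."""
    lms = [record.get(left), record.get(right)]
    present = [(n, lm) for n, lm in zip((left, right), lms) if lm is not None]
    if not present:
        raise UnmeasurableComponentError(
            f"{record.subject_id}/{component.value}: missing landmarks [{left}, {right}]"
        )
    xs = [lm.x for _, lm in present]
    ys = [lm.y for _, lm in present]
    return (sum(xs) / len(xs), sum(ys) / len(ys)), tuple(n for n, _ in present)


def required_landmark_map(thresholds: Thresholds = Thresholds()) -> dict[str, tuple[str, list[list[str]]]]:
    """Per component: viewing plane and alternative required landmark groups.

    Feeds :func:`mdopac.pose_io.apply_exclusion_policy`. The wrist offers
    two alternatives (either hand); trunk midpoints need only the sagittal
    camera's visible (left) side.
    """
    side = thresholds.instrument_side
    other = "left" if side == "right" else "right"
    return {
        ComponentID.HIP_LEVEL.value: ("frontal", [["left_hip", "right_hip"]]),
        ComponentID.TRUNK_FB.value: ("sagittal", [["left_hip", "left_shoulder"]]),
        ComponentID.TRUNK_SS.value: (
            "frontal",
            [["left_hip", "right_hip", "left_shoulder", "right_shoulder"]],
        ),
        ComponentID.NECK_FRONT.value: ("sagittal", [["left_hip", "left_shoulder", "left_ear"]]),
        ComponentID.NECK_SIDE.value: (
            "frontal",
            [["left_hip", "right_hip", "left_shoulder", "right_shoulder", "nose"]],
        ),
        ComponentID.SHOULDER_RELAXED.value: (
            "sagittal",
            [["left_shoulder", "left_ear", "left_hip"]],
        ),
        ComponentID.SHOULDER_LEVEL.value: ("frontal", [["left_shoulder", "right_shoulder"]]),
        ComponentID.UPPER_ARM.value: (
            "frontal",
            [[f"{side}_shoulder", f"{side}_elbow", f"{side}_hip"]],
        ),
        ComponentID.ELBOW.value: ("sagittal", [["left_elbow", "left_wrist"]]),
        ComponentID.WRIST.value: (
            "frontal",
            [
                [f"{side}_elbow", f"{side}_wrist", f"{side}_index"],
                [f"{other}_elbow", f"{other}_wrist", f"{other}_index"],
            ],
        ),
    }


def measure_component(
    capture: SubjectCapture,
    component: ComponentID,
    thresholds: Thresholds = Thresholds(),
) -> AngleMeasurement:
    """Measure one postural component on a capture (exclusion already applied)."""
    view = COMPONENT_VIEW[component]
    rec = capture.record(view)
    side = thresholds.instrument_side

    if component is ComponentID.HIP_LEVEL:
        (lh, rh) = _require(rec, component, "left_hip", "right_hip")
        value = inclination_from_horizontal(lh, rh, ("left_hip", "right_hip"))
        used: tuple[str, ...] = ("left_hip", "right_hip")

    elif component in (ComponentID.TRUNK_FB, ComponentID.TRUNK_SS):
        mh, used_h = _mid(rec, "left_hip", "right_hip", component)
        ms, used_s = _mid(rec, "left_shoulder", "right_shoulder", component)
        value = inclination_from_vertical(mh, ms, used_h + used_s)
        used = used_h + used_s

    elif component in (ComponentID.NECK_FRONT, ComponentID.NECK_SIDE):
        head_name = "left_ear" if component is ComponentID.NECK_FRONT else "nose"
        mh, used_h = _mid(rec, "left_hip", "right_hip", component)
        ms, used_s = _mid(rec, "left_shoulder", "right_shoulder", component)
        (head,) = _require(rec, component, head_name)
        head_axis = _vec(ms, head)
        if thresholds.neck_reference == "trunk":
            ref_axis = _vec(mh, ms)
        else:  # against image vertical, pointing up (decreasing y)
            ref_axis = (0.0, -1.0)
        value = _angle_between(head_axis, ref_axis)
        used = used_h + used_s + (head_name,)

    elif component is ComponentID.SHOULDER_RELAXED:
        (sh, ear, hip) = _require(rec, component, "left_shoulder", "left_ear", "left_hip")
        value = 180.0 - angle_at(sh, ear, hip, ("left_shoulder", "left_ear", "left_hip"))
        used = ("left_shoulder", "left_ear", "left_hip")

    elif component is ComponentID.SHOULDER_LEVEL:
        (ls, rs) = _require(rec, component, "left_shoulder", "right_shoulder")
        value = inclination_from_horizontal(ls, rs, ("left_shoulder", "right_shoulder"))
        used = ("left_shoulder", "right_shoulder")

    elif component is ComponentID.UPPER_ARM:
        names = (f"{side}_shoulder", f"{side}_elbow", f"{side}_hip")
        (sh, el, hip) = _require(rec, component, *names)
        value = angle_at(sh, el, hip, names)
        used = names

    elif component is ComponentID.ELBOW:
        (el, wr) = _require(rec, component, "left_elbow", "left_wrist")
        value = inclination_from_horizontal(el, wr, ("left_elbow", "left_wrist"))
        used = ("left_elbow", "left_wrist")

    elif component is ComponentID.WRIST:
        other = "left" if side == "right" else "right"
        best: tuple[float, tuple[str, ...]] | None = None
        for s in (side, other):
            names = (f"{s}_wrist", f"{s}_elbow", f"{s}_index")
            if all(rec.get(n) is not None for n in names):
                (wr, el, ix) = _require(rec, component, *names)
                dev = 180.0 - angle_at(wr, el, ix, names)
                if best is None or dev > best[0]:
                    best = (dev, names)
        if best is None:
            raise UnmeasurableComponentError(
                f"{rec.subject_id}/{component.value}: neither hand fully visible"
            )
        value, used = best

    else:  # pragma: no cover
        raise ValueError(f"unknown component {component!r}")

    return AngleMeasurement(component=component, value=value, landmarks_used=used, view=view)


def measure_all(
    capture: SubjectCapture, thresholds: Thresholds = Thresholds()
) -> dict[ComponentID, AngleMeasurement]:
    """Measure all ten components; raises on the first unmeasurable one."""
    return {c: measure_component(capture, c, thresholds) for c in ComponentID}
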