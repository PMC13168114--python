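"""Synthetic two-view skeletons and cohorts with known ground truth.

The study's raw photographs are not public, so every pipeline stage is
exercised against generated landmark captures whose component angles are
known exactly. The generator is the forward model inverse to the
measurement geometry: given a target angle per component it places
landmarks so that :func:`mdopac.geometry.measure_component` recovers each
angle to within 1e-6 degrees in the noise-free case.

Construction notes
------------------
Frontal view: the hip and shoulder lines are placed symmetric about the
body midline with the requested tilts, the trunk axis is leaned by the
side-to-side angle, the nose offset from the trunk axis by the neck-side
angle, and the instrument-side arm abducted from the shoulder-hip
direction; the hand (wrist->index) is deflected by the wrist angle, the
other hand kept straight so the "worst hand" rule recovers the target.

Sagittal view: the trunk midline and the ear fix trunk flexion and the
neck angle. Because the forward-slump proxy (ear-shoulder-hip alignment)
shares its triplet with the neck measurement when the left and midline
landmarks coincide, the generator emits far-side landmarks mirrored about
the midline (as a 2D pose estimator does) and solves a small offset of
the near-side shoulder/hip chain in closed form so the slump
deviation is hit exactly while midpoints — and hence the trunk and neck
measurements — are unchanged. Target combinations with no in-frame
solution raise :class:`FeasibilityError`.

Cohorts: per-subject component categories are sampled independently from
configurable per-group probability vectors; an angle is then drawn
uniformly within the category's band (harmful bands capped at 80 deg for
trunk/neck and 90 deg for the elbow to stay anatomically plausible). A
single global seed drives a per-subject derived stream, so cohorts are
reproducible under subsetting. Optional occlusion entries overwrite the
confidence of a component's required landmarks to emulate failed
detection.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .config import Thresholds
from .geometry import (
    ComponentID,
    HARMFUL_CAPABLE,
    required_landmark_map,
)
from .pose_io import Landmark, PoseRecord, SubjectCapture, write_pose
from .scoring import CATEGORIES

_MAX_SIDE_OFFSET = 0.2
_HARM_CAP_TRUNK_NECK = 80.0
_HARM_CAP_ELBOW = 90.0
_BINARY_CAP = 30.0
_SLUMP_CAP = 60.0
_WRIST_CAP = 60.0
_ABDUCTION_CAP = 60.0


class FeasibilityError(ValueError):
    """Requested angle combination admits no in-frame skeleton."""


@dataclass
class BodyScale:
    """Segment lengths and half-widths as fractions of image height."""

    trunk_len: float = 0.22
    neck_len: float = 0.11
    hip_halfwidth: float = 0.07
    shoulder_halfwidth: float = 0.09
    upper_arm_len: float = 0.16
    forearm_len: float = 0.13
    hand_len: float = 0.06
    frontal_anchor: tuple[float, float] = (0.5, 0.72)
    sagittal_anchor: tuple[float, float] = (0.42, 0.72)


@dataclass
class SkeletonSpec:
    """Target deviation (degrees) per component plus body proportions."""

    subject_id: str = "synthetic"
    angles: dict[ComponentID, float] = field(default_factory=dict)
    scale: BodyScale = field(default_factory=BodyScale)

    def __post_init__(self) -> None:
        for comp, ang in self.angles.items():
            if not 0.0 <= ang <= 180.0:
                raise ValueError(f"{comp.value}: target {ang} outside [0, 180]")

    @classmethod
    def ideal(cls, subject_id: str = "ideal") -> "SkeletonSpec":
        """All deviations zero: hips/shoulders level, trunk and neck upright."""
        return cls(subject_id=subject_id, angles={c: 0.0 for c in ComponentID})

    def angle(self, comp: ComponentID) -> float:
        return self.angles.get(comp, 0.0)


def _rot(v: tuple[float, float], deg: float) -> tuple[float, float]:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return (c * v[0] - s * v[1], s * v[0] + c * v[1])


def _unit(v: tuple[float, float]) -> tuple[float, float]:
    n = math.hypot(*v)
    return (v[0] / n, v[1] / n)


def _add(p, v, k=1.0):
    return (p[0] + k * v[0], p[1] + k * v[1])


def _angle_between(v1, v2) -> float:
    n1, n2 = math.hypot(*v1), math.hypot(*v2)
    cosang = (v1[0] * v2[0] + v1[1] * v2[1]) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _solve_side_offset(ms, mh, ear, slump_dev: float) -> tuple[float, float]:
    """Offset vector making angle(shoulder; ear, hip) = 180 - slump_dev.

    The near-side shoulder and hip are displaced by the same vector s*w
    from the midline points, so shoulder->hip stays parallel to the trunk
    axis while shoulder->ear rotates with the offset. Closed form: the
    shoulder->ear vector must lie along one of the two rays at the target
    angle from the trunk axis; writing ear - ms = t*d + s*w and solving
    the 2x2 linear system gives (t, s) for each candidate ray d and
    offset direction w (horizontal or vertical). The smallest valid
    in-frame offset wins.
    """
    A = (mh[0] - ms[0], mh[1] - ms[1])
    na = math.hypot(*A)
    ahat = (A[0] / na, A[1] / na)
    nhat = (-ahat[1], ahat[0])
    phi = math.radians(180.0 - slump_dev)
    e = (ear[0] - ms[0], ear[1] - ms[1])
    best: tuple[float, tuple[float, float]] | None = None
    for sign in (1.0, -1.0):
        d = (
            math.cos(phi) * ahat[0] + sign * math.sin(phi) * nhat[0],
            math.cos(phi) * ahat[1] + sign * math.sin(phi) * nhat[1],
        )
        for w in ((1.0, 0.0), (0.0, 1.0)):
            den = d[0] * w[1] - d[1] * w[0]
            if abs(den) < 1e-12:
                continue  # ray parallel to the offset direction
            t = (e[0] * w[1] - e[1] * w[0]) / den  # shoulder->ear length
            s = (d[0] * e[1] - d[1] * e[0]) / den
            if t > 1e-9 and abs(s) <= _MAX_SIDE_OFFSET:
                if best is None or abs(s) < abs(best[0]):
                    best = (s, w)
    if best is None:
        raise FeasibilityError(
            f"no in-frame shoulder offset achieves slump deviation {slump_dev:.2f} deg"
        )
    s, w = best
    return (s * w[0], s * w[1])


def _make_record(
    subject_id: str,
    view: str,
    points: dict[str, tuple[float, float]],
    rng: np.random.Generator | None,
    jitter: float,
) -> PoseRecord:
    landmarks = {}
    for name, (x, y) in points.items():
        if jitter > 0:
            if rng is None:
                raise ValueError("jitter requires an rng")
            x += float(rng.normal(0.0, jitter))
            y += float(rng.normal(0.0, jitter))
            x, y = min(1.0, max(0.0, x)), min(1.0, max(0.0, y))
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise FeasibilityError(
                f"{subject_id}/{view}: landmark {name!r} out of frame at ({x:.3f}, {y:.3f})"
            )
        landmarks[name] = Landmark(name=name, x=x, y=y, confidence=1.0)
    return PoseRecord(subject_id=subject_id, view=view, landmarks=landmarks)


def generate_skeleton(
    spec: SkeletonSpec,
    view: str,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
    thresholds: Thresholds = Thresholds(),
) -> PoseRecord:
    """Construct one view's landmark record realizing the spec's angles."""
    sc = spec.scale
    side = thresholds.instrument_side
    if view == "frontal":
        alpha = spec.angle(ComponentID.HIP_LEVEL)
        theta_ss = spec.angle(ComponentID.TRUNK_SS)
        beta = spec.angle(ComponentID.SHOULDER_LEVEL)
        theta_ns = spec.angle(ComponentID.NECK_SIDE)
        theta_ua = spec.angle(ComponentID.UPPER_ARM)
        theta_w = spec.angle(ComponentID.WRIST)

        mh = sc.frontal_anchor
        up = (math.sin(math.radians(theta_ss)), -math.cos(math.radians(theta_ss)))
        ms = _add(mh, up, sc.trunk_len)
        hip_dir = (math.cos(math.radians(alpha)), -math.sin(math.radians(alpha)))
        sho_dir = (math.cos(math.radians(beta)), -math.sin(math.radians(beta)))
        pts = {
            "left_hip": _add(mh, hip_dir, sc.hip_halfwidth),
            "right_hip": _add(mh, hip_dir, -sc.hip_halfwidth),
            "left_shoulder": _add(ms, sho_dir, sc.shoulder_halfwidth),
            "right_shoulder": _add(ms, sho_dir, -sc.shoulder_halfwidth),
        }
        if thresholds.neck_reference == "trunk":
            nose_dir = _rot(up, theta_ns)
        else:
            nose_dir = _rot((0.0, -1.0), theta_ns)
        pts["nose"] = _add(ms, nose_dir, sc.neck_len)
        for s in ("left", "right"):
            sh = pts[f"{s}_shoulder"]
            hp = pts[f"{s}_hip"]
            d_sh = _unit((hp[0] - sh[0], hp[1] - sh[1]))
            # rotate the arm laterally away from the midline
            outward = 1.0 if s == "right" else -1.0
            abd = theta_ua if s == side else 8.0
            wdev = theta_w if s == side else 0.0
            arm_dir = _rot(d_sh, outward * abd)
            elbow = _add(sh, arm_dir, sc.upper_arm_len)
            wrist = _add(elbow, arm_dir, sc.forearm_len)
            index = _add(wrist, _rot(arm_dir, outward * wdev), sc.hand_len)
            pts[f"{s}_elbow"] = elbow
            pts[f"{s}_wrist"] = wrist
            pts[f"{s}_index"] = index
        return _make_record(spec.subject_id, view, pts, rng, jitter)

    if view == "sagittal":
        theta_t = spec.angle(ComponentID.TRUNK_FB)
        theta_n = spec.angle(ComponentID.NECK_FRONT)
        slump = spec.angle(ComponentID.SHOULDER_RELAXED)
        theta_e = spec.angle(ComponentID.ELBOW)

        mh = sc.sagittal_anchor
        up = (math.sin(math.radians(theta_t)), -math.cos(math.radians(theta_t)))
        ms = _add(mh, up, sc.trunk_len)
        if thresholds.neck_reference == "trunk":
            ear_dir = _rot(up, theta_n)
        else:
            ear_dir = _rot((0.0, -1.0), theta_n)
        ear = _add(ms, ear_dir, sc.neck_len)
        off = _solve_side_offset(ms, mh, ear, slump)
        sl = _add(ms, off)
        hl = _add(mh, off)
        sr = _add(ms, off, -1.0)
        hr = _add(mh, off, -1.0)
        # upper arm hangs nearly vertical; the forearm carries the elbow angle
        ua_dir = (math.sin(math.radians(5.0)), math.cos(math.radians(5.0)))
        elbow = _add(sl, ua_dir, sc.upper_arm_len)
        fore_dir = (math.cos(math.radians(theta_e)), math.sin(math.radians(theta_e)))
        wrist = _add(elbow, fore_dir, sc.forearm_len)
        pts = {
            "left_hip": hl,
            "right_hip": hr,
            "left_shoulder": sl,
            "right_shoulder": sr,
            "left_ear": ear,
            "left_elbow": elbow,
            "left_wrist": wrist,
        }
        return _make_record(spec.subject_id, view, pts, rng, jitter)

    raise ValueError(f"view must be frontal/sagittal, got {view!r}")


def generate_capture(
    spec: SkeletonSpec,
    gender: str = "male",
    level: str = "D2",
    loupes: bool = False,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
    thresholds: Thresholds = Thresholds(),
) -> SubjectCapture:
    return SubjectCapture(
        subject_id=spec.subject_id,
        frontal=generate_skeleton(spec, "frontal", rng, jitter, thresholds),
        sagittal=generate_skeleton(spec, "sagittal", rng, jitter, thresholds),
        gender=gender,
        level=level,
        loupes=loupes,
    )


# ---------------------------------------------------------------------------
# cohorts

def category_bands(thresholds: Thresholds = Thresholds()) -> dict[ComponentID, dict[str, tuple[float, float]]]:
    """Feasible angle band (lo, hi) per component and category."""
    t = thresholds
    trunklike = {
        "acceptable": (0.0, t.trunk_acceptable_max),
        "compromised": (t.trunk_acceptable_max, t.trunk_harmful_min),
        "harmful": (t.trunk_harmful_min, _HARM_CAP_TRUNK_NECK),
    }
    return {
        ComponentID.HIP_LEVEL: {
            "acceptable": (0.0, t.tau_hip),
            "compromised": (t.tau_hip, _BINARY_CAP),
        },
        ComponentID.TRUNK_FB: dict(trunklike),
        ComponentID.TRUNK_SS: dict(trunklike),
        ComponentID.NECK_FRONT: dict(trunklike),
        ComponentID.NECK_SIDE: dict(trunklike),
        ComponentID.SHOULDER_RELAXED: {
            "acceptable": (0.0, t.tau_slump),
            "compromised": (t.tau_slump, _SLUMP_CAP),
        },
        ComponentID.SHOULDER_LEVEL: {
            "acceptable": (0.0, t.tau_shoulder_level),
            "compromised": (t.tau_shoulder_level, _BINARY_CAP),
        },
        ComponentID.UPPER_ARM: {
            "acceptable": (0.0, t.tau_parallel),
            "compromised": (t.tau_parallel, t.upper_arm_harmful_min),
            "harmful": (t.upper_arm_harmful_min, _ABDUCTION_CAP),
        },
        ComponentID.ELBOW: {
            "acceptable": (0.0, t.tau_elbow),
            "compromised": (t.tau_elbow, t.elbow_harmful_min),
            "harmful": (t.elbow_harmful_min, _HARM_CAP_ELBOW),
        },
        ComponentID.WRIST: {
            "acceptable": (0.0, t.wrist_acceptable_max),
            "compromised": (t.wrist_acceptable_max, _WRIST_CAP),
        },
    }


def sample_angle(
    component: ComponentID,
    category: str,
    rng: np.random.Generator,
    thresholds: Thresholds = Thresholds(),
    margin: float = 1e-3,
) -> float:
    """Uniform draw within the category's band, kept ``margin`` degrees
    clear of both edges so measurement noise below 1e-6 deg cannot flip
    the rating."""
    bands = category_bands(thresholds)[component]
    if category not in bands:
        raise ValueError(f"{component.value} has no {category!r} band")
    lo, hi = bands[category]
    lo = lo + margin if lo > 0 else 0.0
    hi = hi - margin
    return float(rng.uniform(lo, hi))


@dataclass
class CohortGroup:
    """One covariate cell: gender x level with a size and loupes wearers."""

    gender: str
    level: str
    n: int
    loupes_n: int = 0
    probs: dict[ComponentID, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0 or self.loupes_n < 0 or self.loupes_n > self.n:
            raise ValueError("invalid group sizes")
        for comp, p in self.probs.items():
            if abs(sum(p) - 1.0) > 1e-12:
                raise ValueError(f"{comp.value}: probabilities sum to {sum(p)}, not 1")
            if comp not in HARMFUL_CAPABLE and p[2] != 0.0:
                raise ValueError(f"{comp.value} cannot have harmful probability > 0")


@dataclass
class OcclusionSpec:
    """Overwrite the confidence of a component's required landmarks."""

    n_subjects: int
    component: ComponentID
    confidence: float
    subject_ids: list[str] | None = None


@dataclass
class SyntheticCohortConfig:
    groups: list[CohortGroup]
    occlusion: OcclusionSpec | None = None
    seed: int = 0
    jitter: float = 0.0
    thresholds: Thresholds = field(default_factory=Thresholds)
    margin: float = 1e-3


@dataclass
class CohortResult:
    captures: list[SubjectCapture]
    covariates: pd.DataFrame
    truth: pd.DataFrame  # subject_id, component, category, angle


_MAX_RESAMPLE = 100


def _generate_subject(
    sid: str,
    group: CohortGroup,
    loupes: bool,
    rng: np.random.Generator,
    cfg: SyntheticCohortConfig,
) -> tuple[SubjectCapture, dict[ComponentID, tuple[str, float]]]:
    cats: dict[ComponentID, str] = {}
    for comp in ComponentID:
        p = group.probs.get(comp, (1.0, 0.0, 0.0))
        cats[comp] = CATEGORIES[int(rng.choice(3, p=np.asarray(p) / np.sum(p)))]
    # rejection-sample angles within the fixed category bands until the
    # skeleton is geometrically realizable (categories are never changed)
    for _ in range(_MAX_RESAMPLE):
        angles = {
            comp: sample_angle(comp, cats[comp], rng, cfg.thresholds, cfg.margin)
            for comp in ComponentID
        }
        spec = SkeletonSpec(subject_id=sid, angles=angles)
        try:
            capture = generate_capture(
                spec, group.gender, group.level, loupes, rng, cfg.jitter, cfg.thresholds
            )
        except FeasibilityError:
            continue
        truth = {comp: (cats[comp], angles[comp]) for comp in ComponentID}
        return capture, truth
    raise FeasibilityError(
        f"{sid}: no realizable skeleton after {_MAX_RESAMPLE} draws for categories "
        f"{ {c.value: cats[c] for c in ComponentID} }"
    )


def _apply_occlusion(
    captures: list[SubjectCapture], occ: OcclusionSpec, cfg: SyntheticCohortConfig
) -> list[SubjectCapture]:
    ids = [c.subject_id for c in captures]
    if occ.subject_ids is not None:
        chosen = set(occ.subject_ids)
        missing = chosen - set(ids)
        if missing:
            raise ValueError(f"occlusion subject ids not in cohort: {sorted(missing)}")
    else:
        rng = np.random.default_rng([cfg.seed, 999_983])
        chosen = set(rng.choice(ids, size=occ.n_subjects, replace=False))
    req_map = required_landmark_map(cfg.thresholds)
    view, groups = req_map[occ.component.value]
    names = {n for g in groups for n in g}
    # only landmarks distinctive to this component lose confidence, so the
    # exclusion is attributed to it alone (e.g. an arm hugging the torso
    # hides the elbow while shoulders and hips stay detectable)
    protected = {
        n
        for comp, (v, gs) in req_map.items()
        if comp != occ.component.value and len(gs) == 1
        for n in gs[0]
    }
    distinctive = names - protected
    if distinctive:
        names = distinctive
    out = []
    for cap in captures:
        if cap.subject_id not in chosen:
            out.append(cap)
            continue
        rec = cap.record(view)
        new_lms = {
            name: dataclasses.replace(lm, confidence=occ.confidence)
            if name in names
            else lm
            for name, lm in rec.landmarks.items()
        }
        new_rec = dataclasses.replace(rec, landmarks=new_lms)
        out.append(
            dataclasses.replace(
                cap, **{view: new_rec}
            )
        )
    return out


def generate_cohort(cfg: SyntheticCohortConfig) -> CohortResult:
    """Generate captures, covariates and the ground-truth category table."""
    captures: list[SubjectCapture] = []
    truth_rows = []
    cov_rows = []
    idx = 0
    for group in cfg.groups:
        for k in range(group.n):
            sid = f"S{idx:03d}"
            rng = np.random.default_rng([cfg.seed, idx])
            loupes = k < group.loupes_n
            capture, truth = _generate_subject(sid, group, loupes, rng, cfg)
            captures.append(capture)
            cov_rows.append(
                {
                    "subject_id": sid,
                    "gender": group.gender,
                    "level": group.level,
                    "loupes": int(loupes),
                }
            )
            for comp, (cat, ang) in truth.items():
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "component": comp.value,
                        "category": cat,
                        "angle": ang,
                    }
                )
            idx += 1
    if cfg.occlusion is not None:
        captures = _apply_occlusion(captures, cfg.occlusion, cfg)
    return CohortResult(
        captures=captures,
        covariates=pd.DataFrame(cov_rows),
        truth=pd.DataFrame(truth_rows),
    )


def write_cohort(result: CohortResult, out_dir: Union[str, Path]) -> None:
    """Emit the landmark JSON schema, covariate CSV and truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cap in result.captures:
        write_pose(cap.frontal, out / f"{cap.subject_id}_frontal.json")
        write_pose(cap.sagittal, out / f"{cap.subject_id}_sagittal.json")
    result.covariates.to_csv(out / "covariates.csv", index=False)
    result.truth.to_csv(out / "truth.csv", index=False)


# ---------------------------------------------------------------------------
# study-like preset

#: Cohort-wide category probabilities for the components reported only as
#: marginals (acceptable, compromised, harmful). The upper-arm row's
#: published marginals cover 74 of 75 subjects; the missing subject is
#: assigned to harmful here (see docs/methods.md).
PRESET_MARGINALS: dict[ComponentID, tuple[float, float, float]] = {
    ComponentID.TRUNK_FB: (74 / 75, 1 / 75, 0.0),
    ComponentID.TRUNK_SS: (1.0, 0.0, 0.0),
    ComponentID.NECK_FRONT: (23 / 75, 36 / 75, 16 / 75),
    ComponentID.NECK_SIDE: (25 / 75, 44 / 75, 6 / 75),
    ComponentID.SHOULDER_RELAXED: (73 / 75, 2 / 75, 0.0),
    ComponentID.SHOULDER_LEVEL: (74 / 75, 1 / 75, 0.0),
    ComponentID.UPPER_ARM: (22 / 75, 52 / 75, 1 / 75),
    ComponentID.ELBOW: (37 / 75, 38 / 75, 0.0),
}

#: Level-specific acceptable/compromised splits for hip and wrist.
PRESET_HIP_BY_LEVEL: dict[str, tuple[float, float, float]] = {
    "D2": (2 / 18, 16 / 18, 0.0),
    "D3": (10 / 19, 9 / 19, 0.0),
    "D4": (5 / 18, 13 / 18, 0.0),
    "intern": (3 / 20, 17 / 20, 0.0),
}
PRESET_WRIST_BY_LEVEL: dict[str, tuple[float, float, float]] = {
    "D2": (9 / 18, 9 / 18, 0.0),
    "D3": (12 / 19, 7 / 19, 0.0),
    "D4": (2 / 18, 16 / 18, 0.0),
    "intern": (4 / 20, 16 / 20, 0.0),
}

# level -> (male n, female n); totals 18/19/18/20 by level and 36 M / 39 F
_PRESET_SIZES: dict[str, tuple[int, int]] = {
    "D2": (9, 9),
    "D3": (9, 10),
    "D4": (9, 9),
    "intern": (9, 11),
}
# five loupes wearers, fixed allocation
_PRESET_LOUPES: dict[tuple[str, str], int] = {
    ("intern", "male"): 2,
    ("intern", "female"): 1,
    ("D4", "male"): 1,
    ("D4", "female"): 1,
}


def _level_probs(level: str) -> dict[ComponentID, tuple[float, float, float]]:
    probs = dict(PRESET_MARGINALS)
    probs[ComponentID.HIP_LEVEL] = PRESET_HIP_BY_LEVEL[level]
    probs[ComponentID.WRIST] = PRESET_WRIST_BY_LEVEL[level]
    return probs


def preset_paper_cohort(seed: int = 0, n_occluded: int = 0) -> SyntheticCohortConfig:
    """Study-like cohort: 75 analyzable subjects (18/19/18/20 by level,
    36 male / 39 female, 5 loupes wearers) with per-level hip/wrist
    probabilities and cohort-wide marginals for the other components.

    With ``n_occluded`` > 0, that many extra subjects are appended and
    their upper-arm landmarks marked at confidence 0.1, emulating the
    seven occlusion exclusions upstream of the analyzed cohort.
    """
    groups = []
    total = 0
    for level, (n_m, n_f) in _PRESET_SIZES.items():
        probs = _level_probs(level)
        for gender, n in (("male", n_m), ("female", n_f)):
            groups.append(
                CohortGroup(
                    gender=gender,
                    level=level,
                    n=n,
                    loupes_n=_PRESET_LOUPES.get((level, gender), 0),
                    probs=probs,
                )
            )
            total += n
    occlusion = None
    if n_occluded > 0:
        extra_levels = ["D2", "D3", "D4", "intern"]
        extra_ids = []
        for i in range(n_occluded):
            level = extra_levels[i % 4]
            gender = "male" if i % 2 == 0 else "female"
            groups.append(
                CohortGroup(gender=gender, level=level, n=1, probs=_level_probs(level))
            )
            extra_ids.append(f"S{total + i:03d}")
        occlusion = OcclusionSpec(
            n_subjects=n_occluded,
            component=ComponentID.UPPER_ARM,
            confidence=0.1,
            subject_ids=extra_ids,
        )
    return SyntheticCohortConfig(groups=groups, occlusion=occlusion, seed=seed)


def uniform_preset(
    n_per_level: int, seed: int = 0
) -> SyntheticCohortConfig:
    """Equal-size level groups (gender split evenly) with the cohort-wide
    marginal probabilities for every component; used for scale runs."""
    marginal_hip = (20 / 75, 55 / 75, 0.0)
    marginal_wrist = (27 / 75, 48 / 75, 0.0)
    probs = dict(PRESET_MARGINALS)
    probs[ComponentID.HIP_LEVEL] = marginal_hip
    probs[ComponentID.WRIST] = marginal_wrist
    groups = []
    for level in ("D2", "D3", "D4", "intern"):
        n_m = n_per_level // 2
        groups.append(CohortGroup(gender="male", level=level, n=n_m, probs=probs))
        groups.append(
            CohortGroup(gender="female", level=level, n=n_per_level - n_m, probs=probs)
        )
    return SyntheticCohortConfig(groups=groups, seed=seed)
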