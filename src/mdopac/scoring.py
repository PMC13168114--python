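"""Rating and aggregation: the 10-component posture scorecard.

Each measured component is rated acceptable (1 point), compromised
(2 points) or harmful (3 points); only six components — trunk front/back,
trunk side/side, both neck angles, upper-arm abduction and the elbow —
can be rated harmful. Totals therefore range from 10 (ideal) to 26, with
the overall category acceptable at exactly 10, compromised for 11-20 and
harmful at 21 or above.

Band edges follow the printed assessment sheet: trunk/neck <=20 deg is
acceptable and >=45 deg harmful; wrist deviation <=15 deg is acceptable;
upper-arm abduction at or beyond 20 deg is harmful (the sheet leaves
exactly 20 deg unassigned between "<20" and ">20"; the conservative
reading is used); forearm inclination above 60 deg is harmful with
exactly 60 deg compromised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import math

import pandas as pd

from .config import Thresholds
from .geometry import (
    HARMFUL_CAPABLE,
    AngleMeasurement,
    ComponentID,
    measure_all,
)
from .pose_io import SubjectCapture

CATEGORIES = ("acceptable", "compromised", "harmful")
CATEGORY_POINTS = {"acceptable": 1, "compromised": 2, "harmful": 3}

MIN_TOTAL = 10
MAX_TOTAL = 26


@dataclass(frozen=True)
class ComponentRating:
    component: ComponentID
    category: str
    points: int
    measurement: AngleMeasurement | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if CATEGORY_POINTS[self.category] != self.points:
            raise ValueError(f"points {self.points} inconsistent with {self.category!r}")
        if self.category == "harmful" and self.component not in HARMFUL_CAPABLE:
            raise ValueError(f"{self.component.value} cannot be rated harmful")


@dataclass
class PostureScorecard:
    subject_id: str
    ratings: dict[ComponentID, ComponentRating]
    total: int
    overall: str

    def category(self, component: ComponentID) -> str:
        return self.ratings[component].category


def overall_category(total: int) -> str:
    if total == MIN_TOTAL:
        return "acceptable"
    if total <= 20:
        return "compromised"
    return "harmful"


def rate_component(
    m: AngleMeasurement, thresholds: Thresholds = Thresholds()
) -> ComponentRating:
    """Rate one measured component against its threshold bands."""
    if not math.isfinite(m.value) or m.value < 0:
        raise ValueError(f"{m.component.value}: non-finite or negative value {m.value}")
    t = thresholds
    c = m.component
    v = m.value
    if c in (ComponentID.TRUNK_FB, ComponentID.TRUNK_SS, ComponentID.NECK_FRONT, ComponentID.NECK_SIDE):
        if v <= t.trunk_acceptable_max:
            category = "acceptable"
        elif v < t.trunk_harmful_min:
            category = "compromised"
        else:
            category = "harmful"
    elif c is ComponentID.HIP_LEVEL:
        category = "acceptable" if v <= t.tau_hip else "compromised"
    elif c is ComponentID.SHOULDER_RELAXED:
        category = "acceptable" if v <= t.tau_slump else "compromised"
    elif c is ComponentID.SHOULDER_LEVEL:
        category = "acceptable" if v <= t.tau_shoulder_level else "compromised"
    elif c is ComponentID.UPPER_ARM:
        if v <= t.tau_parallel:
            category = "acceptable"
        elif v < t.upper_arm_harmful_min:
            category = "compromised"
        else:
            category = "harmful"
    elif c is ComponentID.ELBOW:
        if v <= t.tau_elbow:
            category = "acceptable"
        elif v <= t.elbow_harmful_min:
            category = "compromised"
        else:
            category = "harmful"
    elif c is ComponentID.WRIST:
        category = "acceptable" if v <= t.wrist_acceptable_max else "compromised"
    else:  # pragma: no cover
        raise ValueError(f"unknown component {c!r}")
    return ComponentRating(
        component=c, category=category, points=CATEGORY_POINTS[category], measurement=m
    )


def build_scorecard(
    ratings: Iterable[ComponentRating], subject_id: str
) -> PostureScorecard:
    """Aggregate exactly one rating per component into a scorecard."""
    by_component: dict[ComponentID, ComponentRating] = {}
    for r in ratings:
        if r.component in by_component:
            raise ValueError(f"duplicate rating for {r.component.value}")
        by_component[r.component] = r
    missing = set(ComponentID) - set(by_component)
    if missing:
        raise ValueError(f"missing ratings for {sorted(c.value for c in missing)}")
    total = sum(r.points for r in by_component.values())
    return PostureScorecard(
        subject_id=subject_id,
        ratings=by_component,
        total=total,
        overall=overall_category(total),
    )


def score_subject(
    capture: SubjectCapture, thresholds: Thresholds = Thresholds()
) -> PostureScorecard:
    measurements = measure_all(capture, thresholds)
    return build_scorecard(
        (rate_component(m, thresholds) for m in measurements.values()),
        capture.subject_id,
    )


@dataclass
class CohortSummary:
    """Per-component category counts plus total-score descriptives."""

    n: int
    category_counts: dict[ComponentID, dict[str, int]]
    total_mean: float
    total_sd: float
    total_min: int
    total_max: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in ComponentID:
            counts = self.category_counts[comp]
            for cat in CATEGORIES:
                n = counts.get(cat, 0)
                if n or cat != "harmful" or comp in HARMFUL_CAPABLE:
                    rows.append(
                        {
                            "component": comp.value,
                            "category": cat,
                            "n": n,
                            "percent": 100.0 * n / self.n if self.n else float("nan"),
                        }
                    )
        return pd.DataFrame(rows)


def score_cohort(
    captures: Sequence[SubjectCapture], thresholds: Thresholds = Thresholds()
) -> tuple[list[PostureScorecard], CohortSummary]:
    """Score every capture (exclusion already applied) and summarize.

    Summary counts sum to the cohort size for every component; totals are
    described by mean, SD (population SD of the observed totals), min, max.
    """
    scorecards = [score_subject(c, thresholds) for c in captures]
    counts = {
        comp: {cat: 0 for cat in CATEGORIES} for comp in ComponentID
    }
    for sc in scorecards:
        for comp, rating in sc.ratings.items():
            counts[comp][rating.category] += 1
    totals = [sc.total for sc in scorecards]
    n = len(totals)
    mean = sum(totals) / n if n else float("nan")
    sd = math.sqrt(sum((t - mean) ** 2 for t in totals) / n) if n else float("nan")
    summary = CohortSummary(
        n=n,
        category_counts=counts,
        total_mean=mean,
        total_sd=sd,
        total_min=min(totals) if totals else 0,
        total_max=max(totals) if totals else 0,
    )
    return scorecards, summary


def scorecards_to_frame(scorecards: Sequence[PostureScorecard]) -> pd.DataFrame:
    rows = []
    for sc in scorecards:
        row: dict[str, object] = {"subject_id": sc.subject_id}
        for comp in ComponentID:
            row[f"{comp.value}_category"] = sc.ratings[comp].category
            row[f"{comp.value}_points"] = sc.ratings[comp].points
        row["total"] = sc.total
        row["overall"] = sc.overall
        rows.append(row)
    return pd.DataFrame(rows)


def write_scorecards(
    scorecards: Sequence[PostureScorecard], path: Union[str, Path]
) -> None:
    scorecards_to_frame(scorecards).to_csv(path, index=False)


def read_scorecards(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "total", "overall"} | {
        f"{c.value}_category" for c in ComponentID
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scorecard CSV missing columns: {sorted(missing)}")
    return df
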