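"""Reading, writing and screening two-view landmark captures.

A capture is a pair of pose records (frontal + sagittal) for one subject,
joined to covariates (gender, academic level, loupes). The occlusion
policy mirrors clinical practice with 2D pose estimators: a subject whose
required landmarks for any postural component are missing or below a
confidence threshold cannot be scored on that component, and under the
strict policy the whole subject is excluded from analysis.

Landmark file schema (JSON, one file per subject per view)::

    {"subject_id": "S001", "view": "frontal", "width": 1920, "height": 1080,
     "landmarks": [{"name": "nose", "x": 0.51, "y": 0.22, "confidence": 0.98}, ...]}

Covariate CSV header: ``subject_id,gender,level,loupes`` with
gender in {male, female}, level in {D2, D3, D4, intern}, loupes in {0, 1}.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import pandas as pd

from .topology import GENDERS, KEYPOINT_INDEX, LEVELS, VIEWS

logger = logging.getLogger(__name__)

_BOUND_EPS = 1e-9


class PoseFileError(ValueError):
    """Malformed landmark file (bad JSON, missing field, bad value)."""


class SchemaError(PoseFileError):
    """Landmark file violates the canonical topology (unknown/duplicate name)."""


class CovariateError(ValueError):
    """Covariate row outside the enumerated levels."""


@dataclass(frozen=True)
class Landmark:
    name: str
    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if self.name not in KEYPOINT_INDEX:
            raise SchemaError(f"unknown keypoint name {self.name!r}")
        for attr in ("x", "y"):
            v = getattr(self, attr)
            if not -_BOUND_EPS <= v <= 1.0 + _BOUND_EPS:
                raise PoseFileError(f"landmark {self.name!r}: {attr}={v} outside [0,1]")
            object.__setattr__(self, attr, min(1.0, max(0.0, v)))
        if not 0.0 <= self.confidence <= 1.0:
            raise PoseFileError(
                f"landmark {self.name!r}: confidence={self.confidence} outside [0,1]"
            )

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class PoseRecord:
    subject_id: str
    view: str
    landmarks: dict[str, Landmark]
    width: int = 1
    height: int = 1
    source: str | None = None

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise PoseFileError(f"view must be one of {VIEWS}, got {self.view!r}")

    def get(self, name: str) -> Landmark | None:
        return self.landmarks.get(name)

    def confident(self, name: str, c_min: float) -> bool:
        """True when ``name`` is present with confidence >= c_min.

        An absent landmark is treated as confidence 0.
        """
        lm = self.landmarks.get(name)
        return lm is not None and lm.confidence >= c_min


@dataclass
class SubjectCapture:
    subject_id: str
    frontal: PoseRecord
    sagittal: PoseRecord
    gender: str
    level: str
    loupes: bool

    def __post_init__(self) -> None:
        for rec in (self.frontal, self.sagittal):
            if rec.subject_id != self.subject_id:
                raise ValueError(
                    f"record subject_id {rec.subject_id!r} != capture {self.subject_id!r}"
                )
        if self.frontal.view != "frontal" or self.sagittal.view != "sagittal":
            raise ValueError("capture views must be (frontal, sagittal)")
        if self.gender not in GENDERS:
            raise CovariateError(f"gender must be in {GENDERS}, got {self.gender!r}")
        if self.level not in LEVELS:
            raise CovariateError(f"level must be in {LEVELS}, got {self.level!r}")

    def record(self, view: str) -> PoseRecord:
        return self.frontal if view == "frontal" else self.sagittal


@dataclass
class ExclusionLog:
    subject_id: str
    component: str
    missing_landmarks: list[str]
    reason: str  # "low_confidence" or "absent"


def parse_pose_file(source: Union[str, Path, IO[str]]) -> PoseRecord:
    """Parse one landmark JSON file into a validated :class:`PoseRecord`."""
    name = getattr(source, "name", None) or str(source)
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PoseFileError(f"{name}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    for key in ("subject_id", "view", "landmarks"):
        if key not in data:
            raise PoseFileError(f"{name}: missing required field {key!r}")
    landmarks: dict[str, Landmark] = {}
    for i, entry in enumerate(data["landmarks"]):
        try:
            lm = Landmark(
                name=entry["name"],
                x=float(entry["x"]),
                y=float(entry["y"]),
                confidence=float(entry.get("confidence", 1.0)),
            )
        except KeyError as exc:
            raise PoseFileError(f"{name}: landmark #{i} missing field {exc}") from exc
        if lm.name in landmarks:
            raise SchemaError(f"{name}: duplicate landmark name {lm.name!r}")
        landmarks[lm.name] = lm
    return PoseRecord(
        subject_id=str(data["subject_id"]),
        view=data["view"],
        landmarks=landmarks,
        width=int(data.get("width", 1)),
        height=int(data.get("height", 1)),
        source=name,
    )


def serialize_pose(record: PoseRecord) -> str:
    """Canonical JSON serialization (landmarks in topology order).

    ``parse_pose_file`` followed by ``serialize_pose`` is the identity on
    canonical files.
    """
    ordered = sorted(record.landmarks.values(), key=lambda lm: KEYPOINT_INDEX[lm.name])
    obj = {
        "subject_id": record.subject_id,
        "view": record.view,
        "width": record.width,
        "height": record.height,
        "landmarks": [
            {"name": lm.name, "x": lm.x, "y": lm.y, "confidence": lm.confidence}
            for lm in ordered
        ],
    }
    return json.dumps(obj, indent=1)


def write_pose(record: PoseRecord, path: Union[str, Path]) -> None:
    Path(path).write_text(serialize_pose(record) + "\n")


def read_covariates(path: Union[str, Path, IO[str]]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "gender", "level", "loupes"}
    missing = required - set(df.columns)
    if missing:
        raise CovariateError(f"covariate CSV missing columns: {sorted(missing)}")
    bad_gender = set(df["gender"]) - set(GENDERS)
    if bad_gender:
        raise CovariateError(f"gender values outside {GENDERS}: {sorted(bad_gender)}")
    bad_level = set(df["level"]) - set(LEVELS)
    if bad_level:
        raise CovariateError(f"level values outside {LEVELS}: {sorted(bad_level)}")
    df["loupes"] = df["loupes"].astype(int).astype(bool)
    return df


def load_cohort(
    landmark_dir: Union[str, Path],
    covariates: Union[str, Path, pd.DataFrame],
) -> tuple[list[SubjectCapture], list[dict]]:
    """Join landmark files with the covariate table on subject_id.

    Landmark files are discovered as ``<subject_id>_<view>.json`` in
    ``landmark_dir``. Returns (captures, skipped): covariate rows without
    both views are reported in ``skipped`` (and logged), never silently
    dropped. Landmark files without a covariate row produce a warning.
    """
    landmark_dir = Path(landmark_dir)
    if isinstance(covariates, pd.DataFrame):
        cov = covariates
    else:
        cov = read_covariates(covariates)
    captures: list[SubjectCapture] = []
    skipped: list[dict] = []
    seen_files: set[Path] = set()
    for row in cov.itertuples(index=False):
        sid = row.subject_id
        paths = {v: landmark_dir / f"{sid}_{v}.json" for v in VIEWS}
        missing = [v for v, p in paths.items() if not p.exists()]
        if missing:
            logger.warning("subject %s: missing %s view file(s); skipped", sid, missing)
            skipped.append({"subject_id": sid, "missing_views": missing})
            continue
        records = {v: parse_pose_file(p) for v, p in paths.items()}
        seen_files.update(paths.values())
        captures.append(
            SubjectCapture(
                subject_id=sid,
                frontal=records["frontal"],
                sagittal=records["sagittal"],
                gender=row.gender,
                level=row.level,
                loupes=bool(row.loupes),
            )
        )
    for orphan in sorted(set(landmark_dir.glob("*.json")) - seen_files):
        logger.warning("orphan landmark file without covariate row: %s", orphan.name)
    return captures, skipped


RequiredMap = Mapping[str, tuple[str, Sequence[Sequence[str]]]]


def apply_exclusion_policy(
    captures: Iterable[SubjectCapture],
    required_map: RequiredMap,
    c_min: float = 0.5,
    policy: str = "strict",
) -> tuple[list[SubjectCapture], list[ExclusionLog]]:
    """Screen captures against the occlusion policy.

    ``required_map`` maps component id -> (view, alternative landmark
    groups); a component is measurable when at least one group has every
    landmark present with confidence >= ``c_min`` (strict less-than
    excludes; exactly c_min is kept). Under ``policy="strict"`` a subject
    failing ANY component is excluded entirely (whole-subject policy);
    under ``policy="partial"`` all subjects are kept and the logs mark the
    unmeasurable components so scoring can skip them.
    """
    if policy not in ("strict", "partial"):
        raise ValueError(f"policy must be strict/partial, got {policy!r}")
    kept: list[SubjectCapture] = []
    logs: list[ExclusionLog] = []
    for cap in captures:
        failures: list[ExclusionLog] = []
        for component, (view, groups) in required_map.items():
            record = cap.record(view)
            best_missing: list[str] | None = None
            for group in groups:
                missing = [n for n in group if not record.confident(n, c_min)]
                if not missing:
                    best_missing = None
                    break
                if best_missing is None or len(missing) < len(best_missing):
                    best_missing = missing
            if best_missing is not None:
                absent = [n for n in best_missing if record.get(n) is None]
                failures.append(
                    ExclusionLog(
                        subject_id=cap.subject_id,
                        component=component,
                        missing_landmarks=best_missing,
                        reason="absent" if absent else "low_confidence",
                    )
                )
        if failures:
            logs.extend(failures)
            for f in failures:
                logger.info(
                    "subject %s: component %s unmeasurable (%s: %s)",
                    f.subject_id, f.component, f.reason, ",".join(f.missing_landmarks),
                )
            if policy == "strict":
                continue
        kept.append(cap)
    return kept, logs


def write_exclusion_log(logs: Sequence[ExclusionLog], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "component": e.component,
                "missing_landmarks": ";".join(e.missing_landmarks),
                "reason": e.reason,
            }
            for e in logs
        ],
        columns=["subject_id", "component", "missing_landmarks", "reason"],
    )
    df.to_csv(path, index=False)
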