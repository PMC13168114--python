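"""Landmark file round-trips, cohort loading, and the occlusion policy."""

import dataclasses
import io
import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdopac import (
    SkeletonSpec,
    apply_exclusion_policy,
    generate_capture,
    generate_cohort,
    load_cohort,
    parse_pose_file,
    preset_paper_cohort,
    required_landmark_map,
    serialize_pose,
    write_cohort,
)
from mdopac.pose_io import PoseFileError, SchemaError, CovariateError, read_covariates


def _minimal_file(landmarks):
    return io.StringIO(
        json.dumps(
            {"subject_id": "S1", "view": "frontal", "width": 640, "height": 480,
             "landmarks": landmarks}
        )
    )


def test_parse_minimal_file():
    rec = parse_pose_file(
        _minimal_file(
            [
                {"name": n, "x": 0.5, "y": 0.5, "confidence": 0.9}
                for n in ("nose", "left_hip", "right_hip", "left_shoulder")
            ]
        )
    )
    assert len(rec.landmarks) == 4
    assert rec.view == "frontal"
    assert rec.landmarks["nose"].confidence == 0.9


@pytest.mark.parametrize(
    "landmarks,exc",
    [
        ([{"name": "nose", "x": 0.5, "y": 0.5}, {"name": "nose", "x": 0.4, "y": 0.4}], SchemaError),
        ([{"name": "third_eye", "x": 0.5, "y": 0.5}], SchemaError),
        ([{"name": "nose", "x": 1.5, "y": 0.5}], PoseFileError),
        ([{"name": "nose", "x": 0.5, "y": 0.5, "confidence": 2.0}], PoseFileError),
    ],
)
def test_parse_rejects_invalid(landmarks, exc):
    with pytest.raises(exc):
        parse_pose_file(_minimal_file(landmarks))


def test_malformed_json_names_line():
    with pytest.raises(PoseFileError, match="line"):
        parse_pose_file(io.StringIO('{"subject_id": "S1",\n  broken'))


def test_coordinates_clamped_only_within_tolerance():
    rec = parse_pose_file(_minimal_file([{"name": "nose", "x": 1.0 + 1e-10, "y": 0.5}]))
    assert rec.landmarks["nose"].x == 1.0


def test_serialize_parse_identity(ideal_capture):
    """parse followed by serialize is the identity on canonical files."""
    text = serialize_pose(ideal_capture.frontal)
    rec = parse_pose_file(io.StringIO(text))
    assert serialize_pose(rec) == text


def test_load_cohort_round_trip(tmp_path, paper_cohort_with_occlusion):
    """A written 82-subject synthetic cohort reloads to 82 captures."""
    write_cohort(paper_cohort_with_occlusion, tmp_path)
    captures, skipped = load_cohort(tmp_path, tmp_path / "covariates.csv")
    assert len(captures) == 82
    assert skipped == []
    by_id = {c.subject_id: c for c in captures}
    orig = {c.subject_id: c for c in paper_cohort_with_occlusion.captures}
    assert by_id.keys() == orig.keys()
    sid = next(iter(by_id))
    assert serialize_pose(by_id[sid].sagittal) == serialize_pose(orig[sid].sagittal)


def test_load_cohort_reports_missing_view(tmp_path, caplog):
    res = generate_cohort(preset_paper_cohort(seed=2))
    small = dataclasses.replace(
        res, captures=res.captures[:3], covariates=res.covariates.iloc[:3]
    )
    write_cohort(small, tmp_path)
    (tmp_path / "S001_sagittal.json").unlink()
    with caplog.at_level("WARNING"):
        captures, skipped = load_cohort(tmp_path, tmp_path / "covariates.csv")
    assert len(captures) == 2
    assert skipped == [{"subject_id": "S001", "missing_views": ["sagittal"]}]
    assert any("S001" in r.message for r in caplog.records)


def test_covariate_validation(tmp_path):
    p = tmp_path / "cov.csv"
    p.write_text("subject_id,gender,level,loupes\nS1,male,D7,0\n")
    with pytest.raises(CovariateError):
        read_covariates(p)


def test_exclusion_all_confident_kept(ideal_capture):
    kept, excluded = apply_exclusion_policy([ideal_capture], required_landmark_map())
    assert len(kept) == 1 and excluded == []


def test_exclusion_drops_occluded_subjects(paper_cohort_with_occlusion):
    """7 of 82 captures with low-confidence upper-arm landmarks are excluded,
    each with an upper_arm exclusion entry."""
    kept, excluded = apply_exclusion_policy(
        paper_cohort_with_occlusion.captures, required_landmark_map(), c_min=0.5
    )
    assert len(kept) == 75
    excluded_ids = {e.subject_id for e in excluded}
    assert len(excluded_ids) == 7
    assert {e.component for e in excluded} == {"upper_arm"}
    assert {e.reason for e in excluded} == {"low_confidence"}


def test_exclusion_boundary_confidence_kept(ideal_capture):
    """Confidence exactly c_min is kept: the cut is strict less-than."""
    rec = ideal_capture.frontal
    lms = {
        n: dataclasses.replace(lm, confidence=0.5) for n, lm in rec.landmarks.items()
    }
    cap = dataclasses.replace(
        ideal_capture, frontal=dataclasses.replace(rec, landmarks=lms)
    )
    kept, _ = apply_exclusion_policy([cap], required_landmark_map(), c_min=0.5)
    assert len(kept) == 1


def test_partial_policy_keeps_subjects(paper_cohort_with_occlusion):
    kept, excluded = apply_exclusion_policy(
        paper_cohort_with_occlusion.captures,
        required_landmark_map(),
        policy="partial",
    )
    assert len(kept) == 82
    assert len({e.subject_id for e in excluded}) == 7


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    c_lo=st.floats(0.0, 1.0),
    c_hi=st.floats(0.0, 1.0),
    confs=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
)
def test_exclusion_partitions_and_is_monotone(c_lo, c_hi, confs):
    """kept + excluded partition the input, and raising c_min never keeps more."""
    caps = []
    for i, conf in enumerate(confs):
        cap = generate_capture(SkeletonSpec.ideal(subject_id=f"P{i}"))
        rec = cap.frontal
        lms = {
            n: dataclasses.replace(lm, confidence=conf)
            for n, lm in rec.landmarks.items()
        }
        caps.append(
            dataclasses.replace(cap, frontal=dataclasses.replace(rec, landmarks=lms))
        )
    req = required_landmark_map()
    results = {}
    for c in (c_lo, c_hi):
        kept, excluded = apply_exclusion_policy(caps, req, c_min=c)
        assert len(kept) + len({e.subject_id for e in excluded}) == len(caps)
        results[c] = len(kept)
    lo, hi = min(c_lo, c_hi), max(c_lo, c_hi)
    assert results[hi] <= results[lo]
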