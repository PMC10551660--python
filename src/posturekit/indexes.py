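"""Computation of the seven static postural indexes from landmark geometry.

All indexes are camera-frame quantities computed from 3D anatomical
landmarks in the canonical frame (X horizontal, Y up, Z depth; mm):

* ``uneven_shoulders`` — angle between the horizontal plane and the
  right->left acromion line: alpha = arcsin(|n . V| / (|n||V|)) with
  n = (0, 1, 0) the horizontal-plane normal.
* ``lateral_pelvic_tilt`` — the same angle over the iliac crest pair.
* ``scapula_inclination`` — the same angle over the scapula inferior
  angle (SIA) pair.
* ``forward_head`` — straight-line earlobe-to-acromion distance along the
  sagittal axis, d = |X_ear - X_acr|, reported in cm. In a left-lateral
  photograph the camera X axis is the subject's sagittal axis.
* ``pelvic_tilt`` (sagittal) — inclination of the PSIS->ASIS line against
  the horizontal, projected to the lateral X-Y plane; anterior tilt when
  the ASIS sits below the PSIS.
* ``knee_alignment`` — per leg, the signed frontal-plane angle between the
  patella->malleolus line and straight down; positive when the malleolus
  deviates medially (varus / O-leg), negative laterally (valgus / X-leg);
  the two legs are averaged.
* ``scoliosis`` — over the posterior spinal chain C7 -> upper/mid/lower
  T-spine -> L1, the largest frontal-plane angle between a consecutive
  segment and the vertical.

Indexes are translation-invariant; angles are scale-invariant while
``forward_head`` scales with the landmarks. They are *not* invariant to
yaw (rotation about the vertical axis): frontal-plane projections assume
the subject squarely faces (or backs) the camera, as posture photography
requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import grading as _grading
from .errors import MissingLandmarkError, PostureError, UndefinedAngleError
from .grading import INDEX_UNITS, GradingRubric
from .joints import VIEWS
from .skeleton import (
    LandmarkSet,
    RawKinectFrame,
    SkeletonFrame,
    average_frames,
    landmarks_from_skeleton,
    merge_landmarks,
    to_canonical,
)

INDEX_VIEW: dict[str, str] = {
    "uneven_shoulders": "anterior",
    "lateral_pelvic_tilt": "anterior",
    "knee_alignment": "anterior",
    "forward_head": "lateral",
    "pelvic_tilt": "lateral",
    "scoliosis": "posterior",
    "scapula_inclination": "posterior",
}

REQUIRED_LANDMARKS: dict[str, tuple[str, ...]] = {
    "uneven_shoulders": ("RIGHT_ACROMION", "LEFT_ACROMION"),
    "lateral_pelvic_tilt": ("RIGHT_ILIAC_CREST", "LEFT_ILIAC_CREST"),
    "knee_alignment": (
        "LEFT_PATELLA",
        "LEFT_MALLEOLUS",
        "RIGHT_PATELLA",
        "RIGHT_MALLEOLUS",
    ),
    "forward_head": ("EARLOBE", "ACROMION"),
    "pelvic_tilt": ("ASIS", "PSIS"),
    "scoliosis": ("C7", "UPPER_T_SPINE", "MID_T_SPINE", "LOWER_T_SPINE", "L1"),
    "scapula_inclination": ("RIGHT_SIA", "LEFT_SIA"),
}

SPINE_CHAIN = ("C7", "UPPER_T_SPINE", "MID_T_SPINE", "LOWER_T_SPINE", "L1")


@dataclass(frozen=True)
class IndexResult:
    """One computed postural index: value, units, laterality, severity."""

    index_name: str
    value: float
    unit: str
    direction: str | None = None
    grade: str | None = None
    grade_tag: str | None = None


@dataclass(frozen=True)
class EvaluationReport:
    """Per-subject assessment: graded indexes plus provenance."""

    subject_id: str
    results: tuple[IndexResult, ...]
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [r.index_name for r in self.results]
        if len(names) != len(set(names)):
            raise PostureError("duplicate index in report")

    def result(self, index_name: str) -> IndexResult:
        for r in self.results:
            if r.index_name == index_name:
                return r
        raise KeyError(index_name)


def angle_to_horizontal(
    p_right: np.ndarray, p_left: np.ndarray
) -> tuple[float, str]:
    """Angle (deg) between the horizontal plane and the right->left line.

    alpha = arcsin(|n . V| / (|n| |V|)) with n = (0, 1, 0) and
    V = p_left - p_right. Direction is ``left_high`` / ``right_high`` /
    ``level`` from the sign of the vertical component.
    """
    v = np.asarray(p_left, dtype=float) - np.asarray(p_right, dtype=float)
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise UndefinedAngleError("coincident points: angle undefined")
    alpha = math.degrees(math.asin(min(1.0, abs(v[1]) / norm)))
    if v[1] > 0:
        direction = "left_high"
    elif v[1] < 0:
        direction = "right_high"
    else:
        direction = "level"
    return alpha, direction


def _require(landmarks: LandmarkSet, index_name: str) -> None:
    for lm in REQUIRED_LANDMARKS[index_name]:
        if lm not in landmarks:
            raise MissingLandmarkError(
                f"index {index_name!r} requires landmark {lm!r} "
                f"({landmarks.view} view)"
            )


def _leg_angle(patella: np.ndarray, malleolus: np.ndarray, side: str) -> float:
    """Signed frontal-plane shank angle; positive = malleolus medial (varus)."""
    v = np.asarray(malleolus, float) - np.asarray(patella, float)
    if v[0] == 0 and v[1] == 0:
        raise UndefinedAngleError("coincident patella and malleolus")
    # Subject's left is +X in the anterior view, so medial is -X for the
    # left leg and +X for the right leg.
    medial_x = -v[0] if side == "left" else v[0]
    return math.degrees(math.atan2(medial_x, -v[1]))


def compute_index(
    index_name: str,
    landmarks: LandmarkSet,
    rubric: GradingRubric | None = None,
) -> IndexResult:
    """Compute one postural index from a landmark set.

    Raises :class:`MissingLandmarkError` naming the index and the absent
    landmark. When ``rubric`` is given the result is graded.
    """
    if index_name not in INDEX_VIEW:
        raise PostureError(f"unknown index {index_name!r}")
    _require(landmarks, index_name)
    unit = INDEX_UNITS[index_name]

    if index_name in ("uneven_shoulders", "lateral_pelvic_tilt", "scapula_inclination"):
        right, left = REQUIRED_LANDMARKS[index_name]
        value, direction = angle_to_horizontal(landmarks[right], landmarks[left])
    elif index_name == "forward_head":
        d_mm = abs(float(landmarks["EARLOBE"][0]) - float(landmarks["ACROMION"][0]))
        value, direction = d_mm / 10.0, None
    elif index_name == "pelvic_tilt":
        v = landmarks["ASIS"] - landmarks["PSIS"]
        if v[0] == 0 and v[1] == 0:
            raise UndefinedAngleError("ASIS and PSIS coincide in the sagittal plane")
        value = math.degrees(math.atan2(abs(v[1]), abs(v[0])))
        direction = "anterior" if v[1] < 0 else ("posterior" if v[1] > 0 else "level")
    elif index_name == "knee_alignment":
        left = _leg_angle(landmarks["LEFT_PATELLA"], landmarks["LEFT_MALLEOLUS"], "left")
        right = _leg_angle(
            landmarks["RIGHT_PATELLA"], landmarks["RIGHT_MALLEOLUS"], "right"
        )
        value = (left + right) / 2.0
        direction = "O" if value > 0 else ("X" if value < 0 else None)
    elif index_name == "scoliosis":
        best, best_dx = 0.0, 0.0
        for upper, lower in zip(SPINE_CHAIN, SPINE_CHAIN[1:]):
            d = landmarks[upper] - landmarks[lower]
            if d[0] == 0 and d[1] == 0:
                raise UndefinedAngleError(
                    f"coincident spinal landmarks {upper}/{lower}"
                )
            ang = math.degrees(math.atan2(abs(d[0]), abs(d[1])))
            if ang > best:
                best, best_dx = ang, float(d[0])
        value = best
        # Posterior photograph mirrors laterality: camera +X is the
        # subject's right side.
        if best_dx < 0:
            direction = "convex_left"
        elif best_dx > 0:
            direction = "convex_right"
        else:
            direction = None

    result = IndexResult(index_name=index_name, value=value, unit=unit,
                         direction=direction)
    if rubric is not None:
        g, tag = rubric.grade(index_name, value)
        result = replace(result, grade=g, grade_tag=tag)
    return result


FrameSeq = Sequence[RawKinectFrame | SkeletonFrame]


def _canonical_seq(frames: FrameSeq) -> list[SkeletonFrame]:
    return [
        to_canonical(f) if isinstance(f, RawKinectFrame) else f for f in frames
    ]


def assess(
    frames_by_view: dict[str, FrameSeq],
    file_landmarks: dict[str, LandmarkSet] | None = None,
    window: int = 10,
    rubric: GradingRubric | None = None,
    subject_id: str = "subject",
) -> EvaluationReport:
    """Run the full per-view pipeline and return a graded report.

    Per view: average the first ``window`` frames, derive the skeleton
    landmarks, merge any file landmarks (file wins), then compute and grade
    every index whose landmarks are present. Indexes that cannot be
    computed are listed in ``skipped`` with the reason. A view may also be
    supplied as file landmarks alone, with no frames.
    """
    file_landmarks = file_landmarks or {}
    if not frames_by_view and not file_landmarks:
        raise PostureError("no views supplied: nothing to assess")
    rubric = rubric or _grading.default_rubric()

    merged: dict[str, LandmarkSet] = {}
    provenance: dict = {"window": window, "rubric_version": rubric.version,
                        "frames": {}}
    for view in VIEWS:
        frames = frames_by_view.get(view)
        file_set = file_landmarks.get(view)
        if frames is None and file_set is None:
            continue
        if frames:
            canon = _canonical_seq(list(frames))
            mean = average_frames(canon, window=window)
            base = landmarks_from_skeleton(mean, view)
            provenance["frames"][view] = len(canon)
        else:
            base = LandmarkSet(view=view, points={}, source={})
            provenance["frames"][view] = 0
        merged[view] = merge_landmarks(base, file_set)

    results: list[IndexResult] = []
    skipped: dict[str, str] = {}
    for index_name, view in INDEX_VIEW.items():
        if view not in merged:
            skipped[index_name] = f"view {view!r} not provided"
            continue
        try:
            results.append(compute_index(index_name, merged[view], rubric=rubric))
        except MissingLandmarkError as exc:
            skipped[index_name] = str(exc)
    return EvaluationReport(
        subject_id=subject_id,
        results=tuple(results),
        skipped=skipped,
        provenance=provenance,
    )


__all__ = [
    "INDEX_VIEW",
    "REQUIRED_LANDMARKS",
    "SPINE_CHAIN",
    "IndexResult",
    "EvaluationReport",
    "angle_to_horizontal",
    "compute_index",
    "assess",
]
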