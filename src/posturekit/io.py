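"""Readers and writers: capture JSON, landmark CSV, rubric, reports.

Capture files follow the offline body-tracking processor dialect: a
top-level ``frames`` array, each frame with a ``timestamp_usec`` and a
``bodies`` array whose entries carry ``joint_positions`` in millimetres
(camera frame, Y down) either as an array of [x, y, z] triplets in SDK
joint order or as an object keyed by joint name. Optional
``confidence_levels`` entries (ints 0-3 or names none/low/medium/high)
are read and logged but not used to weight anything.

Reports are written byte-stably: keys sorted, floats fixed to three
decimals (1 um, far below sensor noise), so identical inputs produce
identical bytes.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np

from .errors import (
    CaptureParseError,
    DuplicateLandmarkError,
    EmptyCaptureError,
    PostureError,
    UnknownLandmarkError,
)
from .grading import INDEX_UNITS
from .indexes import EvaluationReport, IndexResult
from .joints import CONFIDENCE_LEVELS, JOINT_NAMES, LANDMARKS_BY_VIEW, N_JOINTS, VIEWS
from .skeleton import LandmarkSet, RawKinectFrame

logger = logging.getLogger(__name__)

_CONF_BY_INT = dict(enumerate(CONFIDENCE_LEVELS))
_CONF_RANK = {name: i for i, name in enumerate(CONFIDENCE_LEVELS)}


def _parse_confidence(raw, frame_index: int) -> dict[str, str]:
    if raw is None:
        return {name: "medium" for name in JOINT_NAMES}
    if isinstance(raw, dict):
        items = [(name, raw.get(name, "medium")) for name in JOINT_NAMES]
    else:
        if len(raw) != N_JOINTS:
            raise CaptureParseError(
                f"expected {N_JOINTS} confidence levels, got {len(raw)}", frame_index
            )
        items = list(zip(JOINT_NAMES, raw))
    out = {}
    for name, level in items:
        if isinstance(level, (int, float)):
            level = _CONF_BY_INT.get(int(level))
        if level not in CONFIDENCE_LEVELS:
            raise CaptureParseError(
                f"invalid confidence level for {name}: {level!r}", frame_index
            )
        out[name] = level
    return out


def _parse_positions(raw, frame_index: int) -> dict[str, np.ndarray]:
    if isinstance(raw, dict):
        missing = [n for n in JOINT_NAMES if n not in raw]
        if missing:
            raise CaptureParseError(
                f"joint_positions missing joints: {', '.join(missing)}", frame_index
            )
        pairs = [(n, raw[n]) for n in JOINT_NAMES]
    else:
        if len(raw) != N_JOINTS:
            raise CaptureParseError(
                f"expected {N_JOINTS} joint positions, got {len(raw)}", frame_index
            )
        pairs = list(zip(JOINT_NAMES, raw))
    out = {}
    for name, xyz in pairs:
        try:
            p = np.array([float(v) for v in xyz], dtype=float)
        except (TypeError, ValueError) as exc:
            raise CaptureParseError(
                f"malformed position for joint {name}: {xyz!r}", frame_index
            ) from exc
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise CaptureParseError(
                f"malformed position for joint {name}: {xyz!r}", frame_index
            )
        out[name] = p
    return out


def read_kinect_json(path: str | Path) -> list[RawKinectFrame]:
    """Read a body-tracking capture file into raw camera-frame frames.

    Frames are returned in timestamp order. A frame with several tracked
    bodies contributes the body with the highest mean joint confidence
    (logged). Frames with no bodies are skipped (logged); a capture in
    which *no* frame has a body raises :class:`EmptyCaptureError`.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise CaptureParseError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "frames" not in doc:
        raise CaptureParseError(f"{path}: expected a top-level 'frames' array")

    frames: list[RawKinectFrame] = []
    n_skipped = 0
    for i, fr in enumerate(doc["frames"]):
        bodies = fr.get("bodies", [])
        if not bodies:
            n_skipped += 1
            continue
        parsed = []
        for body in bodies:
            if "joint_positions" not in body:
                raise CaptureParseError("body without joint_positions", i)
            conf = _parse_confidence(body.get("confidence_levels"), i)
            pos = _parse_positions(body["joint_positions"], i)
            parsed.append((pos, conf))
        if len(parsed) > 1:
            scores = [
                np.mean([_CONF_RANK[c] for c in conf.values()]) for _, conf in parsed
            ]
            pick = int(np.argmax(scores))
            logger.info(
                "frame %d: %d bodies; keeping body %d (highest mean confidence)",
                i, len(parsed), pick,
            )
        else:
            pick = 0
        pos, conf = parsed[pick]
        try:
            ts = int(fr.get("timestamp_usec", fr.get("timestamp", 0)))
        except (TypeError, ValueError) as exc:
            raise CaptureParseError(f"bad timestamp: {fr.get('timestamp_usec')!r}", i) from exc
        frames.append(RawKinectFrame(timestamp_usec=ts, joints=pos, confidence=conf))
    if not frames:
        raise EmptyCaptureError(f"{path}: no frame contains a tracked body")
    if n_skipped:
        logger.warning("%s: skipped %d frame(s) with no tracked body", path, n_skipped)
    frames.sort(key=lambda f: f.timestamp_usec)
    return frames


def write_kinect_json(frames: list[RawKinectFrame], path: str | Path) -> None:
    """Write raw frames in the capture dialect read by :func:`read_kinect_json`."""
    doc = {
        "frames_count": len(frames),
        "frames": [
            {
                "timestamp_usec": f.timestamp_usec,
                "num_bodies": 1,
                "bodies": [
                    {
                        "body_id": 0,
                        "joint_positions": [
                            [float(v) for v in f.joints[n]] for n in JOINT_NAMES
                        ],
                        "confidence_levels": [
                            _CONF_RANK[f.confidence.get(n, "medium")]
                            for n in JOINT_NAMES
                        ],
                    }
                ],
            }
            for f in frames
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)
        fh.write("\n")


def read_landmarks_table(path: str | Path, view: str) -> LandmarkSet:
    """Read a ``landmark,x_mm,y_mm,z_mm`` CSV for one view.

    Only landmarks valid for the requested view are accepted; an unknown
    name or a duplicate row raises, naming the offender. Positions are in
    the canonical (Y-up) frame.
    """
    if view not in VIEWS:
        raise PostureError(f"unknown view {view!r}; expected one of {VIEWS}")
    vocab = set(LANDMARKS_BY_VIEW[view])
    points: dict[str, np.ndarray] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"landmark", "x_mm", "y_mm", "z_mm"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise PostureError(
                f"{path}: landmark CSV must have columns landmark,x_mm,y_mm,z_mm"
            )
        for row_no, row in enumerate(reader, start=2):
            name = row["landmark"].strip().upper()
            if name not in vocab:
                raise UnknownLandmarkError(
                    f"{path} line {row_no}: {name!r} is not a {view}-view landmark"
                )
            if name in points:
                raise DuplicateLandmarkError(
                    f"{path} line {row_no}: duplicate landmark {name!r}"
                )
            try:
                points[name] = np.array(
                    [float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])]
                )
            except ValueError as exc:
                raise PostureError(
                    f"{path} line {row_no}: malformed coordinates for {name}"
                ) from exc
    return LandmarkSet(view=view, points=points, source={n: "file" for n in points})


def write_landmarks_table(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set to the CSV layout read by read_landmarks_table."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["landmark", "x_mm", "y_mm", "z_mm"])
        for name in sorted(landmarks.points):
            p = landmarks.points[name]
            writer.writerow([name] + [f"{v:.3f}" for v in p])


def _fmt(v: float) -> float:
    return float(f"{v:.3f}")


def _report_payload(report: EvaluationReport) -> dict:
    return {
        "subject_id": report.subject_id,
        "results": [
            {
                "index": r.index_name,
                "value": _fmt(r.value),
                "unit": r.unit,
                "direction": r.direction,
                "grade": r.grade,
                "grade_tag": r.grade_tag,
            }
            for r in report.results
        ],
        "skipped": report.skipped,
        "provenance": report.provenance,
    }


def write_report(
    report: EvaluationReport, path: str | Path, format: str = "json"
) -> None:
    """Write an evaluation report as JSON or CSV.

    Output is byte-stable for identical input: sorted keys and fixed
    3-decimal float formatting.
    """
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_report_payload(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["subject_id", "index", "value", "unit", "direction", "grade",
                 "grade_tag"]
            )
            for r in report.results:
                writer.writerow(
                    [
                        report.subject_id,
                        r.index_name,
                        f"{r.value:.3f}",
                        r.unit,
                        r.direction or "",
                        r.grade or "",
                        r.grade_tag or "",
                    ]
                )
    else:
        raise PostureError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> EvaluationReport:
    """Read a JSON evaluation report back into an EvaluationReport."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        results = tuple(
            IndexResult(
                index_name=r["index"],
                value=float(r["value"]),
                unit=r.get("unit", INDEX_UNITS.get(r["index"], "deg")),
                direction=r.get("direction"),
                grade=r.get("grade"),
                grade_tag=r.get("grade_tag"),
            )
            for r in doc["results"]
        )
        return EvaluationReport(
            subject_id=doc["subject_id"],
            results=results,
            skipped=dict(doc.get("skipped", {})),
            provenance=dict(doc.get("provenance", {})),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise PostureError(f"{path}: malformed report: {exc}") from exc


__all__ = [
    "read_kinect_json",
    "write_kinect_json",
    "read_landmarks_table",
    "write_landmarks_table",
    "write_report",
    "read_report",
]
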