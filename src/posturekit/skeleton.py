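"""Skeleton containers, canonical frame, averaging, landmark derivation.

Coordinate conventions
----------------------
The depth camera reports joint positions in a camera frame whose Y axis
points *down*. All geometry in this package is done in a canonical
right-handed frame:

* X — camera horizontal (the subject's left is +X in an anterior view),
* Y — vertical, up,
* Z — depth, away from the camera.

``to_canonical`` performs the Y flip; everything downstream assumes it.
All lengths are millimetres.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MissingJointError, PostureError
from .joints import (
    JOINT_NAMES,
    LANDMARKS_BY_VIEW,
    SKELETON_LANDMARK_SOURCES,
    VIEWS,
)

logger = logging.getLogger(__name__)

Point = np.ndarray  # shape (3,), float64, mm


@dataclass(frozen=True)
class RawKinectFrame:
    """One body-tracking frame as read from a capture file (camera frame, Y down)."""

    timestamp_usec: int
    joints: dict[str, Point]
    confidence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        missing = [n for n in JOINT_NAMES if n not in self.joints]
        if missing:
            raise MissingJointError(f"frame missing joints: {', '.join(missing)}")
        for name, p in self.joints.items():
            if not np.all(np.isfinite(p)):
                raise PostureError(f"non-finite position for joint {name}")


@dataclass(frozen=True)
class SkeletonFrame:
    """One frame in the canonical (Y-up) frame, all 32 joints present."""

    timestamp_usec: int
    joints: dict[str, Point]

    def positions(self) -> np.ndarray:
        """Joint positions as a (32, 3) array in SDK joint order."""
        return np.array([self.joints[n] for n in JOINT_NAMES], dtype=float)


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical points for one view.

    ``source`` records, per landmark, whether the point was derived from the
    tracked skeleton or supplied from a landmark table ("skeleton" / "file").
    """

    view: str
    points: dict[str, Point]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.view not in VIEWS:
            raise PostureError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        vocab = LANDMARKS_BY_VIEW[self.view]
        for name, p in self.points.items():
            if name not in vocab:
                raise PostureError(
                    f"landmark {name!r} is not valid for the {self.view} view"
                )
            if not np.all(np.isfinite(p)):
                raise PostureError(f"non-finite position for landmark {name}")

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> Point:
        return self.points[name]


def to_canonical(frame: RawKinectFrame) -> SkeletonFrame:
    """Convert a camera-frame (Y-down) frame into the canonical Y-up frame.

    An isometry: (x, y, z) -> (x, -y, z). Applying the Y flip twice restores
    the original coordinates.
    """
    joints = {
        name: np.array([p[0], -p[1], p[2]], dtype=float)
        for name, p in frame.joints.items()
    }
    return SkeletonFrame(timestamp_usec=frame.timestamp_usec, joints=joints)


def average_frames(
    frames: list[SkeletonFrame], window: int = 10, offset: int = 0
) -> SkeletonFrame:
    """Coordinate-wise mean of ``window`` consecutive frames.

    Single-frame skeleton data is noisy, so index computation uses the mean
    of ten frames by default. ``offset`` selects which run of frames is
    averaged (0 = the first ten).
    """
    if window < 1:
        raise PostureError(f"window must be >= 1, got {window}")
    if len(frames) < offset + window:
        raise PostureError(
            f"need at least {offset + window} frames to average "
            f"(window={window}, offset={offset}); got {len(frames)}"
        )
    chunk = frames[offset : offset + window]
    stack = np.stack([f.positions() for f in chunk])  # (window, 32, 3)
    mean = stack.mean(axis=0)
    ts = int(round(np.mean([f.timestamp_usec for f in chunk])))
    return SkeletonFrame(
        timestamp_usec=ts,
        joints={name: mean[i] for i, name in enumerate(JOINT_NAMES)},
    )


def landmarks_from_skeleton(frame: SkeletonFrame, view: str) -> LandmarkSet:
    """Derive the automatically identifiable landmarks for ``view``.

    Anterior landmarks alias limb joints (acromion <- shoulder, iliac crest
    <- hip, patella <- knee, malleolus <- ankle); the lateral earlobe and
    acromion alias the left ear and shoulder. Posterior spinal landmarks
    cannot be located from the tracked skeleton and are never invented here —
    they must be supplied from a landmark table.
    """
    if view not in VIEWS:
        raise PostureError(f"unknown view {view!r}; expected one of {VIEWS}")
    sources = SKELETON_LANDMARK_SOURCES[view]
    points = {lm: frame.joints[j].copy() for lm, j in sources.items()}
    return LandmarkSet(
        view=view, points=points, source={lm: "skeleton" for lm in points}
    )


def merge_landmarks(base: LandmarkSet, override: LandmarkSet | None) -> LandmarkSet:
    """Merge two landmark sets for the same view; ``override`` (file) wins."""
    if override is None:
        return base
    if base.view != override.view:
        raise PostureError(
            f"cannot merge landmark sets from views {base.view!r} and {override.view!r}"
        )
    points = dict(base.points)
    source = dict(base.source)
    points.update(override.points)
    source.update(override.source or {lm: "file" for lm in override.points})
    return LandmarkSet(view=base.view, points=points, source=source)


def map_reference_markers(
    markers: dict[str, Point], mapping: dict[str, list[str]]
) -> dict[str, Point]:
    """Map reference-system (optical mocap) markers onto skeleton joints.

    Each joint takes the position of its single mapped marker, or the
    centroid when several markers are listed. Raises if any mapped marker is
    absent from ``markers``.
    """
    missing = sorted(
        {m for names in mapping.values() for m in names if m not in markers}
    )
    if missing:
        raise PostureError(f"markers absent from input: {', '.join(missing)}")
    out: dict[str, Point] = {}
    for joint, names in mapping.items():
        pts = np.array([markers[m] for m in names], dtype=float)
        out[joint] = pts.mean(axis=0)
    return out


def load_marker_mapping(path: str | Path) -> dict[str, list[str]]:
    """Read a joint -> [marker, ...] mapping table from JSON."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise PostureError("marker mapping must be a JSON object")
    mapping: dict[str, list[str]] = {}
    for joint, names in raw.items():
        if joint not in JOINT_NAMES:
            raise PostureError(f"unknown joint in marker mapping: {joint!r}")
        if isinstance(names, str):
            names = [names]
        if not names:
            raise PostureError(f"empty marker list for joint {joint}")
        mapping[joint] = [str(n) for n in names]
    return mapping


def frame_from_markers(
    markers: dict[str, Point],
    mapping: dict[str, list[str]],
    timestamp_usec: int = 0,
) -> SkeletonFrame:
    """Build a canonical SkeletonFrame from an optical marker cloud."""
    joints = map_reference_markers(markers, mapping)
    missing = [n for n in JOINT_NAMES if n not in joints]
    if missing:
        raise MissingJointError(
            f"marker mapping does not cover joints: {', '.join(missing)}"
        )
    return SkeletonFrame(timestamp_usec=timestamp_usec, joints=joints)


__all__ = [
    "RawKinectFrame",
    "SkeletonFrame",
    "LandmarkSet",
    "to_canonical",
    "average_frames",
    "landmarks_from_skeleton",
    "merge_landmarks",
    "map_reference_markers",
    "load_marker_mapping",
    "frame_from_markers",
]
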