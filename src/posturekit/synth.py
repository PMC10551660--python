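"""Synthetic standing-figurine generator with injectable postural deviations.

Emulates the validation setup of a depth-camera posture system: a rigid
human-sized figurine (stature 183 cm, shoulder width 47 cm) standing still
in front of the camera, captured at 30 Hz, with mm-scale Gaussian jitter on
every tracked joint. Each of the seven postural deviations is injected as
an exact rigid transform of the relevant landmark pair, so in the
noise-free limit every index recovers its injected value exactly —
the generator's core contract.

Geometry lives in a body-centred frame (X = subject's left, Y = up,
Z = subject's posterior) and is mapped into the canonical camera frame per
photographed view:

* anterior:   subject faces the camera; (x, y, z) -> (x, y, D + z)
* lateral:    subject's left side faces the camera; (x, y, z) -> (-z, y, D - x)
* posterior:  subject faces away; (x, y, z) -> (-x, y, D - z)

with D the camera distance. Joint placement uses simple anthropometric
fractions of stature; the indexes depend only on relative landmark
geometry, so the exact fractions are non-critical (documented constants).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import grading as _grading
from .agreement import (
    AgreementReport,
    IndexAgreement,
    PairedSeries,
    accuracy,
    cohens_d,
    confusion,
    icc_2_2,
    index_error,
    kappa,
)
from .errors import ImplausiblePoseError, PostureError
from .grading import GRADES, INDEX_NAMES, GradingRubric
from .joints import JOINT_NAMES, VIEWS
from .skeleton import (
    LandmarkSet,
    RawKinectFrame,
    SkeletonFrame,
    landmarks_from_skeleton,
    merge_landmarks,
)

FRAME_INTERVAL_USEC = 33_333  # 30 Hz capture

DEVIATION_FIELDS = (
    "shoulder_tilt_deg",
    "pelvic_obliquity_deg",
    "knee_alignment_deg",
    "head_forward_cm",
    "pelvic_tilt_deg",
    "scoliosis_deg",
    "scapula_tilt_deg",
)

# deviation field -> index it drives
DEVIATION_INDEX = {
    "shoulder_tilt_deg": "uneven_shoulders",
    "pelvic_obliquity_deg": "lateral_pelvic_tilt",
    "knee_alignment_deg": "knee_alignment",
    "head_forward_cm": "forward_head",
    "pelvic_tilt_deg": "pelvic_tilt",
    "scoliosis_deg": "scoliosis",
    "scapula_tilt_deg": "scapula_inclination",
}


@dataclass(frozen=True)
class FigurineSpec:
    """Figurine dimensions, injected deviations, and capture geometry.

    Deviations are in the units of the index they drive (degrees, except
    ``head_forward_cm``); positive scoliosis bows the upper spine toward
    the subject's left. Camera distance must lie in the 1600-4600 mm range
    the tracking validation covered.
    """

    stature_mm: float = 1830.0
    shoulder_width_mm: float = 470.0
    shoulder_tilt_deg: float = 0.0
    pelvic_obliquity_deg: float = 0.0
    knee_alignment_deg: float = 0.0
    head_forward_cm: float = 0.0
    pelvic_tilt_deg: float = 0.0
    scoliosis_deg: float = 0.0
    scapula_tilt_deg: float = 0.0
    camera_distance_mm: float = 1900.0
    seed: int = 0

    def __post_init__(self):
        if self.stature_mm <= 0:
            raise PostureError("stature must be positive")
        if not 1600.0 <= self.camera_distance_mm <= 4600.0:
            raise PostureError(
                "camera distance must be within the validated 1600-4600 mm range"
            )
        for name in DEVIATION_FIELDS:
            if abs(getattr(self, name)) > 30.0:
                raise ImplausiblePoseError(
                    f"{name}={getattr(self, name)} outside the plausible +-30 range"
                )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FigurineSpec":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise PostureError(f"unknown figurine spec fields: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class NoiseModel:
    """Joint-position jitter model.

    ``sigma_mm`` is the per-axis Gaussian Std (the tracked-joint Std in the
    optimal 160-250 cm band is about 1.2-2.3 mm, hence the 2.0 default).
    ``distance_scaling`` grows sigma linearly per metre beyond 1900 mm;
    ``interference`` multiplies sigma to emulate a co-running optical
    mocap system (10x is a representative degradation); ``axis_weights``
    lets depth/X instability dominate if desired.
    """

    sigma_mm: float = 2.0
    distance_scaling: float = 0.0
    interference: float = 1.0
    axis_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.sigma_mm < 0 or self.interference < 0:
            raise PostureError("noise scales must be >= 0")

    def sigma_xyz(self, camera_distance_mm: float) -> np.ndarray:
        scale = max(
            0.0, 1.0 + self.distance_scaling * (camera_distance_mm - 1900.0) / 1000.0
        )
        return self.sigma_mm * self.interference * scale * np.asarray(
            self.axis_weights, float
        )


def _rot_xy(points: dict[str, np.ndarray], names: tuple[str, str], deg: float):
    """Rotate a left/right pair about its midpoint in the frontal (X-Y) plane;
    positive angles raise the +X (subject-left) member."""
    left, right = names
    m = (points[left] + points[right]) / 2.0
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    for name in names:
        d = points[name] - m
        points[name] = m + np.array(
            [c * d[0] - s * d[1], s * d[0] + c * d[1], d[2]]
        )


@dataclass(frozen=True)
class Figurine:
    """A deterministic noise-free body: joints and landmarks in body frame."""

    spec: FigurineSpec
    joints_body: dict[str, np.ndarray]
    file_landmarks_body: dict[str, dict[str, np.ndarray]]

    def _to_view(self, p: np.ndarray, view: str) -> np.ndarray:
        d = self.spec.camera_distance_mm
        x, y, z = p
        if view == "anterior":
            return np.array([x, y, d + z])
        if view == "lateral":
            return np.array([-z, y, d - x])
        if view == "posterior":
            return np.array([-x, y, d - z])
        raise PostureError(f"unknown view {view!r}")

    def skeleton_frame(self, view: str = "anterior") -> SkeletonFrame:
        """Noise-free skeleton in the canonical camera frame for ``view``."""
        return SkeletonFrame(
            timestamp_usec=0,
            joints={n: self._to_view(p, view) for n, p in self.joints_body.items()},
        )

    def file_landmarks(self, view: str) -> LandmarkSet:
        """Landmarks that a real system needs from markers/manual input."""
        pts = {
            n: self._to_view(p, view)
            for n, p in self.file_landmarks_body.get(view, {}).items()
        }
        return LandmarkSet(view=view, points=pts, source={n: "file" for n in pts})

    def landmarks(self, view: str) -> LandmarkSet:
        """Complete landmark set: skeleton-derived merged with file landmarks."""
        derived = landmarks_from_skeleton(self.skeleton_frame(view), view)
        return merge_landmarks(derived, self.file_landmarks(view))

    @property
    def reference_frame(self) -> SkeletonFrame:
        return self.skeleton_frame("anterior")

    @property
    def landmark_sets(self) -> dict[str, LandmarkSet]:
        return {view: self.landmarks(view) for view in VIEWS}


def make_figurine(spec: FigurineSpec | None = None) -> Figurine:
    """Build the deterministic figurine with the spec's deviations applied.

    The null pose (all deviations zero) computes every index to exactly 0;
    each deviation is an exact transform of its landmark pair, so injecting
    a value recovers it exactly through the index computation, and
    deviations compose independently.
    """
    spec = spec or FigurineSpec()
    h = spec.stature_mm
    hw = spec.shoulder_width_mm / 2.0

    def p(x, yfrac, z=0.0):
        return np.array([float(x), yfrac * h, float(z)])

    j: dict[str, np.ndarray] = {
        "PELVIS": p(0, 0.55),
        "SPINE_NAVEL": p(0, 0.65),
        "SPINE_CHEST": p(0, 0.74),
        "NECK": p(0, 0.86),
        "CLAVICLE_LEFT": p(0.3 * hw, 0.84),
        "SHOULDER_LEFT": p(hw, 0.82),
        "ELBOW_LEFT": p(hw + 20, 0.63),
        "WRIST_LEFT": p(hw + 30, 0.47),
        "HAND_LEFT": p(hw + 30, 0.44),
        "HANDTIP_LEFT": p(hw + 30, 0.40),
        "THUMB_LEFT": p(hw + 10, 0.45),
        "HIP_LEFT": p(95, 0.53),
        "KNEE_LEFT": p(100, 0.285),
        "ANKLE_LEFT": p(100, 0.04),
        "FOOT_LEFT": p(100, 0.0, -120),
        "HEAD": p(0, 1.00),
        "NOSE": p(0, 0.94, -100),
        "EYE_LEFT": p(30, 0.945, -90),
        "EAR_LEFT": p(70, 0.93, 0),
    }
    # Mirror the left side for the right (x -> -x).
    for left_name, pt in list(j.items()):
        if left_name.endswith("_LEFT"):
            right = left_name.replace("_LEFT", "_RIGHT")
            j[right] = pt * np.array([-1.0, 1.0, 1.0])
    assert set(j) == set(JOINT_NAMES)

    lm: dict[str, dict[str, np.ndarray]] = {
        "anterior": {},
        "lateral": {
            "ASIS": np.array([80.0, 0.55 * h, -90.0]),
            "PSIS": np.array([80.0, 0.55 * h, 90.0]),
        },
        "posterior": {
            "C7": np.array([0.0, 0.86 * h, 110.0]),
            "UPPER_T_SPINE": np.array([0.0, 0.80 * h, 115.0]),
            "MID_T_SPINE": np.array([0.0, 0.74 * h, 120.0]),
            "LOWER_T_SPINE": np.array([0.0, 0.68 * h, 118.0]),
            "L1": np.array([0.0, 0.63 * h, 115.0]),
            "LEFT_SIA": np.array([90.0, 0.71 * h, 115.0]),
            "RIGHT_SIA": np.array([-90.0, 0.71 * h, 115.0]),
        },
    }

    # --- inject deviations (each an exact transform of its pair) ---
    if spec.shoulder_tilt_deg:
        _rot_xy(j, ("SHOULDER_LEFT", "SHOULDER_RIGHT"), spec.shoulder_tilt_deg)
    if spec.pelvic_obliquity_deg:
        _rot_xy(j, ("HIP_LEFT", "HIP_RIGHT"), spec.pelvic_obliquity_deg)
    if spec.scapula_tilt_deg:
        _rot_xy(lm["posterior"], ("LEFT_SIA", "RIGHT_SIA"), spec.scapula_tilt_deg)
    if spec.knee_alignment_deg:
        th = math.radians(spec.knee_alignment_deg)
        for side, sgn in (("LEFT", -1.0), ("RIGHT", 1.0)):  # medial direction
            knee, ankle, foot = f"KNEE_{side}", f"ANKLE_{side}", f"FOOT_{side}"
            length = j[knee][1] - j[ankle][1]
            new_ankle = j[knee] + np.array(
                [sgn * length * math.sin(th), -length * math.cos(th), 0.0]
            )
            shift = new_ankle - j[ankle]
            j[ankle] = new_ankle
            j[foot] = j[foot] + np.array([shift[0], 0.0, 0.0])
    if spec.head_forward_cm:
        dz = -10.0 * spec.head_forward_cm  # anterior is -Z in the body frame
        for name in ("HEAD", "NOSE", "EYE_LEFT", "EYE_RIGHT", "EAR_LEFT", "EAR_RIGHT"):
            j[name] = j[name] + np.array([0.0, 0.0, dz])
    if spec.pelvic_tilt_deg:
        th = math.radians(spec.pelvic_tilt_deg)
        mid = (lm["lateral"]["ASIS"] + lm["lateral"]["PSIS"]) / 2.0
        half = 90.0
        lm["lateral"]["ASIS"] = mid + np.array(
            [0.0, -half * math.sin(th), -half * math.cos(th)]
        )
        lm["lateral"]["PSIS"] = mid + np.array(
            [0.0, half * math.sin(th), half * math.cos(th)]
        )
    if spec.scoliosis_deg:
        th = math.radians(spec.scoliosis_deg)
        base = lm["posterior"]["UPPER_T_SPINE"]
        seg = lm["posterior"]["C7"] - base  # vertical segment, length |seg_y|
        length = seg[1]
        lm["posterior"]["C7"] = base + np.array(
            [length * math.sin(th), length * math.cos(th), seg[2]]
        )

    return Figurine(spec=spec, joints_body=j, file_landmarks_body=lm)


def simulate_capture(
    figurine: Figurine,
    n_frames: int,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    view: str = "anterior",
) -> list[RawKinectFrame]:
    """Simulate a 30 Hz body-tracking capture of the figurine.

    Returns raw camera-frame (Y-down) frames: reference pose plus iid
    Gaussian jitter per joint per frame, timestamps 33333 us apart.
    Reproducible: the same seed yields an identical stream.
    """
    if n_frames < 1:
        raise PostureError("n_frames must be >= 1")
    noise = noise or NoiseModel()
    seed = figurine.spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    ref = figurine.skeleton_frame(view)
    base = ref.positions() * np.array([1.0, -1.0, 1.0])  # canonical -> camera Y-down
    sigma = noise.sigma_xyz(figurine.spec.camera_distance_mm)
    frames = []
    for i in range(n_frames):
        jitter = rng.normal(0.0, 1.0, size=base.shape) * sigma
        pos = base + jitter
        frames.append(
            RawKinectFrame(
                timestamp_usec=i * FRAME_INTERVAL_USEC,
                joints={name: pos[k] for k, name in enumerate(JOINT_NAMES)},
                confidence={name: "medium" for name in JOINT_NAMES},
            )
        )
    return frames


# Grade-band centre levels used when no deviation grid is given: one level
# per severity grade, away from the breakpoints.
DEFAULT_DEVIATION_GRID: dict[str, tuple[float, ...]] = {
    "uneven_shoulders": (1.0, 3.0, 5.0),
    "lateral_pelvic_tilt": (1.0, 3.0, 5.0),
    "scoliosis": (1.0, 3.0, 5.0),
    "scapula_inclination": (2.5, 7.5, 12.5),
    "pelvic_tilt": (7.5, 20.0, 30.0),
    "forward_head": (1.25, 3.75, 6.25),
    "knee_alignment": (1.0, 4.0, 6.0),
}


@dataclass(frozen=True)
class AgreementStudy:
    """Output of a simulated two-system grading study."""

    report: AgreementReport
    data: dict[str, dict] = field(default_factory=dict)

    def per_level_accuracy(self, index_name: str) -> dict[float, float]:
        return self.data[index_name]["per_level_accuracy"]


def simulate_agreement_study(
    grades_per_level: int = 60,
    deviation_grid: dict[str, tuple[float, ...]] | None = None,
    noise_sigma: float = 0.3,
    ref_sigma: float = 0.05,
    bias: float = 0.0,
    seed: int = 0,
    rubric: GradingRubric | None = None,
) -> AgreementStudy:
    """Simulate the grade-level validation protocol and run the full
    agreement pipeline.

    For each index, the figurine is set to each deviation level in turn and
    measured ``grades_per_level`` times by the system under test
    (truth + ``bias`` + N(0, ``noise_sigma``), in the index's own unit) and
    by the reference system (truth + N(0, ``ref_sigma``)). Measurements are
    graded with the rubric and pooled across levels into Cohen's d,
    ICC(2,2), the confusion matrix, accuracy, kappa, and MAE/RMSE.
    """
    if grades_per_level < 2:
        raise PostureError("need at least 2 measurements per level")
    grid = deviation_grid or DEFAULT_DEVIATION_GRID
    for levels in grid.values():
        if len(levels) < 2:
            raise PostureError("need at least 2 deviation levels per index")
    rubric = rubric or _grading.default_rubric()
    rng = np.random.default_rng(seed)

    per_index: dict[str, IndexAgreement] = {}
    data: dict[str, dict] = {}
    for index_name in INDEX_NAMES:
        if index_name not in grid:
            continue
        levels = grid[index_name]
        tests, refs, lvl_tags = [], [], []
        for level in levels:
            t = level + bias + rng.normal(0.0, noise_sigma, grades_per_level)
            r = level + rng.normal(0.0, ref_sigma, grades_per_level)
            if index_name != "knee_alignment":  # admissible range starts at 0
                t, r = np.clip(t, 0.0, None), np.clip(r, 0.0, None)
            tests.append(t)
            refs.append(r)
            lvl_tags.extend([level] * grades_per_level)
        x_test = np.concatenate(tests)
        x_ref = np.concatenate(refs)
        g_test = [rubric.grade(index_name, v)[0] for v in x_test]
        g_ref = [rubric.grade(index_name, v)[0] for v in x_ref]
        cm = confusion(g_ref, g_test, GRADES)
        series = PairedSeries(x_test=x_test, x_ref=x_ref)
        mae, rmse = index_error(series)
        icc, lo, hi = icc_2_2(np.column_stack([x_test, x_ref]))
        per_level = {}
        tags = np.asarray(lvl_tags)
        for level in levels:
            mask = tags == level
            agree = [gt == gr for gt, gr, m in zip(g_test, g_ref, mask) if m]
            per_level[level] = float(np.mean(agree))
        per_index[index_name] = IndexAgreement(
            index_name=index_name,
            cohens_d=cohens_d(series),
            icc=icc,
            icc_ci=(lo, hi),
            confusion=cm,
            accuracy=accuracy(cm),
            kappa=kappa(cm),
            mae=mae,
            rmse=rmse,
        )
        data[index_name] = {
            "levels": tuple(levels),
            "x_test": x_test,
            "x_ref": x_ref,
            "grades_test": g_test,
            "grades_ref": g_ref,
            "per_level_accuracy": per_level,
        }
    return AgreementStudy(report=AgreementReport(per_index=per_index), data=data)


__all__ = [
    "FRAME_INTERVAL_USEC",
    "DEVIATION_FIELDS",
    "DEVIATION_INDEX",
    "DEFAULT_DEVIATION_GRID",
    "FigurineSpec",
    "NoiseModel",
    "Figurine",
    "AgreementStudy",
    "make_figurine",
    "simulate_capture",
    "simulate_agreement_study",
]
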