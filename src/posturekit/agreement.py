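"""Precision, relative accuracy, and two-system agreement statistics.

These are the validation statistics used to compare a depth-camera posture
system against a gold-standard optical motion-capture reference:

* per-joint precision (standard deviations over a static capture),
* relative accuracy (difference of the two systems' measured displacement
  between adjacent camera positions, avoiding a rigid cross-system
  registration),
* Cohen's d with the pooled standard deviation,
* ICC(2,2): two-way random-effects, absolute-agreement, mean of k = 2
  raters, with an F-based 95% confidence interval,
* confusion matrix over severity grades, accuracy, and Cohen's kappa,
* MAE / RMSE of paired index series.

All standard deviations use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import DegenerateModelError, PostureError
from .joints import JOINT_NAMES
from .skeleton import SkeletonFrame


@dataclass(frozen=True)
class PrecisionSummary:
    """Per-joint Std. of the Euclidean distance from the camera origin and
    of the Z (depth), X and Y coordinates, over a static capture."""

    per_joint: pd.DataFrame  # index = joint, columns = euclidean/z/x/y (mm)

    def stats(self) -> pd.DataFrame:
        """max / min / mean of each Std. column across the 32 joints."""
        return self.per_joint.agg(["max", "min", "mean"])

    def to_csv(self, path) -> None:
        self.per_joint.to_csv(path, float_format="%.3f")


@dataclass(frozen=True)
class PairedSeries:
    """Measurements of one quantity by the system under test and a reference.

    ``paired`` marks element-wise correspondence (same trial measured by
    both systems); dispersion statistics need n >= 2 on each side.
    """

    x_test: np.ndarray
    x_ref: np.ndarray
    paired: bool = True

    def __post_init__(self):
        object.__setattr__(self, "x_test", np.asarray(self.x_test, float).ravel())
        object.__setattr__(self, "x_ref", np.asarray(self.x_ref, float).ravel())
        if self.paired and len(self.x_test) != len(self.x_ref):
            raise PostureError(
                "paired series must have equal lengths "
                f"({len(self.x_test)} vs {len(self.x_ref)})"
            )


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k counts; rows = reference-system grade, columns = test-system grade."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        k = len(self.classes)
        if c.shape != (k, k):
            raise PostureError(f"counts shape {c.shape} does not match {k} classes")
        if (c < 0).any():
            raise PostureError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass(frozen=True)
class IndexAgreement:
    """Agreement statistics for one postural index."""

    index_name: str
    cohens_d: float
    icc: float
    icc_ci: tuple[float, float]
    confusion: ConfusionMatrix
    accuracy: float
    kappa: float
    mae: float
    rmse: float


@dataclass(frozen=True)
class AgreementReport:
    """Two-system agreement statistics, one row per index."""

    per_index: dict[str, IndexAgreement] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, a in self.per_index.items():
            rows.append(
                {
                    "index": name,
                    "cohens_d": a.cohens_d,
                    "icc": a.icc,
                    "icc_ci_low": a.icc_ci[0],
                    "icc_ci_high": a.icc_ci[1],
                    "accuracy": a.accuracy,
                    "kappa": a.kappa,
                    "mae": a.mae,
                    "rmse": a.rmse,
                }
            )
        return pd.DataFrame(rows).set_index("index")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.3f")


def precision_summary(frames: list[SkeletonFrame]) -> PrecisionSummary:
    """Std. of joint Euclidean distance / depth / X / Y over a capture.

    The "Euclidean distance" of a joint is its distance from the camera
    origin, the only reading that needs no second reference point.
    """
    if len(frames) < 2:
        raise PostureError(f"need >= 2 frames for a precision summary, got {len(frames)}")
    stack = np.stack([f.positions() for f in frames])  # (n, 32, 3)
    eucl = np.linalg.norm(stack, axis=2)
    data = {
        "euclidean": eucl.std(axis=0, ddof=1),
        "z": stack[:, :, 2].std(axis=0, ddof=1),
        "x": stack[:, :, 0].std(axis=0, ddof=1),
        "y": stack[:, :, 1].std(axis=0, ddof=1),
    }
    df = pd.DataFrame(data, index=list(JOINT_NAMES))
    df.index.name = "joint"
    return PrecisionSummary(per_joint=df)


def relative_accuracy(delta_test: float, delta_ref: float) -> float:
    """Difference between the displacements two systems measured for the
    same camera move: delta_test - delta_ref (mm)."""
    if not (np.isfinite(delta_test) and np.isfinite(delta_ref)):
        raise PostureError("non-finite displacement")
    return float(delta_test) - float(delta_ref)


def depth_deltas(
    frames_a: list[SkeletonFrame], frames_b: list[SkeletonFrame]
) -> pd.Series:
    """Per-joint change in mean depth between two captures (mm).

    Convenience for the relative-accuracy protocol: capture the same static
    subject from two camera positions and compare each joint's mean Z.
    """
    za = np.stack([f.positions()[:, 2] for f in frames_a]).mean(axis=0)
    zb = np.stack([f.positions()[:, 2] for f in frames_b]).mean(axis=0)
    return pd.Series(zb - za, index=list(JOINT_NAMES), name="delta_z_mm")


def relative_accuracy_per_joint(
    frames_a: list[SkeletonFrame],
    frames_b: list[SkeletonFrame],
    delta_ref: float,
) -> pd.Series:
    """Per-joint relative accuracy against a reference displacement (mm)."""
    d = depth_deltas(frames_a, frames_b)
    return (d - float(delta_ref)).rename("relative_accuracy_mm")


def cohens_d(series: PairedSeries) -> float:
    """Standardized mean difference (test - reference) / pooled Std.

    Pooled Std S = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)). The sign is
    preserved. Conventional magnitude bands: 0.2-0.5 small, 0.5-0.8 medium,
    > 0.8 large.
    """
    xs, xo = series.x_test, series.x_ref
    n1, n2 = len(xs), len(xo)
    if n1 < 2 or n2 < 2:
        raise PostureError("cohens_d needs n >= 2 in both groups")
    s1, s2 = xs.std(ddof=1), xo.std(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise DegenerateModelError("zero pooled Std: effect size undefined")
    return float((xs.mean() - xo.mean()) / pooled)


def effect_size_label(d: float) -> str:
    """Qualitative label for |d|: negligible / small / medium / large."""
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way n x k rating layout, no replication."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_2_2(
    ratings: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """ICC(2,2): two-way random, absolute agreement, mean of two raters.

    ICC = (MSR - MSE) / (MSR + (MSC - MSE)/n) from the two-way ANOVA mean
    squares (MSR rows/subjects, MSC columns/raters, MSE error). The 95% CI
    is the F-based interval for the single-rater absolute-agreement ICC,
    converted to the average-measures scale by the Spearman-Brown step —
    the convention followed by the standard statistical packages.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise PostureError(f"ratings must be n x 2, got {x.shape}")
    n, k = x.shape
    if n < 5:
        raise PostureError(f"need n >= 5 subjects, got {n}")
    msr, msc, mse = _anova_mean_squares(x)
    if np.isclose(msr, 0.0):
        raise DegenerateModelError("zero between-subject variance: ICC undefined")
    icc_k = (msr - mse) / (msr + (msc - mse) / n)

    # Single-measure absolute-agreement ICC and its F-based CI
    # (two-way random effects), then Spearman-Brown up to k raters.
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    fj = msc / mse if mse > 0 else np.inf
    num = (k - 1) * (n - 1) * (
        k * icc_1 * fj + n * (1 + (k - 1) * icc_1) - k * icc_1
    ) ** 2
    den = (n - 1) * k**2 * icc_1**2 * fj**2 + (
        n * (1 + (k - 1) * icc_1) - k * icc_1
    ) ** 2
    v = num / den if den > 0 else 1.0
    f_upper = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f_lower = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (msr - f_upper * mse) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi1 = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr
    )
    lo_k = k * lo1 / (1 + (k - 1) * lo1)
    hi_k = k * hi1 / (1 + (k - 1) * hi1)
    return float(icc_k), float(lo_k), float(hi_k)


def confusion(
    grades_ref: list[str], grades_test: list[str], classes: tuple[str, ...]
) -> ConfusionMatrix:
    """Cross-tabulate reference vs test grades in a fixed class order."""
    if len(grades_ref) != len(grades_test):
        raise PostureError(
            f"length mismatch: {len(grades_ref)} reference vs "
            f"{len(grades_test)} test grades"
        )
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for r, t in zip(grades_ref, grades_test):
        if r not in idx:
            raise PostureError(f"unknown reference class {r!r}")
        if t not in idx:
            raise PostureError(f"unknown test class {t!r}")
        counts[idx[r], idx[t]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of cases graded identically by both systems (trace / total).

    For two classes this is (TP+TN)/(TP+TN+FP+FN); the trace form is its
    multi-class generalization.
    """
    if cm.total == 0:
        raise PostureError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), chance agreement from the
    marginals: p_e = sum_i row_i * col_i / total^2."""
    if cm.total == 0:
        raise PostureError("empty confusion matrix")
    total = cm.total
    p_o = np.trace(cm.counts) / total
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    p_e = float((rows * cols).sum()) / total**2
    if p_e >= 1.0:
        raise DegenerateModelError(
            "all observations in a single class: kappa undefined"
        )
    return float((p_o - p_e) / (1 - p_e))


def index_error(series: PairedSeries) -> tuple[float, float]:
    """(MAE, RMSE) of a paired test-vs-reference series."""
    if not series.paired:
        raise PostureError("MAE/RMSE require paired series")
    diff = series.x_test - series.x_ref
    mae = float(np.abs(diff).mean())
    rmse = float(np.sqrt((diff**2).mean()))
    return mae, rmse


__all__ = [
    "PrecisionSummary",
    "PairedSeries",
    "ConfusionMatrix",
    "IndexAgreement",
    "AgreementReport",
    "precision_summary",
    "relative_accuracy",
    "depth_deltas",
    "relative_accuracy_per_joint",
    "cohens_d",
    "effect_size_label",
    "icc_2_2",
    "confusion",
    "accuracy",
    "kappa",
    "index_error",
]
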