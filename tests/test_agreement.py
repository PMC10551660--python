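"""Precision and agreement statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from posturekit.agreement import (
    ConfusionMatrix,
    PairedSeries,
    accuracy,
    cohens_d,
    confusion,
    depth_deltas,
    effect_size_label,
    icc_2_2,
    index_error,
    kappa,
    precision_summary,
    relative_accuracy,
    relative_accuracy_per_joint,
)
from posturekit.errors import DegenerateModelError, PostureError
from posturekit.joints import JOINT_NAMES
from posturekit.skeleton import SkeletonFrame, to_canonical
from posturekit.synth import FigurineSpec, NoiseModel, make_figurine, simulate_capture


def _frame(x=0.0, y=100.0, z=2000.0):
    return SkeletonFrame(
        timestamp_usec=0,
        joints={n: np.array([x, y, z]) for n in JOINT_NAMES},
    )


class TestPrecisionSummary:
    def test_identical_frames_zero_std(self):
        summary = precision_summary([_frame()] * 5)
        assert np.allclose(summary.per_joint.to_numpy(), 0.0, atol=1e-9)

    def test_alternating_depth_closed_form(self):
        """z alternating 2000/2002 over 1000 frames: sample Std with the
        n-1 denominator is sqrt(1000/999) ~ 1.0005 mm."""
        frames = [_frame(z=2000.0 + 2.0 * (i % 2)) for i in range(1000)]
        summary = precision_summary(frames)
        expected = np.sqrt(1000.0 / 999.0)
        assert summary.per_joint.loc["PELVIS", "z"] == pytest.approx(expected, abs=1e-9)

    def test_monte_carlo_recovers_sigma(self):
        fig = make_figurine(FigurineSpec())
        raw = simulate_capture(fig, 2000, noise=NoiseModel(sigma_mm=2.0), seed=5)
        summary = precision_summary([to_canonical(f) for f in raw])
        for axis in ("x", "y", "z"):
            assert summary.per_joint[axis].mean() == pytest.approx(2.0, rel=0.10)

    def test_requires_two_frames(self):
        with pytest.raises(PostureError):
            precision_summary([_frame()])


class TestRelativeAccuracy:
    def test_equal_deltas_zero(self):
        assert relative_accuracy(300.0, 300.0) == 0.0

    def test_signed_difference(self):
        assert relative_accuracy(299.0, 305.0) == pytest.approx(-6.0)

    def test_noise_free_camera_shift_exact_zero_per_joint(self):
        """Moving the camera 300 mm back changes every joint's mean depth
        by exactly 300 mm, so the relative accuracy is 0 for every joint."""
        near = make_figurine(FigurineSpec(camera_distance_mm=1900.0))
        far = make_figurine(FigurineSpec(camera_distance_mm=2200.0))
        quiet = NoiseModel(sigma_mm=0.0)
        fa = [to_canonical(f) for f in simulate_capture(near, 5, noise=quiet, seed=1)]
        fb = [to_canonical(f) for f in simulate_capture(far, 5, noise=quiet, seed=2)]
        ra = relative_accuracy_per_joint(fa, fb, delta_ref=300.0)
        assert np.allclose(ra.to_numpy(), 0.0, atol=1e-9)

    def test_noisy_shift_mean_near_zero(self):
        near = make_figurine(FigurineSpec(camera_distance_mm=1900.0))
        far = make_figurine(FigurineSpec(camera_distance_mm=2200.0))
        noise = NoiseModel(sigma_mm=2.0)
        n = 500
        fa = [to_canonical(f) for f in simulate_capture(near, n, noise=noise, seed=3)]
        fb = [to_canonical(f) for f in simulate_capture(far, n, noise=noise, seed=4)]
        ra = relative_accuracy_per_joint(fa, fb, delta_ref=300.0)
        # mean depth of n frames has Std sigma/sqrt(n); difference sqrt(2) of that
        tol = 3.0 * 2.0 * np.sqrt(2.0 / n)
        assert abs(ra.mean()) < tol


class TestCohensD:
    def test_identical_samples_zero(self):
        d = cohens_d(PairedSeries([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert d == 0.0

    def test_hand_computed_pooled_sd(self):
        # both groups have s=1, pooled s=1, mean difference -1
        assert cohens_d(PairedSeries([1, 2, 3], [2, 3, 4])) == pytest.approx(-1.0)

    def test_antisymmetric(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.4, 1.2, 30)
        assert cohens_d(PairedSeries(a, b)) == pytest.approx(
            -cohens_d(PairedSeries(b, a))
        )

    def test_unequal_sizes_allowed(self, rng):
        s = PairedSeries(rng.normal(0, 1, 10), rng.normal(0, 1, 25), paired=False)
        cohens_d(s)  # must not raise

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(DegenerateModelError):
            cohens_d(PairedSeries([1.0, 1.0, 1.0], [2.0, 2.0, 2.0]))

    def test_effect_size_labels(self):
        assert effect_size_label(0.1) == "negligible"
        assert effect_size_label(-0.3) == "small"
        assert effect_size_label(0.6) == "medium"
        assert effect_size_label(-1.2) == "large"


def _icc_bruteforce(x):
    """Direct ANOVA mean squares, independent of the implementation."""
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        icc, lo, hi = icc_2_2(x)
        assert icc == pytest.approx(1.0)

    def test_matches_bruteforce_anova(self, rng):
        x = rng.normal(50, 10, size=(12, 2)) + rng.normal(0, 3, size=(12, 2))
        icc, _, _ = icc_2_2(x)
        assert icc == pytest.approx(_icc_bruteforce(x), abs=1e-10)

    def test_matches_pingouin_including_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        a = rng.normal(10, 3, 20)
        b = a + rng.normal(0.5, 1.0, 20)
        icc, lo, hi = icc_2_2(np.column_stack([a, b]))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(20), 2),
                "raters": ["s", "o"] * 20,
                "ratings": np.column_stack([a, b]).ravel(),
            }
        )
        row = pg.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        ).set_index("Type").loc["ICC(A,k)"]
        assert icc == pytest.approx(row["ICC"], abs=1e-10)
        assert lo == pytest.approx(row["CI95"][0], abs=0.01)
        assert hi == pytest.approx(row["CI95"][1], abs=0.01)

    def test_independent_ratings_near_zero(self, rng):
        x = rng.normal(0, 1, size=(10_000, 2))
        icc, _, _ = icc_2_2(x)
        assert abs(icc) < 0.05

    def test_shift_invariant(self, rng):
        x = rng.normal(5, 2, size=(15, 2))
        a, _, _ = icc_2_2(x)
        b, _, _ = icc_2_2(x + 123.456)
        assert b == pytest.approx(a, abs=1e-9)

    def test_zero_between_subject_variance_raises(self):
        x = np.column_stack([np.full(8, 1.0), np.full(8, 3.0)])
        with pytest.raises(DegenerateModelError):
            icc_2_2(x)


class TestConfusionAccuracyKappa:
    def test_perfect_agreement_diagonal(self):
        grades = ["light", "medium", "heavy"] * 20
        cm = confusion(grades, grades, ("light", "medium", "heavy"))
        assert np.trace(cm.counts) == 60
        assert accuracy(cm) == 1.0
        assert kappa(cm) == pytest.approx(1.0)

    def test_total_disagreement_single_cell(self):
        cm = confusion(["light"] * 9, ["heavy"] * 9, ("light", "medium", "heavy"))
        assert cm.counts[0, 2] == 9
        assert cm.counts.sum() == 9
        assert accuracy(cm) == 0.0

    def test_marginals_conserved(self, rng):
        classes = ("light", "medium", "heavy")
        ref = rng.choice(classes, 200).tolist()
        test = rng.choice(classes, 200).tolist()
        cm = confusion(ref, test, classes)
        for i, c in enumerate(classes):
            assert cm.counts[i].sum() == ref.count(c)
            assert cm.counts[:, i].sum() == test.count(c)

    def test_accuracy_hand_case(self):
        cm = ConfusionMatrix(np.array([[40, 10], [5, 45]]), ("neg", "pos"))
        assert accuracy(cm) == pytest.approx(0.85)

    def test_uniform_matrix_chance_accuracy(self):
        cm = ConfusionMatrix(np.full((3, 3), 7), ("a", "b", "c"))
        assert accuracy(cm) == pytest.approx(1.0 / 3.0)

    def test_kappa_hand_case(self):
        # p_o = 0.85, p_e = (50*45 + 50*55)/100^2 = 0.5
        cm = ConfusionMatrix(np.array([[40, 10], [5, 45]]), ("neg", "pos"))
        assert kappa(cm) == pytest.approx((0.85 - 0.5) / 0.5, abs=1e-10)

    def test_kappa_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        classes = ("light", "medium", "heavy")
        ref = rng.choice(classes, 300).tolist()
        test = rng.choice(classes, 300).tolist()
        cm = confusion(ref, test, classes)
        assert kappa(cm) == pytest.approx(
            sk.cohen_kappa_score(ref, test), abs=1e-12
        )

    def test_kappa_null_large_sample(self, rng):
        classes = ("a", "b", "c")
        ref = rng.choice(classes, 100_000).tolist()
        test = rng.choice(classes, 100_000).tolist()
        assert abs(kappa(confusion(ref, test, classes))) < 0.02

    def test_single_class_kappa_undefined(self):
        cm = confusion(["light"] * 5, ["light"] * 5, ("light", "medium", "heavy"))
        with pytest.raises(DegenerateModelError):
            kappa(cm)

    def test_length_mismatch(self):
        with pytest.raises(PostureError, match="mismatch"):
            confusion(["light"], ["light", "heavy"], ("light", "heavy"))

    def test_kappa_one_iff_accuracy_one(self, rng):
        classes = ("light", "medium", "heavy")
        grades = rng.choice(classes, 100).tolist()
        cm = confusion(grades, grades, classes)
        assert accuracy(cm) == 1.0 and kappa(cm) == pytest.approx(1.0)


class TestIndexError:
    def test_identical_series_zero(self):
        assert index_error(PairedSeries([1.0, 2.0], [1.0, 2.0])) == (0.0, 0.0)

    def test_unit_diffs(self):
        mae, rmse = index_error(PairedSeries([1, 0, 1, 0], [0, 1, 0, 1]))
        assert (mae, rmse) == (1.0, 1.0)

    def test_hand_case(self):
        mae, rmse = index_error(PairedSeries([0, 0, 3], [0, 0, 0]))
        assert mae == pytest.approx(1.0)
        assert rmse == pytest.approx(np.sqrt(3.0))

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            a, b = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
            mae, rmse = index_error(PairedSeries(a, b))
            assert rmse >= mae - 1e-12

    def test_unpaired_rejected(self, rng):
        s = PairedSeries(rng.normal(0, 1, 5), rng.normal(0, 1, 7), paired=False)
        with pytest.raises(PostureError):
            index_error(s)


def test_depth_deltas_reflect_camera_move():
    near = make_figurine(FigurineSpec(camera_distance_mm=1600.0))
    far = make_figurine(FigurineSpec(camera_distance_mm=1900.0))
    quiet = NoiseModel(sigma_mm=0.0)
    fa = [to_canonical(f) for f in simulate_capture(near, 3, noise=quiet, seed=0)]
    fb = [to_canonical(f) for f in simulate_capture(far, 3, noise=quiet, seed=0)]
    d = depth_deltas(fa, fb)
    assert np.allclose(d.to_numpy(), 300.0)
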