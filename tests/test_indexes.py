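"""Postural index geometry: analytic cases, parameter recovery, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posturekit.errors import MissingLandmarkError, PostureError, UndefinedAngleError
from posturekit.indexes import (
    INDEX_VIEW,
    EvaluationReport,
    angle_to_horizontal,
    assess,
    compute_index,
)
from posturekit.skeleton import LandmarkSet
from posturekit.synth import (
    DEVIATION_INDEX,
    FigurineSpec,
    NoiseModel,
    make_figurine,
    simulate_capture,
)


class TestAngleToHorizontal:
    def test_horizontal_line_is_level(self):
        a, direction = angle_to_horizontal(
            np.array([-175.0, 1400.0, 2000.0]), np.array([175.0, 1400.0, 2000.0])
        )
        assert a == pytest.approx(0.0, abs=1e-9)
        assert direction == "level"

    def test_45_degree_construction(self):
        a, direction = angle_to_horizontal(
            np.array([0.0, 0.0, 0.0]), np.array([300.0, 300.0, 0.0])
        )
        assert a == pytest.approx(45.0, abs=1e-9)
        assert direction == "left_high"

    def test_two_degree_boundary_vs_arctan_oracle(self):
        """Raising the left point 12.22 mm over a 350 mm span gives the
        2 deg grading boundary; arcsin and arctan forms must agree."""
        a, _ = angle_to_horizontal(
            np.array([-175.0, 1400.0, 2000.0]), np.array([175.0, 1412.22, 2000.0])
        )
        oracle = math.degrees(math.atan(12.22 / 350.0))
        assert a == pytest.approx(oracle, abs=1e-9)
        assert a == pytest.approx(2.000, abs=1e-3)

    def test_right_high_direction(self):
        a, direction = angle_to_horizontal(
            np.array([-175.0, 1410.0, 0.0]), np.array([175.0, 1400.0, 0.0])
        )
        assert direction == "right_high"
        assert a > 0

    def test_coincident_points_raise(self):
        p = np.array([1.0, 2.0, 3.0])
        with pytest.raises(UndefinedAngleError):
            angle_to_horizontal(p, p.copy())

    def test_depth_component_participates(self):
        """The angle uses the full 3D norm, not the frontal projection."""
        a, _ = angle_to_horizontal(
            np.array([0.0, 0.0, 0.0]), np.array([300.0, 300.0, 300.0])
        )
        assert a == pytest.approx(math.degrees(math.asin(300 / math.sqrt(3) / 300)))


class TestComputeIndex:
    def test_forward_head_three_cm(self):
        lms = LandmarkSet(
            view="lateral",
            points={
                "EARLOBE": np.array([2050.0, 1600.0, 1980.0]),
                "ACROMION": np.array([2020.0, 1500.0, 1985.0]),
            },
        )
        r = compute_index("forward_head", lms)
        assert r.value == pytest.approx(3.0)
        assert r.unit == "cm"

    def test_vertical_shanks_give_zero_knee_angle(self, null_figurine):
        r = compute_index("knee_alignment", null_figurine.landmarks("anterior"))
        assert r.value == pytest.approx(0.0, abs=1e-12)

    def test_collinear_spine_gives_zero_scoliosis(self, null_figurine):
        r = compute_index("scoliosis", null_figurine.landmarks("posterior"))
        assert r.value == pytest.approx(0.0, abs=1e-12)

    def test_missing_landmark_names_index_and_landmark(self):
        lms = LandmarkSet(view="lateral", points={})
        with pytest.raises(MissingLandmarkError, match="forward_head.*EARLOBE"):
            compute_index("forward_head", lms)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("shoulder_tilt_deg", 3.7),
            ("pelvic_obliquity_deg", 2.2),
            ("knee_alignment_deg", -2.0),
            ("knee_alignment_deg", 4.0),
            ("head_forward_cm", 3.0),
            ("pelvic_tilt_deg", 18.0),
            ("scoliosis_deg", 2.5),
            ("scapula_tilt_deg", 7.0),
        ],
    )
    def test_noise_free_parameter_recovery(self, field, value):
        """Injecting a deviation into the noise-free figurine recovers it
        exactly through the index computation."""
        spec = FigurineSpec(**{field: value})
        fig = make_figurine(spec)
        index = DEVIATION_INDEX[field]
        r = compute_index(index, fig.landmarks(INDEX_VIEW[index]))
        assert r.value == pytest.approx(value, abs=1e-6)

    def test_knee_direction_tags(self):
        varus = make_figurine(FigurineSpec(knee_alignment_deg=4.0))
        valgus = make_figurine(FigurineSpec(knee_alignment_deg=-2.0))
        assert compute_index("knee_alignment", varus.landmarks("anterior")).direction == "O"
        assert compute_index("knee_alignment", valgus.landmarks("anterior")).direction == "X"

    def test_pelvic_tilt_anterior_direction(self):
        fig = make_figurine(FigurineSpec(pelvic_tilt_deg=10.0))
        r = compute_index("pelvic_tilt", fig.landmarks("lateral"))
        assert r.direction == "anterior"


class TestInvariances:
    @settings(max_examples=20, deadline=None)
    @given(
        st.floats(-500, 500), st.floats(-500, 500), st.floats(-500, 500),
    )
    def test_translation_invariance(self, dx, dy, dz):
        fig = make_figurine(
            FigurineSpec(shoulder_tilt_deg=3.7, knee_alignment_deg=-2.0,
                         head_forward_cm=3.0, pelvic_tilt_deg=18.0,
                         scoliosis_deg=2.5, scapula_tilt_deg=7.0,
                         pelvic_obliquity_deg=2.2)
        )
        shift = np.array([dx, dy, dz])
        for index, view in INDEX_VIEW.items():
            lms = fig.landmarks(view)
            shifted = LandmarkSet(
                view=view, points={n: p + shift for n, p in lms.points.items()}
            )
            a = compute_index(index, lms).value
            b = compute_index(index, shifted).value
            assert b == pytest.approx(a, abs=1e-9)

    def test_angles_scale_invariant_distance_scales(self, deviated_figurine):
        for index, view in INDEX_VIEW.items():
            lms = deviated_figurine.landmarks(view)
            scaled = LandmarkSet(
                view=view, points={n: 2.0 * p for n, p in lms.points.items()}
            )
            a = compute_index(index, lms).value
            b = compute_index(index, scaled).value
            if index == "forward_head":
                assert b == pytest.approx(2.0 * a, rel=1e-12)
            else:
                assert b == pytest.approx(a, abs=1e-9)

    def test_yaw_changes_frontal_indexes(self):
        """Indexes are camera-frame quantities: a yaw of the landmark cloud
        changes frontal-plane projections (documented, not hidden)."""
        fig = make_figurine(FigurineSpec(knee_alignment_deg=4.0))
        lms = fig.landmarks("anterior")
        th = math.radians(30)
        rot = np.array(
            [[math.cos(th), 0, math.sin(th)], [0, 1, 0],
             [-math.sin(th), 0, math.cos(th)]]
        )
        yawed = LandmarkSet(
            view="anterior", points={n: rot @ p for n, p in lms.points.items()}
        )
        a = compute_index("knee_alignment", lms).value
        b = compute_index("knee_alignment", yawed).value
        assert abs(a - b) > 0.1


class TestAssess:
    def _captures(self, fig, n=10):
        return {
            view: simulate_capture(fig, n, noise=NoiseModel(sigma_mm=0.0),
                                   seed=i, view=view)
            for i, view in enumerate(("anterior", "lateral", "posterior"))
        }

    def _files(self, fig):
        return {v: fig.file_landmarks(v) for v in ("lateral", "posterior")}

    def test_all_views_give_seven_indexes(self, deviated_figurine):
        rep = assess(self._captures(deviated_figurine),
                     file_landmarks=self._files(deviated_figurine))
        assert len(rep.results) == 7
        assert rep.skipped == {}
        assert all(r.grade in ("light", "medium", "heavy") for r in rep.results)

    def test_anterior_only_gives_three_plus_skips(self, deviated_figurine):
        caps = {"anterior": self._captures(deviated_figurine)["anterior"]}
        rep = assess(caps)
        names = {r.index_name for r in rep.results}
        assert names == {"uneven_shoulders", "lateral_pelvic_tilt", "knee_alignment"}
        assert len(rep.skipped) == 4

    def test_missing_posterior_table_skips_with_reason(self, deviated_figurine):
        caps = self._captures(deviated_figurine)
        rep = assess(caps, file_landmarks={"lateral": deviated_figurine.file_landmarks("lateral")})
        assert "scoliosis" in rep.skipped
        assert "C7" in rep.skipped["scoliosis"]

    def test_deterministic(self, deviated_figurine):
        caps = self._captures(deviated_figurine)
        files = self._files(deviated_figurine)
        a = assess(caps, file_landmarks=files)
        b = assess(caps, file_landmarks=files)
        assert a == b

    def test_no_views_raises(self):
        with pytest.raises(PostureError, match="no views"):
            assess({})

    def test_duplicate_index_rejected(self):
        from posturekit.indexes import IndexResult

        r = IndexResult("forward_head", 1.0, "cm")
        with pytest.raises(PostureError, match="duplicate"):
            EvaluationReport(subject_id="s", results=(r, r))
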