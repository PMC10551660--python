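"""Assess the posture of a synthetic figurine with known deviations.

Builds a 183 cm figurine with a 3.7 deg shoulder tilt, 3 cm forward head
and 2.5 deg scoliosis, simulates a noisy 30 Hz three-view capture, and runs
the full assessment pipeline (10-frame averaging -> landmark derivation ->
index computation -> severity grading).
"""

from posturekit import assess
from posturekit.synth import FigurineSpec, NoiseModel, make_figurine, simulate_capture

spec = FigurineSpec(shoulder_tilt_deg=3.7, head_forward_cm=3.0, scoliosis_deg=2.5)
figurine = make_figurine(spec)

noise = NoiseModel(sigma_mm=2.0)  # per-axis joint jitter, mm
captures = {
    view: simulate_capture(figurine, n_frames=10, noise=noise, seed=i, view=view)
    for i, view in enumerate(("anterior", "lateral", "posterior"))
}
# Pelvic-spine and posterior landmarks cannot be derived from the tracked
# skeleton; a real operator supplies them from markers. The figurine knows
# its own.
file_landmarks = {v: figurine.file_landmarks(v) for v in ("lateral", "posterior")}

report = assess(captures, file_landmarks=file_landmarks, subject_id="figurine-183")

print(f"subject: {report.subject_id}")
for r in report.results:
    tag = f" ({r.grade_tag})" if r.grade_tag else ""
    direction = f"  [{r.direction}]" if r.direction else ""
    print(f"  {r.index_name:22s} {r.value:7.3f} {r.unit:3s} -> {r.grade}{tag}{direction}")

# Each line shows the measured index, its unit, and the severity grade under
# the default rubric. The injected deviations (3.7 deg, 3.0 cm, 2.5 deg)
# are recovered to within the jitter left after ten-frame averaging; the
# untouched indexes stay near zero and grade light.
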