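# Methods

This note documents the models, conventions, and numerical choices behind
`posturekit`, and what the synthetic validation does and does not show
about real captures.

## Coordinate conventions and input model

Body-tracking input is the 32-joint skeleton of the Azure-Kinect-style
SDK: per frame, a microsecond timestamp and one 3D position (mm) per named
joint, in a camera frame whose Y axis points down. All geometry is done in
a canonical right-handed frame obtained by flipping Y: X = camera
horizontal (subject's left is +X in an anterior view), Y = up, Z = depth
away from the camera. Capture files follow the offline body-tracking
processor dialect (`frames → bodies → joint_positions`); positions may be
an array in SDK joint order or an object keyed by joint name. Joint
confidence levels are read and logged but never used to weight
computations — no principled weighting is established for this task, and
the frame-selection rule (highest mean confidence among multiple bodies)
already uses them where they matter.

The assessment protocol photographs three planes — anterior, left-lateral,
posterior — each a separate capture with the subject squarely facing (or
backing) the camera. Landmarks either alias skeleton joints (acromion ←
shoulder, iliac crest ← hip, patella ← knee, malleolus ← ankle, earlobe ←
left ear) or must be supplied from a landmark table (`landmark,x_mm,y_mm,
z_mm` CSV): the pelvic spines (ASIS/PSIS) and the whole posterior spinal
chain cannot be located from the tracked skeleton and are never invented.
When both sources provide a landmark, the file value wins — it represents
a deliberate operator correction.

## Index definitions

Only two indexes have canonical closed forms in the source methodology:
the shoulder-line angle α = arcsin(|n·V|/(‖n‖‖V‖)) against the horizontal
plane normal n = (0,1,0), and the sagittal earlobe–acromion distance
d = |X_ear − X_acr|. The remaining five are documented operational
definitions chosen to be consistent with their grading bands:

* lateral pelvic tilt and scapula inclination reuse the shoulder-line
  angle over their landmark pairs;
* sagittal pelvic tilt is the PSIS→ASIS line's inclination projected to
  the lateral X–Y plane; the 0–15° light band accommodates normal anterior
  tilt;
* knee alignment is the signed frontal-plane angle of each
  patella→malleolus line from straight down, positive when the malleolus
  deviates toward the midline (varus/O-leg), matching the positive O-leg
  grading bands; the legs are averaged into one value;
* scoliosis is the maximum frontal-plane deviation from vertical over
  consecutive segments of the five-point spinal chain — an interpretation
  (flagged as such) consistent with its 0–2° light band.

The α form reports magnitudes only; laterality is carried separately as a
direction tag (left/right high, anterior/posterior tilt, O/X,
convex-left/right). In the posterior view the camera mirrors laterality
(camera +X is the subject's right); convexity tags account for this. All
internal lengths are mm; forward head converts to cm only at result
construction, because the grading thresholds are stated in cm.

Indexes are translation-invariant, angle indexes are scale-invariant, and
none are yaw-invariant: they are camera-frame quantities, as in any
photograph-based posture assessment. The ten-frame averaging rule
(single frames are outlier-prone) averages the *first* ten frames by
default; which ten is configurable via an offset since the choice is not
canonical.

## Grading

Grades are light/medium/heavy over half-open intervals (lower bound
inclusive). Breakpoints: shoulders / lateral pelvic tilt / scoliosis at
2° and 4°; scapula inclination 5° and 10°; sagittal pelvic tilt 15° and
25°; forward head 2.5 cm and 5 cm; knee −3°, −1°, 3°, 5° on the signed
axis with O/X tags. As printed, the knee medium band (−3° ≤ α < −1°) and
heavy band (α ≤ −3°) both contain exactly −3°; the tie resolves to the
severer grade. Rubrics are JSON-configurable and validated (no gaps, no
overlaps except double-inclusive shared breakpoints, which resolve
severer-wins); reports record the rubric version.

## Agreement statistics

All dispersion uses the n−1 denominator. Cohen's d uses the pooled Std
S = √(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)) and keeps its sign. ICC(2,2) is
the two-way random-effects, absolute-agreement, average-of-two-raters
form (MSR − MSE)/(MSR + (MSC − MSE)/n) from the ANOVA mean squares; its
95% CI is the McGraw–Wong F-based interval for the single-rater
absolute-agreement ICC transformed to the k = 2 scale by the
Spearman–Brown step — the convention the standard statistical packages
follow (verified against pingouin in the tests). κ is unweighted; grades
are treated as nominal despite their ordinality, since no weighting is
part of the validated protocol. Accuracy is trace/total, the multi-class
generalization of (TP+TN)/(TP+TN+FP+FN). The confusion matrix puts the
reference system on rows.

A joint's "Euclidean distance" in the precision summary is its distance
from the camera origin — the only reading that needs no second reference
point. Relative accuracy compares the displacement two systems measure for
the same physical camera move (Δd_test − Δd_ref), which sidesteps rigid
registration between the two systems' frames; the per-joint convenience
wrapper uses mean joint depths of two captures per position.

## Synthetic figurine

The generator emulates the hardware validation subject: a rigid figurine
of stature 1830 mm and shoulder width 470 mm, captured at 30 Hz at a
camera distance of 1900 mm (configurable within the validated
1600–4600 mm range). Joints are placed by fixed anthropometric fractions
of stature (hip 0.53·H, shoulders 0.82·H, knee 0.285·H, …; the HEAD joint
sits at the crown so the skeleton spans exactly the stature). The
fractions are documented constants, not fitted values — the indexes depend
only on relative landmark geometry.

Each deviation is injected as an exact rigid transform of its landmark
pair (shoulder tilt rotates the acromion pair about the sagittal axis
through its midpoint by exactly θ; forward head translates the head
cluster by 10·d mm along the sagittal axis; and so on), so in the
noise-free limit every index recovers its injected value to machine
precision, deviations compose independently, and deviations beyond ±30
are rejected as implausible poses.

Noise is iid isotropic Gaussian jitter per joint per frame with
σ = 2.0 mm by default, matching the observed mm-scale tracking Std in the
optimal 160–250 cm operating band. Optional knobs: per-axis weights
(tracking instability concentrates in depth and X in practice), a linear
distance-scaling factor, and an interference multiplier (default 10× when
used) emulating a co-running optical mocap system purely as a noise
scale, not a physical model. All randomness flows from a single explicit
seed.

The simulated agreement study mirrors the grade-level protocol: one
deviation level per severity grade (band centres by default), 60
measurements per level by the test system (σ = 0.3 index units) and a
near-perfect reference (σ = 0.05), pooled per index through the full
statistics pipeline. Placing a level exactly on a grading breakpoint
collapses that level's accuracy toward chance — the threshold-vicinity
behaviour any thresholded ordinal screen exhibits.

**What this does not show.** The figurine has no soft tissue, no tracking
failure modes (lost or swapped limbs, body-model bias), Gaussian rather
than heavy-tailed noise, and perfectly known landmarks; the file
landmarks it supplies are noise-free. Passing the synthetic suite
demonstrates the correctness of the geometry, grading, and statistics —
not the field accuracy of any particular camera.

## Numerical choices

* Angles via `arcsin` with the ratio clamped to 1 against rounding;
  coincident points raise rather than return 0.
* Frame averaging is a plain coordinate-wise mean; timestamps average and
  round to integer microseconds.
* Report serialization sorts keys and fixes floats to three decimals
  (1 µm, far below sensor noise) so identical inputs give identical
  bytes; capture JSON keeps full float precision for round-tripping.
* ICC requires n ≥ 5 subjects and raises on zero between-subject
  variance; κ raises when both systems use a single shared class
  (p_e = 1); Cohen's d raises on zero pooled Std.
* Problem sizes in the test and acceptance runs (10-frame windows, 500
  averaging repetitions, 2000-frame precision captures, 10⁴–10⁵ null
  samples) are chosen so Monte-Carlo tolerances (±10–15%, ±0.02 for κ,
  ±0.05 for ICC) hold comfortably at fixed seeds while the whole suite
  runs in seconds.

## Known limitations

* The five operationally-defined indexes are reasonable defaults, not a
  canonical standard; in particular scapula inclination is computed as
  the left–right SIA line angle, and scoliosis as a max-segment
  deviation, both of which have defensible alternatives.
* Yaw sensitivity is inherent and asserted, not corrected; no rigid
  registration between test and reference systems is provided
  (relative accuracy exists precisely to avoid it).
* No temporal resampling: paired-system comparisons assume per-trial
  scalar measurements, not synchronized 120 Hz vs 30 Hz streams.
* The default optical-marker-to-joint mapping table is a documented,
  overridable stand-in (data, not algorithm); real deployments should
  supply their own.
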