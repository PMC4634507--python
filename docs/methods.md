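# Methods

This note records the model behind `facesym`, the choices made where the
design was genuinely open, and what the synthetic experiments do and do not
establish about real video.

## The measurement model

Input is a 49-point landmark trajectory (pixels, image convention with y
downward, 1-based indices) annotated with three disjoint motion segments:
rest, eyebrow raise, smile. All quantities are built from three plane
primitives — point-set centroid, Euclidean distance, and perpendicular
point-to-line distance — and from two aggregations: the mean over rest
frames and the maximum over motion frames.

Per side (left/right) and region (forehead/mouth) a distance series is
computed frame by frame:

| region   | geometry | distance per frame                                          |
|----------|----------|-------------------------------------------------------------|
| forehead | region   | brow centroid (P1–5 / P6–10) to eye centroid (P20–25 / P26–31) |
| forehead | axis     | brow centroid to the inter-canthal line through P23, P26    |
| mouth    | region   | mean distance of corner P32 / P38 to midline P35, P41, P45, P48 |
| mouth    | axis     | corner P32 / P38 to the perpendicular of the canthal line through EM |

The displacement is `|max(motion) − mean(rest)|` and the asymmetry index is
`min(r_left, r_right) / max(r_left, r_right)`. Distances are unit-free
ratios in the end, so image resolution is irrelevant; the test suite checks
scale and in-plane rigid invariance at 1e-9 instead of assuming them.

Numerical conventions:

* **0/0 displacement ratio → 1.0.** No measurable motion on either side is
  symmetric, not asymmetric. `degenerate="nan"` propagates NaN instead, for
  auditing pipelines that want to catch dead segments.
* **Exact ties → 1.0**, so floating-point equal displacements are stable.
* **Axes are recomputed every frame** (the head may drift); this is what
  makes in-plane invariance exact rather than approximate. A
  `freeze_axes_at_rest` flag reuses the first rest frame's axes for
  sensitivity analysis.
* **Coincident medial canthi** raise a degenerate-geometry error; there is
  no meaningful axis system in that case.
* "Left"/"right" are fixed labels of the mark-up. Every index is invariant
  under a global left/right relabelling (tested), so the anatomical
  assignment of the labels cannot change a classification.

## Classification

Features are 2D: (forehead index, mouth index) for one of the four geometry
combinations. Two linear classifiers are provided:

* **LDA**, solved in closed form: `w = S⁻¹(μ₁ − μ₀)` with the pooled
  within-class covariance `S` (n−2 denominator), bias from the class means
  plus the log prior ratio. Priors default to class frequencies
  (`priors="equal"` available). When `cond(S) > 1e10` a ridge of 1e-8 times
  the mean diagonal is added — needed only for degenerate toy data, never
  for realistic cohorts.
* **Linear SVM** via scikit-learn's `SVC(kernel="linear")`, C = 1.0 by
  default (deterministic for fixed data).

Evaluation is leave-one-out cross-validation with a single confusion matrix
pooled over folds — the convention that yields one accuracy/precision/recall
triple per table cell. Palsy is the positive class for the headline
precision/recall; both per-class breakdowns are always emitted because the
convention is not universal. A fold whose training set collapses to one
class is skipped with a warning and listed in the report. Undefined metric
denominators yield NaN with a warning rather than an exception.

## The synthetic cohort

Real palsy video datasets are rarely shareable, so the package generates
its own study conditions: 13 normal and 23 palsy subjects by default, with
palsy severities (motion-attenuation factors) drawn uniformly from
[0.1, 0.7], one affected side per subject. Frames come from the 2D shape
model `x = s·R·(base + Φ g) + t`, whose basis Φ holds the four per-side
motion fields (left/right × raise/smile) and whose coefficients ramp
linearly from 0 to the per-side amplitude across the motion segment (the
index only uses the max, so the ramp shape is free; linear is the most
analysable). Nuisance terms: i.i.d. Gaussian landmark noise (σ = 0.5 px at
the 100 px inter-ocular template scale — a plausible tracker error) and
per-frame similarity jitter (±1% scale, ±3° rotation, ±5 px translation)
emulating a handheld camera. Segments are 30 frames each at 30 fps.

Two template choices are deliberate and worth stating plainly:

* each eyebrow centroid lies exactly above its eye centroid and the raise
  motion is purely vertical (10 px);
* the four lip-midline landmarks are stacked at the mouth centre at the
  same image height as the corners, and the smile is a pure lateral corner
  excursion (7 px).

These make every distance the indices use *exactly linear* in motion
amplitude, so a noise-free palsy recording's index equals its assigned
severity to machine precision — the generator carries its own analytic
ground truth, and parameter-recovery tests can assert at 1e-9 instead of
eyeballing. The affected side attenuates brow and mouth motion by the same
factor (unilateral palsy affects both regions); per-region severities are a
one-line extension through `generate_recording`.

What the generator does **not** emulate: correlated tracker noise and
drift, initialization failures, out-of-plane head motion during recording,
inter-subject anatomy variation, or lip midline points dragged along by the
unaffected corner (a real phenomenon that degrades the mouth-region
geometry on patients). Passing tests therefore certify the *formulas and
machinery*, not clinical performance; cross-validated accuracies on this
cohort (≈0.97–1.0) say the pipeline separates what it was told to separate,
nothing more.

## The head-pose study

A mirror-symmetric 49-point 3D face (the 2D template lifted with a
plausible depth profile: nose ≈30 units forward, brow ridge 10, mouth
corners recessed to 2) performs mirror-symmetric raise and smile motions
while being rotated and orthographically projected. Axis convention: roll
about z (in-plane), pitch about x (nodding), yaw about y (head shake);
composition `R_pitch·R_yaw·R_roll` about the face centroid (sweeps are
single-axis, where order is immaterial). Because geometry and motion are
both symmetric, any index below 1 on the grid is a pure projection
artifact. Three facts are asserted by the tests:

* **roll** changes nothing (in-plane rigid invariance, to 1e-9 over the
  full ±30° sweep);
* **pitch** keeps a symmetric face at exactly 1.0 — rotation about x
  transforms mirror pairs identically, so symmetry survives projection;
* **yaw** fabricates asymmetry whenever motion has a depth component. The
  default smile pulls the corners 4 units posteriorly; under yaw θ the
  projected lateral displacement becomes `dx·cosθ ∓ dz·sinθ` on the two
  sides, driving the mouth-axis index from 1.0 at 0° to ≈0.50 at ±30°,
  while the forehead (motion purely vertical) stays at 1.0.

The 3D template is a synthetic stand-in — no published coordinates exist —
so the specific yaw angle at which a trained classifier flips to "palsy"
depends on the depth profile and the training cohort; only the ordering
(yaw ≫ pitch ≈ roll in harm) is a robust conclusion, and only that ordering
is asserted.

## Problem sizes and determinism

Defaults keep everything interactive: 36-subject cohorts of 90 frames,
61-cell single-axis pose sweeps (a 61×61 pitch-yaw grid is available
through `pose_grid`/`pose-sim`), and 1000 random recordings for the
formula-fidelity check. Every stochastic path takes a seed or
`numpy.random.Generator`; identical cohort specs reproduce trajectory files
byte for byte. `scripts/acceptance.py --seed N --out f.json` re-derives all
headline quantities from scratch in well under a minute.

## Known limitations

* The eye region is not analysed (eye closure is poorly captured by
  point displacement, and unilateral palsy shows in forehead/mouth anyway);
  severity is binary palsy/normal, not a multi-grade scale.
* The linear SVM is a thin wrapper over scikit-learn; only LDA exposes the
  closed-form weights for inspection.
* Orthographic projection ignores perspective; at smartphone distances the
  approximation is mild but unmodelled.
* The trajectory reader validates structure, not plausibility: a tracker
  that swaps left/right halfway through a recording will corrupt indices
  silently (the per-index swap symmetry only holds for a global,
  whole-recording swap).
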