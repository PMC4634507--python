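"""Synthetic landmark-trajectory cohorts for palsy-screening experiments.

Real facial-palsy video datasets are rarely shareable, so this module
generates labelled 49-point trajectories that emulate the study protocol:
every subject performs rest, eyebrow-raise and smile segments; normal
subjects move both sides equally, palsy subjects have the motion of one
(affected) side attenuated by a severity factor ``s`` in [0, 1).

Frames are produced through a 2D shape model

    x(p) = scale * R(theta) * (base + sum_k g_k * basis_k) + t

whose basis columns are the left/right brow-raise and smile motion fields;
the coefficients ``g`` ramp linearly from 0 to the per-side amplitude over
the motion segment.  Per-frame similarity jitter (scale/rotation/translation)
emulates handheld-camera drift and Gaussian noise emulates tracker error.

The template is laid out at a 100 px inter-ocular scale with two deliberate
geometric properties that make the generator analysable:

* each eyebrow centroid sits exactly above its eye centroid, and the raise
  motion is purely vertical;
* the four lip-midline landmarks are stacked at the mouth centre at the same
  image height as the mouth corners, and the smile motion is a pure lateral
  corner excursion.

Both choices make every distance the asymmetry indices use *exactly linear*
in the motion amplitude, so in the noise-free, jitter-free limit the
extracted asymmetry index of a palsy subject equals the assigned severity —
the generator carries its own analytic ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .landmarks import (
    InvalidInputError,
    LandmarkFrame,
    MotionSegment,
    Recording,
    load_recording,
    save_recording,
)

__all__ = [
    "RAISE_AMPLITUDE_PX",
    "SMILE_AMPLITUDE_PX",
    "default_template",
    "motion_fields_2d",
    "ShapeModelParams",
    "apply_shape_model",
    "CohortSpec",
    "generate_recording",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

#: Peak excursion of the brow during the raise motion, template pixels.
RAISE_AMPLITUDE_PX = 10.0
#: Peak lateral excursion of a mouth corner during the smile, template pixels.
SMILE_AMPLITUDE_PX = 7.0

# 49-point mean face, image coordinates (y downward), eyes on y = 0,
# mirror-symmetric about x = 0, inter-ocular distance 100 px.
_TEMPLATE = np.array([
    (-70, -25), (-60, -28), (-50, -30), (-40, -28), (-30, -25),   # 1-5 left brow
    (70, -25), (60, -28), (50, -30), (40, -28), (30, -25),        # 6-10 right brow
    (0, 5), (0, 15), (0, 25), (0, 35),                            # 11-14 nose bridge
    (-12, 45), (-6, 48), (0, 50), (6, 48), (12, 45),              # 15-19 nostrils
    (-68, 0), (-58, -5), (-42, -5), (-32, 0), (-42, 5), (-58, 5), # 20-25 left eye
    (32, 0), (42, -5), (58, -5), (68, 0), (58, 5), (42, 5),       # 26-31 right eye
    (-35, 75), (-22, 69), (-10, 66), (0, 75), (10, 66), (22, 69), # 32-37 outer lip
    (35, 75), (22, 82), (10, 85), (0, 75), (-10, 85), (-22, 82),  # 38-43 outer lip
    (-15, 74), (0, 75), (15, 74), (15, 78), (0, 75), (-15, 78),   # 44-49 inner lip
], dtype=float)


def default_template() -> np.ndarray:
    """The (49, 2) mirror-symmetric mean face, 100 px inter-ocular scale."""
    return _TEMPLATE.copy()


def motion_fields_2d() -> dict:
    """Per-side 2D motion fields, (49, 2) each, at unit amplitude coefficient.

    ``raise_left``/``raise_right`` lift the five brow points of one side
    straight up; ``smile_left``/``smile_right`` pull the mouth corner (and,
    for realism, its two outer-lip neighbours at half strength) laterally
    outward.
    """
    fields = {k: np.zeros((49, 2)) for k in
              ("raise_left", "raise_right", "smile_left", "smile_right")}
    for i in range(1, 6):          # left brow points 1-5
        fields["raise_left"][i - 1] = (0.0, -RAISE_AMPLITUDE_PX)
    for i in range(6, 11):         # right brow points 6-10
        fields["raise_right"][i - 1] = (0.0, -RAISE_AMPLITUDE_PX)
    fields["smile_left"][32 - 1] = (-SMILE_AMPLITUDE_PX, 0.0)
    fields["smile_left"][33 - 1] = (-SMILE_AMPLITUDE_PX / 2, 0.0)
    fields["smile_left"][43 - 1] = (-SMILE_AMPLITUDE_PX / 2, 0.0)
    fields["smile_right"][38 - 1] = (SMILE_AMPLITUDE_PX, 0.0)
    fields["smile_right"][37 - 1] = (SMILE_AMPLITUDE_PX / 2, 0.0)
    fields["smile_right"][39 - 1] = (SMILE_AMPLITUDE_PX / 2, 0.0)
    return fields


@dataclass(frozen=True)
class ShapeModelParams:
    """Similarity pose plus non-rigid coefficients of the 2D shape model."""

    scale: float = 1.0
    rotation: float = 0.0           # radians, counter-clockwise in (x, y)
    translation: tuple = (0.0, 0.0)
    coeffs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    basis: np.ndarray = field(default_factory=lambda: np.zeros((0, 49, 2)))

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InvalidInputError("shape-model scale must be positive")
        g = np.asarray(self.coeffs, dtype=float)
        B = np.asarray(self.basis, dtype=float)
        if B.ndim != 3 or B.shape[1:] != (49, 2):
            raise InvalidInputError("basis must have shape (k, 49, 2)")
        if g.shape != (B.shape[0],):
            raise InvalidInputError(
                f"{g.shape[0] if g.ndim == 1 else g.shape} coefficients do not "
                f"match a {B.shape[0]}-column basis"
            )
        object.__setattr__(self, "coeffs", g)
        object.__setattr__(self, "basis", B)


def apply_shape_model(base: np.ndarray, params: ShapeModelParams) -> LandmarkFrame:
    """Instantiate the shape model: scale * R * (base + basis @ g) + t."""
    base = np.asarray(base, dtype=float)
    if base.shape != (49, 2):
        raise InvalidInputError(f"base shape must be (49, 2), got {base.shape}")
    shape = base
    if params.coeffs.size:
        shape = shape + np.tensordot(params.coeffs, params.basis, axes=1)
    c, s = np.cos(params.rotation), np.sin(params.rotation)
    R = np.array([[c, -s], [s, c]])
    pts = params.scale * (shape @ R.T) + np.asarray(params.translation, dtype=float)
    return LandmarkFrame(points=pts)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror a 36-subject clinical screen: 13 normals and 23 palsy
    subjects with severities drawn uniformly from [0.1, 0.7], tracker noise
    of 0.5 px at the 100 px inter-ocular template scale, and mild handheld
    jitter (1% scale, 3 degrees rotation, 5 px translation per frame).
    Segments are one second each at 30 fps.
    """

    n_normal: int = 13
    n_palsy: int = 23
    severity_min: float = 0.1
    severity_max: float = 0.7
    affected_side: str = "random"      # left | right | random
    noise_sigma: float = 0.5           # px, i.i.d. Gaussian per point per frame
    jitter_scale: float = 0.01         # max fractional per-frame scale change
    jitter_rotation_deg: float = 3.0   # max per-frame in-plane rotation
    jitter_translation_px: float = 5.0
    n_rest: int = 30
    n_motion: int = 30
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_palsy < 0:
            raise InvalidInputError("cohort counts must be nonnegative")
        if not (0.0 <= self.severity_min <= self.severity_max < 1.0):
            raise InvalidInputError("severity range must satisfy 0 <= min <= max < 1")
        if self.affected_side not in ("left", "right", "random"):
            raise InvalidInputError("affected_side must be left, right or random")
        if self.noise_sigma < 0 or min(self.jitter_scale, self.jitter_rotation_deg,
                                       self.jitter_translation_px) < 0:
            raise InvalidInputError("noise and jitter magnitudes must be nonnegative")
        if self.n_rest < 1 or self.n_motion < 1:
            raise InvalidInputError("segments need at least one frame")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidInputError(f"unknown cohort-spec keys: {sorted(unknown)}")
        return cls(**d)


def _jitter_params(spec: CohortSpec, rng, coeffs, basis) -> ShapeModelParams:
    return ShapeModelParams(
        scale=1.0 + rng.uniform(-spec.jitter_scale, spec.jitter_scale),
        rotation=np.deg2rad(rng.uniform(-spec.jitter_rotation_deg,
                                        spec.jitter_rotation_deg)),
        translation=tuple(rng.uniform(-spec.jitter_translation_px,
                                      spec.jitter_translation_px, size=2)),
        coeffs=coeffs,
        basis=basis,
    )


def generate_recording(
    spec: CohortSpec,
    subject_label: str,
    severity: float = 1.0,
    affected_side: str | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "synthetic",
) -> Recording:
    """One subject's rest / raise / smile trajectory.

    ``severity`` is the motion-attenuation factor of the affected side: a
    palsy subject's affected brow and mouth corner move ``severity`` times
    as far as the unaffected side.  Normals ignore it (both sides at full
    amplitude).  In the noise-free, jitter-free limit the extracted
    asymmetry index equals ``severity`` exactly.
    """
    if subject_label not in ("normal", "palsy"):
        raise InvalidInputError("subject_label must be 'normal' or 'palsy'")
    if subject_label == "palsy" and not (0.0 <= severity < 1.0):
        raise InvalidInputError("palsy severity must lie in [0, 1)")
    rng = np.random.default_rng(0) if rng is None else rng
    side = affected_side or spec.affected_side
    if side == "random":
        side = "left" if rng.random() < 0.5 else "right"

    fields = motion_fields_2d()
    basis = np.stack([fields["raise_left"], fields["raise_right"],
                      fields["smile_left"], fields["smile_right"]])
    if subject_label == "normal":
        amp_left = amp_right = 1.0
    else:
        amp_left = severity if side == "left" else 1.0
        amp_right = severity if side == "right" else 1.0

    base = default_template()
    frames = []

    def emit(coeffs):
        noisy = base + (rng.normal(0.0, spec.noise_sigma, size=(49, 2))
                        if spec.noise_sigma > 0 else 0.0)
        frame = apply_shape_model(noisy, _jitter_params(spec, rng, coeffs, basis))
        frames.append(LandmarkFrame(points=frame.points, frame_index=len(frames)))

    for _ in range(spec.n_rest):
        emit(np.zeros(4))
    for i in range(spec.n_motion):           # brow raise, linear ramp to peak
        t = (i + 1) / spec.n_motion
        emit(np.array([t * amp_left, t * amp_right, 0.0, 0.0]))
    for i in range(spec.n_motion):           # smile
        t = (i + 1) / spec.n_motion
        emit(np.array([0.0, 0.0, t * amp_left, t * amp_right]))

    segments = {
        "rest": MotionSegment("rest", 0, spec.n_rest),
        "raise": MotionSegment("raise", spec.n_rest, spec.n_rest + spec.n_motion),
        "smile": MotionSegment("smile", spec.n_rest + spec.n_motion,
                               spec.n_rest + 2 * spec.n_motion),
    }
    return Recording(
        subject_id=subject_id,
        frames=frames,
        segments=segments,
        class_label=subject_label,
        fps=spec.fps,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list, dict]:
    """All recordings of a cohort plus a manifest of assigned ground truth.

    Deterministic: the same spec (including seed) reproduces the cohort
    byte for byte.
    """
    rng = np.random.default_rng(spec.seed)
    recordings, subjects = [], []
    for i in range(spec.n_normal):
        sid = f"normal_{i + 1:02d}"
        recordings.append(generate_recording(spec, "normal", rng=rng, subject_id=sid))
        subjects.append({"subject_id": sid, "label": "normal",
                         "severity": 1.0, "affected_side": None})
    for i in range(spec.n_palsy):
        sid = f"palsy_{i + 1:02d}"
        severity = float(rng.uniform(spec.severity_min, spec.severity_max))
        side = spec.affected_side
        if side == "random":
            side = "left" if rng.random() < 0.5 else "right"
        recordings.append(
            generate_recording(spec, "palsy", severity=severity,
                               affected_side=side, rng=rng, subject_id=sid)
        )
        subjects.append({"subject_id": sid, "label": "palsy",
                         "severity": severity, "affected_side": side})
    manifest = {"spec": spec.to_dict(), "subjects": subjects}
    return recordings, manifest


def write_cohort(recordings, manifest: dict, outdir) -> None:
    """Write per-subject trajectory CSV + segment JSON files and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        save_recording(rec,
                       outdir / f"{rec.subject_id}_trajectory.csv",
                       outdir / f"{rec.subject_id}_segments.json")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_cohort(indir) -> tuple[list, dict]:
    """Read a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    recordings = []
    for subj in manifest["subjects"]:
        sid = subj["subject_id"]
        recordings.append(
            load_recording(indir / f"{sid}_trajectory.csv",
                           indir / f"{sid}_segments.json")
        )
    return recordings, manifest
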