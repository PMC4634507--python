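"""Head-orientation robustness study on a synthetic 3D face.

The asymmetry indices are computed from a 2D projection of a 3D face, so
out-of-plane head rotation can masquerade as facial asymmetry.  This module
quantifies that failure mode: a mirror-symmetric 49-point 3D face with
mirror-symmetric motion fields is rotated through roll / pitch / yaw,
orthographically projected onto the image plane, and the resulting 2D
trajectory is pushed through the normal feature-extraction and
classification pipeline.  Because face *and* motion are perfectly
symmetric, any "palsy" call on the grid is purely a projection artifact.

Axis convention (right-handed, image coordinates, z toward the camera):
roll is the in-plane rotation about z, pitch the nodding rotation about x,
yaw the head-shake rotation about y.  Composition is fixed as
``R = R_pitch @ R_yaw @ R_roll`` about the face centroid (the study sweeps
one axis at a time, where the order is immaterial).

Three analytic facts anchor the study and are enforced by the test suite:
roll changes nothing (the indices are rigid-invariant in-plane); pitch
changes nothing on a symmetric face (rotation about x maps mirror pairs
identically); yaw breaks symmetry whenever motion has a depth component,
because the side turning toward the camera projects a larger displacement.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import default_template
from .features import extract_features
from .landmarks import (
    LEFT_RIGHT_PAIRS,
    MIDLINE_POINTS,
    InvalidInputError,
    LandmarkFrame,
    MotionSegment,
    Recording,
)

__all__ = [
    "Face3D",
    "default_face3d",
    "rotation_matrix",
    "rotate3d",
    "project",
    "synthesize_recording",
    "pose_grid",
    "write_grid",
    "read_grid",
    "plot_pose_grid",
]

DEFAULT_ANGLES = tuple(range(-30, 31))  # degrees, 1 degree steps
AXES = ("roll", "pitch", "yaw")


def _check_mirror(points: np.ndarray, tol: float, what: str) -> None:
    # left = (-x, y, z) of right; midline points have x = 0
    for li, ri in LEFT_RIGHT_PAIRS:
        l, r = points[li - 1], points[ri - 1]
        mirrored = r.copy()
        mirrored[0] = -mirrored[0]
        if np.max(np.abs(l - mirrored)) > tol:
            raise InvalidInputError(
                f"{what}: points {li}/{ri} are not mirror images about x=0"
            )
    for mi in MIDLINE_POINTS:
        if abs(points[mi - 1, 0]) > tol:
            raise InvalidInputError(f"{what}: midline point {mi} has nonzero x")


@dataclass(frozen=True)
class Face3D:
    """A mirror-symmetric 49-point 3D face template with motion fields.

    ``points`` is (49, 3); ``motion_fields`` maps ``"raise"`` and ``"smile"``
    to (49, 3) displacement fields at unit amplitude.  Mirror symmetry about
    the x = 0 plane is validated for the geometry and for every motion
    field; the depth coordinate must vary across points (a planar face
    cannot exhibit the yaw artifact this module studies).
    """

    points: np.ndarray
    motion_fields: dict
    tol: float = 1e-9

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (49, 3):
            raise InvalidInputError(f"Face3D needs (49, 3) points, got {pts.shape}")
        _check_mirror(pts, self.tol, "Face3D geometry")
        if np.ptp(pts[:, 2]) == 0.0:
            raise InvalidInputError("Face3D must be non-planar (z must vary)")
        fields = {}
        for label in ("raise", "smile"):
            if label not in self.motion_fields:
                raise InvalidInputError(f"Face3D lacks the {label!r} motion field")
            f = np.asarray(self.motion_fields[label], dtype=float)
            if f.shape != (49, 3):
                raise InvalidInputError(f"motion field {label!r} must be (49, 3)")
            _check_mirror(f, self.tol, f"motion field {label!r}")
            fields[label] = f
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "motion_fields", fields)


# depth profile (z, toward camera) of the default template, per landmark
_DEPTH = np.zeros(49)
_DEPTH[0:10] = 10.0                       # brow ridge forward of the canthi
_DEPTH[10:14] = (12.0, 18.0, 24.0, 30.0)  # nose bridge
_DEPTH[14:19] = (18.0, 24.0, 28.0, 24.0, 18.0)  # nostrils
_DEPTH[19] = _DEPTH[28] = -2.0            # lateral eye corners recede
_DEPTH[31] = _DEPTH[37] = 2.0             # mouth corners recessed vs lips
_DEPTH[32] = _DEPTH[36] = 7.0
_DEPTH[33] = _DEPTH[35] = 10.0
_DEPTH[34] = _DEPTH[40] = 12.0
_DEPTH[38] = _DEPTH[42] = 7.0
_DEPTH[39] = _DEPTH[41] = 10.0
_DEPTH[43] = _DEPTH[45] = 10.0
_DEPTH[44] = _DEPTH[47] = 12.0
_DEPTH[46] = _DEPTH[48] = 10.0


def default_face3d() -> Face3D:
    """The package's synthetic 3D face (synthetic stand-in; no published
    template exists): the 2D mean face lifted with a plausible depth
    profile, plus symmetric raise and smile motion fields.

    The smile pulls the mouth corners laterally, slightly upward and
    *posteriorly* (corners retract toward the face), which is the depth
    component that makes the mouth index yaw-sensitive.
    """
    pts = np.column_stack([default_template(), _DEPTH])
    raise_field = np.zeros((49, 3))
    raise_field[0:10] = (0.0, -10.0, 0.0)      # both brows straight up

    smile = np.zeros((49, 3))
    smile[32 - 1] = (-7.0, -5.0, -4.0)         # left corner: out, up, back
    smile[38 - 1] = (7.0, -5.0, -4.0)
    smile[33 - 1] = (-3.5, -2.5, -2.0)
    smile[37 - 1] = (3.5, -2.5, -2.0)
    smile[43 - 1] = (-3.5, -2.5, -2.0)
    smile[39 - 1] = (3.5, -2.5, -2.0)
    return Face3D(points=pts, motion_fields={"raise": raise_field, "smile": smile})


def rotation_matrix(roll: float = 0.0, pitch: float = 0.0, yaw: float = 0.0) -> np.ndarray:
    """Right-handed rotation matrix, angles in degrees, R = Rx(pitch) Ry(yaw) Rz(roll)."""
    r, p, y = np.deg2rad([roll, pitch, yaw])
    cr, sr = np.cos(r), np.sin(r)
    cp, sp = np.cos(p), np.sin(p)
    cy, sy = np.cos(y), np.sin(y)
    Rz = np.array([[cr, -sr, 0], [sr, cr, 0], [0, 0, 1]])
    Rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return Rx @ Ry @ Rz


def rotate3d(
    points: np.ndarray,
    roll: float = 0.0,
    pitch: float = 0.0,
    yaw: float = 0.0,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Rotate a 3D point cloud about ``center`` (default: its centroid)."""
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite([roll, pitch, yaw])):
        raise InvalidInputError("rotation angles must be finite")
    c = pts.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    R = rotation_matrix(roll, pitch, yaw)
    return (pts - c) @ R.T + c


def project(points: np.ndarray) -> LandmarkFrame:
    """Orthographic projection onto the image plane: drop z, keep (x, y)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape != (49, 3):
        raise InvalidInputError(f"project expects (49, 3) points, got {pts.shape}")
    return LandmarkFrame(points=pts[:, :2])


def synthesize_recording(
    face: Face3D,
    roll: float = 0.0,
    pitch: float = 0.0,
    yaw: float = 0.0,
    n_rest: int = 3,
    n_motion: int = 8,
) -> Recording:
    """Rotate-and-project the face while it performs both motions.

    Rest frames are the rotated neutral face; the raise and smile segments
    ramp the corresponding motion field linearly from 0 to full amplitude
    before rotation and projection.  Rotation is about the neutral-face
    centroid for every frame.
    """
    if n_rest < 1 or n_motion < 1:
        raise InvalidInputError("segments need at least one frame")
    center = face.points.mean(axis=0)
    frames = []

    def emit(points3d):
        rotated = rotate3d(points3d, roll, pitch, yaw, center=center)
        frames.append(LandmarkFrame(points=project(rotated).points,
                                    frame_index=len(frames)))

    for _ in range(n_rest):
        emit(face.points)
    for label in ("raise", "smile"):
        for i in range(n_motion):
            t = (i + 1) / n_motion
            emit(face.points + t * face.motion_fields[label])

    segments = {
        "rest": MotionSegment("rest", 0, n_rest),
        "raise": MotionSegment("raise", n_rest, n_rest + n_motion),
        "smile": MotionSegment("smile", n_rest + n_motion, n_rest + 2 * n_motion),
    }
    return Recording(subject_id="face3d", frames=frames, segments=segments,
                     class_label="normal", fps=30.0)


def pose_grid(
    face: Face3D,
    classifier,
    axes: Sequence[str] = ("yaw",),
    angles: Sequence[float] = DEFAULT_ANGLES,
    combo: str = "forehead_region+mouth_axis",
    n_rest: int = 3,
    n_motion: int = 8,
) -> pd.DataFrame:
    """Sweep one or two rotation axes and classify every orientation.

    Returns a table with columns roll, pitch, yaw, forehead_index,
    mouth_index, predicted_label; un-swept axes stay at 0 degrees.
    """
    if classifier is None or not hasattr(classifier, "predict"):
        raise InvalidInputError("pose_grid needs a fitted classifier")
    bad = [a for a in axes if a not in AXES]
    if bad:
        raise InvalidInputError(f"unknown rotation axes {bad}; choose from {AXES}")
    if len(axes) not in (1, 2):
        raise InvalidInputError("sweep one or two axes")
    angles = list(angles)
    if angles and (min(angles) < -30 or max(angles) > 30):
        warnings.warn("sweep extends beyond +/-30 degrees", stacklevel=2)

    grids = [angles] * len(axes)
    rows = []
    for combo_angles in itertools.product(*grids):
        cell = {"roll": 0.0, "pitch": 0.0, "yaw": 0.0}
        for axis, angle in zip(axes, combo_angles):
            cell[axis] = float(angle)
        rec = synthesize_recording(face, cell["roll"], cell["pitch"], cell["yaw"],
                                   n_rest=n_rest, n_motion=n_motion)
        feats = extract_features(rec, combo)
        pred = classifier.predict(feats.as_array().reshape(1, -1))[0]
        rows.append({**cell,
                     "forehead_index": feats.forehead_index,
                     "mouth_index": feats.mouth_index,
                     "predicted_label": str(pred)})
    return pd.DataFrame(rows, columns=["roll", "pitch", "yaw", "forehead_index",
                                       "mouth_index", "predicted_label"])


def write_grid(path, grid: pd.DataFrame) -> None:
    grid.to_csv(path, index=False, float_format="%.12g")


def read_grid(path) -> pd.DataFrame:
    return pd.read_csv(path)


def plot_pose_grid(grid: pd.DataFrame, path, axes: Sequence[str] = ("pitch", "yaw")) -> None:
    """Correct/wrong map of a two-axis sweep: blue where the symmetric face is
    classified normal, red where projection artifacts flip the call."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax_a, ax_b = axes
    pivot = grid.pivot_table(index=ax_a, columns=ax_b, values="predicted_label",
                             aggfunc=lambda s: float(np.mean(s == "normal")))
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        pivot.to_numpy(), origin="lower", cmap="bwr_r", vmin=0.0, vmax=1.0,
        extent=(pivot.columns.min(), pivot.columns.max(),
                pivot.index.min(), pivot.index.max()),
        aspect="auto",
    )
    ax.set_xlabel(f"{ax_b} (deg)")
    ax.set_ylabel(f"{ax_a} (deg)")
    ax.set_title("Classification of a symmetric face under head rotation")
    fig.colorbar(im, ax=ax, label="fraction classified normal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
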