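"""Bilateral asymmetry indices of the forehead and mouth regions.

The asymmetry index of a facial region compares how far the left and the
right side move during a voluntary motion (eyebrow raise for the forehead,
smile for the mouth).  For each side a per-frame distance is measured, the
motion displacement is ``|max over motion frames - mean over rest frames|``,
and the index is the smaller displacement divided by the larger one:
1 means perfectly symmetric motion, 0 a completely immobile side.

Two geometries are provided per region:

* **region** (local-points based): the forehead distance is between the
  eyebrow centroid and the eye centroid of the same side; the mouth distance
  is the mean distance from the mouth corner to the four lip-midline
  landmarks (P35, P41, P45, P48).
* **axis** based: a horizontal reference line is drawn through the two
  medial canthi (P23, P26) and a vertical line perpendicular to it through
  their midpoint EM.  The forehead distance is from the eyebrow centroid to
  the horizontal line; the mouth distance from the mouth corner to the
  vertical line.

The four combinations of forehead/mouth geometry form a 2D feature vector
per subject; all of them are ratios of distances and therefore invariant
under global scaling and under in-plane rigid motion of the face.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landmarks import (
    LEFT_BROW,
    LEFT_EYE,
    LEFT_MEDIAL_CANTHUS,
    LEFT_MOUTH_CORNER,
    MOUTH_MIDLINE,
    RIGHT_BROW,
    RIGHT_EYE,
    RIGHT_MEDIAL_CANTHUS,
    RIGHT_MOUTH_CORNER,
    DegenerateGeometryError,
    InvalidInputError,
    LandmarkFrame,
    Line2D,
    Recording,
    centroid,
    euclidean,
    point_line_distance,
)

__all__ = [
    "COMBOS",
    "SideDistances",
    "SideDisplacements",
    "AsymmetryFeatures",
    "FaceAxes",
    "parse_combo",
    "combo_name",
    "brow_eye_distances",
    "mouth_corner_distances",
    "face_axes",
    "axis_brow_distances",
    "axis_mouth_distances",
    "displacement",
    "symmetry_ratio",
    "extract_features",
    "extract_feature_table",
    "write_feature_table",
    "read_feature_table",
]

GEOMETRIES = ("region", "axis")

#: The four forehead/mouth geometry combinations, in canonical spelling.
COMBOS = (
    "forehead_axis+mouth_axis",
    "forehead_axis+mouth_region",
    "forehead_region+mouth_axis",
    "forehead_region+mouth_region",
)


def parse_combo(name: str) -> tuple[str, str]:
    """Split a combination name into (forehead geometry, mouth geometry).

    Accepts the canonical ``forehead_region+mouth_axis`` spelling as well as
    variants differing in case, spaces around '+', or '_' vs no separator.
    """
    norm = name.strip().lower().replace(" ", "")
    try:
        fore, mouth = norm.split("+")
        fkind = fore.removeprefix("forehead").lstrip("_")
        mkind = mouth.removeprefix("mouth").lstrip("_")
    except ValueError:
        raise InvalidInputError(f"cannot parse combination name {name!r}") from None
    if fkind not in GEOMETRIES or mkind not in GEOMETRIES:
        raise InvalidInputError(
            f"combination {name!r} must pair forehead and mouth geometries "
            f"from {GEOMETRIES}"
        )
    return fkind, mkind


def combo_name(forehead_geometry: str, mouth_geometry: str) -> str:
    return f"forehead_{forehead_geometry}+mouth_{mouth_geometry}"


@dataclass(frozen=True)
class SideDistances:
    """A left/right pair of per-frame distances, in pixels."""

    left: float
    right: float
    kind: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.left) and np.isfinite(self.right)):
            raise InvalidInputError("side distances must be finite")
        if self.left < 0 or self.right < 0:
            raise InvalidInputError("side distances must be nonnegative")


@dataclass(frozen=True)
class SideDisplacements:
    """Left/right motion displacements (absolute values), in pixels."""

    left: float
    right: float
    region: str
    geometry: str

    def __post_init__(self) -> None:
        if self.left < 0 or self.right < 0:
            raise InvalidInputError("displacements are absolute values, must be >= 0")


@dataclass(frozen=True)
class AsymmetryFeatures:
    """The (forehead index, mouth index) pair for one recording and combo."""

    forehead_index: float
    mouth_index: float
    combo: str

    def __post_init__(self) -> None:
        for v in (self.forehead_index, self.mouth_index):
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise InvalidInputError(f"asymmetry index {v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.forehead_index, self.mouth_index], dtype=float)


@dataclass(frozen=True)
class FaceAxes:
    """The inter-canthal horizontal line, its perpendicular, and midpoint EM."""

    horizontal: Line2D
    vertical: Line2D
    em: np.ndarray


# ---------------------------------------------------------------------------
# per-frame distances
# ---------------------------------------------------------------------------

def brow_eye_distances(frame: LandmarkFrame) -> SideDistances:
    """Distance between eyebrow centroid and eye centroid, per side."""
    left = euclidean(centroid(frame.take(LEFT_BROW)), centroid(frame.take(LEFT_EYE)))
    right = euclidean(centroid(frame.take(RIGHT_BROW)), centroid(frame.take(RIGHT_EYE)))
    return SideDistances(left=left, right=right, kind="forehead_region")


def mouth_corner_distances(frame: LandmarkFrame) -> SideDistances:
    """Mean distance from each mouth corner to the four lip-midline landmarks."""
    midline = frame.take(MOUTH_MIDLINE)
    lc = frame.point(LEFT_MOUTH_CORNER)
    rc = frame.point(RIGHT_MOUTH_CORNER)
    left = float(np.mean([euclidean(lc, m) for m in midline]))
    right = float(np.mean([euclidean(rc, m) for m in midline]))
    return SideDistances(left=left, right=right, kind="mouth_region")


def face_axes(frame: LandmarkFrame) -> FaceAxes:
    """Reference axes: the line through the medial canthi and its perpendicular
    through the inter-canthal midpoint EM."""
    p23 = frame.point(LEFT_MEDIAL_CANTHUS)
    p26 = frame.point(RIGHT_MEDIAL_CANTHUS)
    d = p26 - p23
    if np.linalg.norm(d) == 0.0:
        raise DegenerateGeometryError(
            "medial canthi coincide; the face axes are undefined"
        )
    em = (p23 + p26) / 2.0
    horizontal = Line2D(point=em, direction=d)
    # 90 degree rotation of the horizontal direction
    perp = np.array([-horizontal.direction[1], horizontal.direction[0]])
    vertical = Line2D(point=em, direction=perp)
    return FaceAxes(horizontal=horizontal, vertical=vertical, em=em)


def axis_brow_distances(frame: LandmarkFrame, axes: FaceAxes | None = None) -> SideDistances:
    """Perpendicular distance from each eyebrow centroid to the horizontal axis."""
    axes = axes if axes is not None else face_axes(frame)
    left = point_line_distance(centroid(frame.take(LEFT_BROW)), axes.horizontal)
    right = point_line_distance(centroid(frame.take(RIGHT_BROW)), axes.horizontal)
    return SideDistances(left=left, right=right, kind="forehead_axis")


def axis_mouth_distances(frame: LandmarkFrame, axes: FaceAxes | None = None) -> SideDistances:
    """Perpendicular distance from each mouth corner to the vertical axis."""
    axes = axes if axes is not None else face_axes(frame)
    left = point_line_distance(frame.point(LEFT_MOUTH_CORNER), axes.vertical)
    right = point_line_distance(frame.point(RIGHT_MOUTH_CORNER), axes.vertical)
    return SideDistances(left=left, right=right, kind="mouth_axis")


# ---------------------------------------------------------------------------
# displacement and ratio
# ---------------------------------------------------------------------------

def displacement(rest_values: Sequence[float], motion_values: Sequence[float]) -> float:
    """|max of the motion-segment distances - mean of the rest distances|."""
    rest = np.asarray(rest_values, dtype=float)
    motion = np.asarray(motion_values, dtype=float)
    if rest.size == 0 or motion.size == 0:
        raise InvalidInputError("displacement needs non-empty rest and motion series")
    return float(abs(motion.max() - rest.mean()))


def symmetry_ratio(left: float, right: float, degenerate: str = "one") -> float:
    """Smaller displacement over larger displacement, in [0, 1].

    Equal displacements (including both zero when ``degenerate='one'``)
    give 1.0: no motion on either side is symmetric, not asymmetric.  With
    ``degenerate='nan'`` the 0/0 case propagates NaN for auditing.
    """
    if left < 0 or right < 0:
        raise InvalidInputError("displacements must be nonnegative")
    if degenerate not in ("one", "nan"):
        raise InvalidInputError("degenerate mode must be 'one' or 'nan'")
    if left == right == 0.0:
        return 1.0 if degenerate == "one" else float("nan")
    if left > right:
        return right / left
    return left / right


_FOREHEAD_FNS = {"region": brow_eye_distances, "axis": axis_brow_distances}
_MOUTH_FNS = {"region": mouth_corner_distances, "axis": axis_mouth_distances}
_MOTION_FOR_REGION = {"forehead": "raise", "mouth": "smile"}


def _distance_series(frames, fn, axes_fn) -> tuple[np.ndarray, np.ndarray]:
    lefts = np.empty(len(frames))
    rights = np.empty(len(frames))
    for i, frame in enumerate(frames):
        sd = fn(frame, axes_fn(frame)) if axes_fn is not None else fn(frame)
        lefts[i] = sd.left
        rights[i] = sd.right
    return lefts, rights


def extract_features(
    recording: Recording,
    combo: str = "forehead_region+mouth_axis",
    degenerate: str = "one",
    freeze_axes_at_rest: bool = False,
) -> AsymmetryFeatures:
    """Compute the (forehead, mouth) asymmetry indices of one recording.

    Parameters
    ----------
    recording
        Landmark trajectory with rest / raise / smile segments.
    combo
        Which geometry to use per region, e.g. ``"forehead_region+mouth_axis"``.
    degenerate
        How a 0/0 displacement ratio is reported (``"one"`` or ``"nan"``).
    freeze_axes_at_rest
        By default the canthal axes are recomputed in every frame, which
        makes the indices exactly invariant to in-plane head motion.  When
        True, the axes of the first rest frame are reused for all frames
        (sensitivity analysis for a head held still).
    """
    fkind, mkind = parse_combo(combo)
    frozen = face_axes(recording.frames_for("rest")[0]) if freeze_axes_at_rest else None

    indices = {}
    for region, kind, fns in (
        ("forehead", fkind, _FOREHEAD_FNS),
        ("mouth", mkind, _MOUTH_FNS),
    ):
        fn = fns[kind]
        needs_axes = kind == "axis"
        if needs_axes:
            axes_fn = (lambda f: frozen) if frozen is not None else face_axes
        else:
            axes_fn = None
        rest_l, rest_r = _distance_series(recording.frames_for("rest"), fn, axes_fn)
        motion_label = _MOTION_FOR_REGION[region]
        mot_l, mot_r = _distance_series(recording.frames_for(motion_label), fn, axes_fn)
        disp = SideDisplacements(
            left=displacement(rest_l, mot_l),
            right=displacement(rest_r, mot_r),
            region=region,
            geometry=kind,
        )
        indices[region] = symmetry_ratio(disp.left, disp.right, degenerate=degenerate)

    return AsymmetryFeatures(
        forehead_index=indices["forehead"],
        mouth_index=indices["mouth"],
        combo=combo_name(fkind, mkind),
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def extract_feature_table(
    recordings: Iterable[Recording],
    combos: Sequence[str] = COMBOS,
    degenerate: str = "one",
    freeze_axes_at_rest: bool = False,
) -> pd.DataFrame:
    """One row per recording per combination: subject_id, combo, indices, label."""
    rows = []
    for rec in recordings:
        for combo in combos:
            feats = extract_features(
                rec, combo, degenerate=degenerate,
                freeze_axes_at_rest=freeze_axes_at_rest,
            )
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "combo": feats.combo,
                    "forehead_index": feats.forehead_index,
                    "mouth_index": feats.mouth_index,
                    "label": rec.class_label,
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "combo", "forehead_index", "mouth_index", "label"]
    )


def write_feature_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "combo", "forehead_index", "mouth_index", "label"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"feature table {path} must have columns {sorted(required)}")
    return df
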