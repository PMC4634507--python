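"""49-point facial landmark data model, indexing conventions and plane geometry.

The package works on the standard 49-point facial mark-up (the 68-point
iBUG annotation with the 17 face-contour points and the two inner mouth
corners dropped).  Landmark indices are 1-based at every public boundary,
matching the conventional figure labels (P23 = left medial canthus, P32 =
left mouth corner, ...).  Coordinates follow the image convention: x grows
rightward, y grows *downward*; every quantity derived from them is a
distance, so the choice is visible only in fixtures and documentation.

Index map
---------
==================  ==========
left eyebrow        1-5
right eyebrow       6-10
nose                11-19
left eye            20-25 (medial canthus 23)
right eye           26-31 (medial canthus 26)
mouth, outer lip    32-43 (left corner 32, right corner 38)
mouth, inner lip    44-49
lip midline         35, 41, 45, 48
==================  ==========

"Left"/"right" are fixed labels of the annotation scheme; every downstream
asymmetry ratio is symmetric under a global left/right swap, so whether the
labels are image-left or subject-left never affects a result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_POINTS",
    "LEFT_BROW",
    "RIGHT_BROW",
    "LEFT_EYE",
    "RIGHT_EYE",
    "LEFT_MEDIAL_CANTHUS",
    "RIGHT_MEDIAL_CANTHUS",
    "LEFT_MOUTH_CORNER",
    "RIGHT_MOUTH_CORNER",
    "MOUTH_MIDLINE",
    "LEFT_RIGHT_PAIRS",
    "MIDLINE_POINTS",
    "SEGMENT_LABELS",
    "InvalidInputError",
    "DegenerateGeometryError",
    "LandmarkFrame",
    "MotionSegment",
    "Recording",
    "Line2D",
    "centroid",
    "euclidean",
    "point_line_distance",
    "swap_left_right",
    "read_trajectory",
    "write_trajectory",
    "read_segments",
    "write_segments",
    "load_recording",
    "save_recording",
]

N_POINTS = 49

LEFT_BROW = tuple(range(1, 6))
RIGHT_BROW = tuple(range(6, 11))
NOSE = tuple(range(11, 20))
LEFT_EYE = tuple(range(20, 26))
RIGHT_EYE = tuple(range(26, 32))
LEFT_MEDIAL_CANTHUS = 23
RIGHT_MEDIAL_CANTHUS = 26
LEFT_MOUTH_CORNER = 32
RIGHT_MOUTH_CORNER = 38
MOUTH_MIDLINE = (35, 41, 45, 48)

#: Mirror pairs (left index, right index) of the mark-up.  Points not listed
#: lie on the facial midline and map to themselves under a left/right swap.
LEFT_RIGHT_PAIRS = (
    (1, 6), (2, 7), (3, 8), (4, 9), (5, 10),          # brows
    (15, 19), (16, 18),                                # nostrils
    (20, 29), (21, 28), (22, 27), (23, 26), (24, 31), (25, 30),  # eyes
    (32, 38), (33, 37), (34, 36), (43, 39), (42, 40),  # outer lip
    (44, 46), (49, 47),                                # inner lip
)

MIDLINE_POINTS = (11, 12, 13, 14, 17, 35, 41, 45, 48)

SEGMENT_LABELS = ("rest", "raise", "smile")


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateGeometryError(InvalidInputError):
    """Raised when a geometric construction is undefined (e.g. coincident canthi)."""


# ---------------------------------------------------------------------------
# plane-geometry primitives
# ---------------------------------------------------------------------------

def centroid(points: Iterable[Sequence[float]]) -> np.ndarray:
    """Arithmetic mean of a non-empty set of 2D points."""
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float)
    if arr.size == 0:
        raise InvalidInputError("centroid of an empty point set is undefined")
    arr = arr.reshape(-1, arr.shape[-1])
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("centroid requires finite coordinates")
    return arr.mean(axis=0)


def euclidean(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two points, in the coordinate unit (pixels)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


@dataclass(frozen=True)
class Line2D:
    """An infinite line given by a point on it and a unit direction vector."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if norm == 0.0 or not np.isfinite(norm):
            raise InvalidInputError("Line2D direction must be a nonzero finite vector")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / norm)

    def foot(self, p: Sequence[float]) -> np.ndarray:
        """Orthogonal projection of ``p`` onto the line."""
        p = np.asarray(p, dtype=float)
        t = float(np.dot(p - self.point, self.direction))
        return self.point + t * self.direction


def point_line_distance(p: Sequence[float], line: Line2D) -> float:
    """Perpendicular distance from point ``p`` to ``line``.

    Equals the distance from ``p`` to the foot of the perpendicular dropped
    onto the line, which is how the axis-based indices are defined.
    """
    p = np.asarray(p, dtype=float)
    return euclidean(p, line.foot(p))


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkFrame:
    """One video frame's 49 tracked landmark positions, in pixels.

    ``points`` is a (49, 2) float array; external indexing is 1-based
    (``frame.point(23)`` is the left medial canthus).
    """

    points: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_POINTS, 2):
            raise InvalidInputError(
                f"a landmark frame needs exactly {N_POINTS} 2D points, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("landmark coordinates must be finite")
        if self.frame_index < 0:
            raise InvalidInputError("frame_index must be >= 0")
        object.__setattr__(self, "points", pts)

    def point(self, index: int) -> np.ndarray:
        """Return landmark ``index`` (1-based)."""
        if not 1 <= index <= N_POINTS:
            raise InvalidInputError(f"landmark index {index} outside 1..{N_POINTS}")
        return self.points[index - 1]

    def take(self, indices: Iterable[int]) -> np.ndarray:
        """Return the selected landmarks (1-based indices) as a (k, 2) array."""
        idx = np.asarray(list(indices), dtype=int)
        if idx.size == 0 or idx.min() < 1 or idx.max() > N_POINTS:
            raise InvalidInputError("landmark indices must lie in 1..49")
        return self.points[idx - 1]

    def transformed(self, fn) -> "LandmarkFrame":
        """New frame with ``fn`` applied to the (49, 2) point array."""
        return LandmarkFrame(points=fn(self.points.copy()), frame_index=self.frame_index)


@dataclass(frozen=True)
class MotionSegment:
    """A half-open frame range [start, end) labelled with its facial motion."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise InvalidInputError(
                f"segment label {self.label!r} not one of {SEGMENT_LABELS}"
            )
        if not (0 <= self.start < self.end):
            raise InvalidInputError(
                f"segment [{self.start}, {self.end}) must satisfy 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "MotionSegment") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Recording:
    """One subject's landmark trajectory with rest / raise / smile annotations.

    Frames are stored in temporal order; ``segments`` holds exactly one
    pairwise-disjoint, non-empty segment per motion label, indexing into
    ``frames`` by position.
    """

    subject_id: str
    frames: list
    segments: Mapping[str, MotionSegment]
    class_label: str = "normal"
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.class_label not in ("palsy", "normal"):
            raise InvalidInputError(
                f"class_label must be 'palsy' or 'normal', got {self.class_label!r}"
            )
        if set(self.segments) != set(SEGMENT_LABELS):
            raise InvalidInputError(
                f"a recording needs exactly the segments {SEGMENT_LABELS}, "
                f"got {sorted(self.segments)}"
            )
        n = len(self.frames)
        segs = list(self.segments.values())
        for seg in segs:
            if seg.end > n:
                raise InvalidInputError(
                    f"segment {seg.label!r} [{seg.start}, {seg.end}) exceeds the "
                    f"{n} available frames"
                )
        for i, a in enumerate(segs):
            for b in segs[i + 1:]:
                if a.overlaps(b):
                    raise InvalidInputError(
                        f"segments {a.label!r} and {b.label!r} overlap"
                    )

    def frames_for(self, label: str) -> list:
        """The frames of one motion segment, in order."""
        seg = self.segments[label]
        return self.frames[seg.start:seg.end]

    def transformed(self, fn) -> "Recording":
        """New recording with ``fn`` applied to every frame's point array."""
        return Recording(
            subject_id=self.subject_id,
            frames=[f.transformed(fn) for f in self.frames],
            segments=dict(self.segments),
            class_label=self.class_label,
            fps=self.fps,
        )


def swap_left_right(frame: LandmarkFrame) -> LandmarkFrame:
    """Exchange the coordinates of every left/right landmark pair.

    This relabels sides without moving any point, so all bilateral
    asymmetry ratios are invariant under it.
    """
    pts = frame.points.copy()
    for li, ri in LEFT_RIGHT_PAIRS:
        pts[[li - 1, ri - 1]] = pts[[ri - 1, li - 1]]
    return LandmarkFrame(points=pts, frame_index=frame.frame_index)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------
# Trajectory CSV: columns frame,point,x,y with point in 1..49, one row per
# point per frame.  Segment JSON: subject_id, label, fps and the three
# motion segments.

def write_trajectory(path, frames: Sequence[LandmarkFrame]) -> None:
    rows = []
    for i, frame in enumerate(frames):
        for j in range(N_POINTS):
            rows.append((i, j + 1, frame.points[j, 0], frame.points[j, 1]))
    df = pd.DataFrame(rows, columns=["frame", "point", "x", "y"])
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectory(path) -> list:
    df = pd.read_csv(path)
    required = {"frame", "point", "x", "y"}
    if not required.issubset(df.columns):
        raise InvalidInputError(
            f"trajectory file {path} must have columns {sorted(required)}"
        )
    frames = []
    for fi, grp in df.groupby("frame", sort=True):
        if len(grp) != N_POINTS or set(grp["point"]) != set(range(1, N_POINTS + 1)):
            raise InvalidInputError(
                f"frame {fi} in {path} does not contain exactly points 1..{N_POINTS}"
            )
        grp = grp.sort_values("point")
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        frames.append(LandmarkFrame(points=pts, frame_index=int(fi)))
    if not frames:
        raise InvalidInputError(f"trajectory file {path} holds no frames")
    return frames


def write_segments(path, recording: Recording) -> None:
    doc = {
        "subject_id": recording.subject_id,
        "label": recording.class_label,
        "fps": recording.fps,
        "segments": [
            {"label": s.label, "start": s.start, "end": s.end}
            for s in (recording.segments[l] for l in SEGMENT_LABELS)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_segments(path) -> dict:
    doc = json.loads(Path(path).read_text())
    for key in ("subject_id", "label", "fps", "segments"):
        if key not in doc:
            raise InvalidInputError(f"segment file {path} lacks required key {key!r}")
    segments = {}
    for s in doc["segments"]:
        seg = MotionSegment(label=s["label"], start=int(s["start"]), end=int(s["end"]))
        if seg.label in segments:
            raise InvalidInputError(f"duplicate segment label {seg.label!r} in {path}")
        segments[seg.label] = seg
    doc["segments"] = segments
    return doc


def load_recording(trajectory_path, segments_path) -> Recording:
    """Read and validate a trajectory CSV + segment JSON pair."""
    frames = read_trajectory(trajectory_path)
    meta = read_segments(segments_path)
    return Recording(
        subject_id=str(meta["subject_id"]),
        frames=frames,
        segments=meta["segments"],
        class_label=meta["label"],
        fps=float(meta["fps"]),
    )


def save_recording(recording: Recording, trajectory_path, segments_path) -> None:
    write_trajectory(trajectory_path, recording.frames)
    write_segments(segments_path, recording)
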