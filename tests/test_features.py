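"""Asymmetry-index computation: hand-computed examples, invariances, oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from facesym.cohort import CohortSpec, default_template, generate_recording
from facesym.features import (
    COMBOS,
    axis_brow_distances,
    axis_mouth_distances,
    brow_eye_distances,
    displacement,
    extract_feature_table,
    extract_features,
    face_axes,
    mouth_corner_distances,
    parse_combo,
    read_feature_table,
    symmetry_ratio,
    write_feature_table,
)
from facesym.landmarks import (
    DegenerateGeometryError,
    InvalidInputError,
    LandmarkFrame,
    swap_left_right,
)

from _helpers import make_random_recording, oracle_indices


def frame_with(**landmarks):
    """Template-based frame with selected landmarks (1-based) overridden."""
    pts = default_template()
    for key, value in landmarks.items():
        pts[int(key.lstrip("p")) - 1] = value
    return LandmarkFrame(points=pts)


# ---------------------------------------------------------------------------
# per-frame distances
# ---------------------------------------------------------------------------

def test_brow_eye_distance_hand_computed():
    """Left brow centroid (2,0), left eye centroid (2,6) -> distance 6."""
    frame = frame_with(
        p1=(0, 0), p2=(1, 0), p3=(2, 0), p4=(3, 0), p5=(4, 0),
        p20=(2, 5), p21=(2, 6), p22=(2, 7), p23=(2, 5), p24=(2, 6), p25=(2, 7),
    )
    assert brow_eye_distances(frame).left == pytest.approx(6.0, abs=1e-12)


def test_brow_eye_distance_symmetric_template():
    frame = LandmarkFrame(points=default_template())
    sd = brow_eye_distances(frame)
    assert sd.left == pytest.approx(sd.right, abs=1e-12)


def test_mouth_corner_distance_hand_computed():
    """mean(sqrt10, sqrt10, sqrt9.25, sqrt9.25) with corner at (-3, 0)."""
    frame = frame_with(
        p32=(-3, 0), p35=(0, 1), p41=(0, -1), p45=(0, 0.5), p48=(0, -0.5),
    )
    expected = np.mean([np.sqrt(10), np.sqrt(10), np.sqrt(9.25), np.sqrt(9.25)])
    assert mouth_corner_distances(frame).left == pytest.approx(expected, abs=1e-12)


def test_mouth_corner_distance_degenerate_midline():
    frame = frame_with(p32=(-4, 0), p35=(0, 0), p41=(0, 0), p45=(0, 0), p48=(0, 0))
    assert mouth_corner_distances(frame).left == pytest.approx(4.0, abs=1e-12)


@pytest.mark.parametrize(
    "p23, p26, em, direction",
    [
        ((-1, 0), (1, 0), (0, 0), (1, 0)),
        ((0, -1), (0, 1), (0, 0), (0, 1)),
        ((0, 0), (2, 2), (1, 1), (1 / np.sqrt(2), 1 / np.sqrt(2))),
    ],
)
def test_face_axes_geometry(p23, p26, em, direction):
    axes = face_axes(frame_with(p23=p23, p26=p26))
    assert np.allclose(axes.em, em, atol=1e-12)
    assert abs(abs(np.dot(axes.horizontal.direction, direction)) - 1) < 1e-12
    assert abs(np.dot(axes.horizontal.direction, axes.vertical.direction)) < 1e-9


def test_face_axes_coincident_canthi_error():
    with pytest.raises(DegenerateGeometryError):
        face_axes(frame_with(p23=(5, 5), p26=(5, 5)))


def test_axis_brow_distance_hand_computed():
    """Canthal line y=x; left brow centroid (0,2) is sqrt(2) away."""
    frame = frame_with(
        p23=(0, 0), p26=(2, 2),
        p1=(0, 2), p2=(0, 2), p3=(0, 2), p4=(0, 2), p5=(0, 2),
    )
    assert axis_brow_distances(frame).left == pytest.approx(np.sqrt(2), abs=1e-12)


def test_axis_mouth_distance_hand_computed():
    """Canthi (0,0),(2,0): the vertical axis is x=1; P38=(4,5) sits 3 away."""
    frame = frame_with(p23=(0, 0), p26=(2, 0), p38=(4, 5))
    assert axis_mouth_distances(frame).right == pytest.approx(3.0, abs=1e-12)
    on_axis = frame_with(p23=(-1, 0), p26=(1, 0), p32=(0, 6))
    assert axis_mouth_distances(on_axis).left == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# displacement and ratio
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rest, motion, expected",
    [
        ([10, 10, 10], [10, 12, 13], 3.0),
        ([9, 11], [10], 0.0),
        ([10], [7, 8], 2.0),  # absolute-value branch
    ],
)
def test_displacement_examples(rest, motion, expected):
    assert displacement(rest, motion) == pytest.approx(expected, abs=1e-12)


def test_displacement_rejects_empty_series():
    with pytest.raises(InvalidInputError):
        displacement([], [1.0])
    with pytest.raises(InvalidInputError):
        displacement([1.0], [])


@pytest.mark.parametrize(
    "left, right, expected",
    [(3, 4, 0.75), (5, 5, 1.0), (0, 0, 1.0), (0, 2, 0.0)],
)
def test_symmetry_ratio_examples(left, right, expected):
    assert symmetry_ratio(left, right) == pytest.approx(expected, abs=1e-12)


def test_symmetry_ratio_degenerate_nan_mode():
    assert np.isnan(symmetry_ratio(0.0, 0.0, degenerate="nan"))
    assert symmetry_ratio(1.0, 2.0, degenerate="nan") == pytest.approx(0.5)
    with pytest.raises(InvalidInputError):
        symmetry_ratio(-1.0, 1.0)


def test_parse_combo_accepts_display_names():
    assert parse_combo("Forehead_region + Mouth_axis") == ("region", "axis")
    assert parse_combo("forehead_axis+mouth_region") == ("axis", "region")
    with pytest.raises(InvalidInputError):
        parse_combo("forehead_region")
    with pytest.raises(InvalidInputError):
        parse_combo("forehead_blur+mouth_axis")


# ---------------------------------------------------------------------------
# end-to-end feature extraction
# ---------------------------------------------------------------------------

def test_symmetric_recording_all_indices_exactly_one(noise_free_spec, rng):
    rec = generate_recording(noise_free_spec, "normal", rng=rng)
    for combo in COMBOS:
        feats = extract_features(rec, combo)
        assert feats.forehead_index == 1.0
        assert feats.mouth_index == 1.0


def test_palsy_recording_indices_equal_severity(noise_free_spec, rng):
    rec = generate_recording(noise_free_spec, "palsy", severity=0.5,
                             affected_side="left", rng=rng)
    for combo in COMBOS:
        feats = extract_features(rec, combo)
        assert feats.forehead_index == pytest.approx(0.5, abs=1e-9)
        assert feats.mouth_index == pytest.approx(0.5, abs=1e-9)


def test_indices_always_in_unit_interval(rng):
    for _ in range(20):
        rec = make_random_recording(rng)
        for combo in COMBOS:
            feats = extract_features(rec, combo)
            assert 0.0 <= feats.forehead_index <= 1.0
            assert 0.0 <= feats.mouth_index <= 1.0


def test_matches_independent_straight_line_oracle(rng):
    for _ in range(50):
        rec = make_random_recording(rng)
        for combo in COMBOS:
            fg, mg = parse_combo(combo)
            feats = extract_features(rec, combo)
            of, om = oracle_indices(rec, fg, mg)
            assert feats.forehead_index == pytest.approx(of, abs=1e-9)
            assert feats.mouth_index == pytest.approx(om, abs=1e-9)


def test_left_right_swap_leaves_indices_unchanged(noise_free_spec, rng):
    rec = generate_recording(noise_free_spec, "palsy", severity=0.3,
                             affected_side="left", rng=rng)
    swapped = rec.transformed(lambda pts: pts)  # copy, then swap frame-wise
    swapped.frames = [swap_left_right(f) for f in rec.frames]
    for combo in COMBOS:
        a = extract_features(rec, combo)
        b = extract_features(swapped, combo)
        assert a.forehead_index == pytest.approx(b.forehead_index, abs=1e-12)
        assert a.mouth_index == pytest.approx(b.mouth_index, abs=1e-12)


@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    angle=st.floats(min_value=-np.pi, max_value=np.pi),
    tx=st.floats(min_value=-500, max_value=500),
    ty=st.floats(min_value=-500, max_value=500),
)
def test_scale_and_rigid_invariance(scale, angle, tx, ty):
    """Resizing the video or rotating/translating the face changes no index."""
    rng = np.random.default_rng(7)
    rec = make_random_recording(rng)
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    moved = rec.transformed(lambda pts: scale * (pts @ R.T) + np.array([tx, ty]))
    for combo in COMBOS:
        a = extract_features(rec, combo)
        b = extract_features(moved, combo)
        assert b.forehead_index == pytest.approx(a.forehead_index, abs=1e-9)
        assert b.mouth_index == pytest.approx(a.mouth_index, abs=1e-9)


def test_frozen_axes_match_per_frame_axes_without_head_drift(noise_free_spec, rng):
    rec = generate_recording(noise_free_spec, "palsy", severity=0.4,
                             affected_side="right", rng=rng)
    for combo in COMBOS:
        live = extract_features(rec, combo)
        frozen = extract_features(rec, combo, freeze_axes_at_rest=True)
        assert frozen.forehead_index == pytest.approx(live.forehead_index, abs=1e-9)
        assert frozen.mouth_index == pytest.approx(live.mouth_index, abs=1e-9)


def test_feature_table_round_trip(tmp_path, noise_free_spec, rng):
    recs = [generate_recording(noise_free_spec, "normal", rng=rng, subject_id="n1"),
            generate_recording(noise_free_spec, "palsy", severity=0.2,
                               affected_side="left", rng=rng, subject_id="p1")]
    table = extract_feature_table(recs)
    assert len(table) == len(recs) * len(COMBOS)
    assert set(table["combo"]) == set(COMBOS)
    path = tmp_path / "features.csv"
    write_feature_table(path, table)
    loaded = read_feature_table(path)
    assert np.allclose(loaded["forehead_index"], table["forehead_index"], atol=1e-12)
    assert list(loaded["label"]) == list(table["label"])
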