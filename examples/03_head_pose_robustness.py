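"""Map how head orientation corrupts the asymmetry indices.

A perfectly mirror-symmetric 3D face performing symmetric motions is
rotated through roll, pitch and yaw (one axis at a time, -30..30 degrees),
projected orthographically, and pushed through feature extraction and a
trained LDA classifier.  Any index below 1 or any palsy call is a pure
projection artifact of the head pose.
"""

from facesym import (
    CohortSpec,
    default_face3d,
    extract_feature_table,
    fit_lda,
    generate_cohort,
    pose_grid,
)

recordings, _ = generate_cohort(CohortSpec(seed=7))
table = extract_feature_table(recordings, combos=["forehead_region+mouth_axis"])
clf = fit_lda(table[["forehead_index", "mouth_index"]].to_numpy(),
              table["label"].to_numpy())

face = default_face3d()
for axis in ("roll", "pitch", "yaw"):
    grid = pose_grid(face, clf, axes=(axis,))
    n_wrong = int((grid["predicted_label"] != "normal").sum())
    print(f"{axis:6s} sweep: forehead index in "
          f"[{grid['forehead_index'].min():.4f}, {grid['forehead_index'].max():.4f}], "
          f"mouth index in "
          f"[{grid['mouth_index'].min():.4f}, {grid['mouth_index'].max():.4f}], "
          f"{n_wrong}/61 cells misclassified")

print("\nRoll (in-plane) leaves both indices exactly constant and pitch keeps "
      "a symmetric face at 1.0; yaw drags the mouth index down because the "
      "smile's backward pull projects asymmetrically once the head turns.")
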