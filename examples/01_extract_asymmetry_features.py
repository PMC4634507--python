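"""Extract the four asymmetry-index combinations from one synthetic subject.

A palsy recording with the left side attenuated to 40% of normal motion is
generated (with realistic tracker noise) and the forehead/mouth indices are
computed under every geometry combination.  An index of 1 means perfectly
symmetric motion; the noise-free ground truth here is 0.40 for both regions.
"""

import numpy as np

from facesym import CohortSpec, COMBOS, extract_features, generate_recording

spec = CohortSpec()  # 0.5 px tracker noise, mild handheld jitter
rec = generate_recording(spec, "palsy", severity=0.40, affected_side="left",
                         rng=np.random.default_rng(42), subject_id="demo")

print(f"subject {rec.subject_id}: {len(rec.frames)} frames, "
      f"label={rec.class_label}, assigned severity 0.40\n")
print(f"{'combination':38s} {'forehead':>9s} {'mouth':>9s}")
for combo in COMBOS:
    feats = extract_features(rec, combo)
    print(f"{combo:38s} {feats.forehead_index:9.3f} {feats.mouth_index:9.3f}")
print("\nThe forehead index tracks the assigned 0.40 closely; the mouth "
      "index runs higher because the smile excursion (7 px) is smaller than "
      "the brow raise (10 px), so the same 0.5 px tracker noise inflates its "
      "max-over-frames displacement proportionally more.")
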