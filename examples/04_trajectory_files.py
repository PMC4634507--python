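"""Write and reload the on-disk trajectory format.

Recordings live as a trajectory CSV (frame, point, x, y with 1-based
landmark indices) plus a segment JSON naming the rest / raise / smile frame
ranges.  Any tracker that produces 49-point trajectories can feed the
pipeline through these two files.
"""

import tempfile
from pathlib import Path

import numpy as np

from facesym import CohortSpec, extract_features, generate_recording, \
    load_recording, save_recording

rec = generate_recording(CohortSpec(), "palsy", severity=0.55,
                         affected_side="right",
                         rng=np.random.default_rng(3), subject_id="p001")

with tempfile.TemporaryDirectory() as tmp:
    traj = Path(tmp) / "p001_trajectory.csv"
    seg = Path(tmp) / "p001_segments.json"
    save_recording(rec, traj, seg)
    print(f"trajectory CSV: {traj.stat().st_size} bytes, "
          f"{len(rec.frames)} frames x 49 points")
    print("segment JSON  :", seg.read_text().replace("\n", " ")[:120], "...")

    loaded = load_recording(traj, seg)
    feats = extract_features(loaded, "forehead_region+mouth_axis")
    print(f"\nreloaded subject {loaded.subject_id}: "
          f"forehead index {feats.forehead_index:.3f}, "
          f"mouth index {feats.mouth_index:.3f} (assigned severity 0.55)")
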