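"""TM7 kink drift and conformational-state clustering.

The agonist-like fixture bends TM7 about its proline pivot from 155 to
130 degrees while the intracellular helix ends move apart through three
scheduled phases.  Measures the kink series, clusters frames in the 3D
end-distance space and compares the result with the planted states.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from gpcrtraj import cluster_states, end_distance_series, kink_series
from gpcrtraj.state_clustering import medoid_frames
from gpcrtraj.synthetic_data import build_bundle, default_helices, fixture_specs

spec = fixture_specs(seed=11, n_frames=700)["agonist"]
traj, manifest = build_bundle(spec)
helices = {hp.definition.helix_id: hp.definition for hp in default_helices()}

kink = kink_series(traj, helices[7], pivot_seq=308, window=7)
print(f"kink: first 25-frame mean {kink.values[:25].mean():6.1f} deg "
      f"(planted 155), last {kink.values[-25:].mean():6.1f} deg (planted 130)")

ed = end_distance_series(traj, helices[3], helices[6], helices[7], end_length=4)
assignment = cluster_states(ed, k=3, seed=0)
ari = adjusted_rand_score(manifest.state_labels, list(assignment.labels))
print(f"states: sizes {assignment.sizes}, silhouette {assignment.silhouette:.2f}, "
      f"ARI vs planted truth {ari:.3f}")
for state, frame in medoid_frames(assignment, ed).items():
    print(f"  central structure of {state!r}: frame {frame} "
          f"(distances {np.round(ed.values[frame], 1)})")
# A silhouette > 0.6 quantifies "well separated"; ARI 1.0 means the
# clustering reproduces the planted phase labels exactly.
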