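"""RMSD clustering of a two-state conformer ensemble.

Generates 40 frames scattered around two reference conformations
("open" and "closed", 5 A apart, 0.2 A thermal noise plus random rigid
motions), clusters the pairwise-RMSD matrix with k-medoids, and labels
each cluster representative by its nearer reference.
"""

import numpy as np

from stdgem import (
    GenerationConfig, assign_state, cluster_frames, make_two_state_ensemble,
    rmsd_matrix,
)

ensemble, truth = make_two_state_ensemble(
    GenerationConfig(seed=0), n_frames=40, separation_A=5.0, noise_sigma_A=0.2
)

M = rmsd_matrix(ensemble)
print(f"{len(ensemble)} frames; mean pairwise RMSD {M[np.triu_indices(40, 1)].mean():.2f} A")

result = cluster_frames(M, k=2, seed=0)
print(f"k=2 medoids: {result.representatives}, "
      f"within-cluster cost {result.within_cluster_cost:.2f} A")

planted = np.array([s == "OPEN" for s in truth.state_labels])
got = result.labels == result.labels[0]
agreement = max((got == planted).mean(), (got != planted).mean())
print(f"planted-state recovery: {100 * agreement:.0f}%")

for medoid in result.medoid_indices:
    label, margin = assign_state(
        ensemble.frames[medoid],
        truth.ref_coords["OPEN"], truth.ref_coords["CLOSED"],
    )
    print(f"  representative {ensemble.frame_ids[medoid]}: {label.value} "
          f"(margin {margin:.2f} A)")

# With the 25:1 separation-to-noise ratio of these frames the two planted
# conformational states are recovered exactly, and each representative
# sits clearly nearer one reference (margin of several Angstrom).
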