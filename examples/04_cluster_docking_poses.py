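"""Post-process an ensemble-docking run: align, cluster and rank poses.

Generates three planted bundles of ligand poses with synthetic scores,
clusters them with the size-adaptive cutoff d_c = 0.067 Å x N_nh, and
prints the ranked cluster report.
"""

import numpy as np

from pocketcv import (
    adaptive_cutoff,
    cluster_and_rank_poses,
    make_perturbed_pose_set,
    pose_distance_matrix,
)

rng = np.random.default_rng(5)
ligand = rng.normal(size=(23, 3)) * 2.5  # an AMP-sized ligand (23 heavy atoms)

d_c = adaptive_cutoff(ligand.shape[0])
print(f"ligand with {ligand.shape[0]} heavy atoms -> clustering cutoff "
      f"d_c = {d_c} Å")

poses, truth = make_perturbed_pose_set(
    ligand, counts=(8, 6, 6), offsets=(0.0, 12.0, 24.0),
    jitter=0.3, seed=5, best_bundle=1,
)
matrix = pose_distance_matrix(poses)
result = cluster_and_rank_poses(matrix, d_c, poses)

print(f"\n{len(poses)} poses -> {len(result)} clusters "
      "(ordered by best score within each cluster):")
print(result.report().to_string(index=False))

best = result.clusters[0]
print(f"\nrank-1 cluster holds the globally best score "
      f"({best.best_score:.2f}, pose {best.best_pose_id}); with well-"
      "separated bundles the clustering recovers the planted groups exactly.")
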