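"""Distill an open->close trajectory into a diverse receptor ensemble.

Evaluates the binding-site CVs along a noisy closing trajectory, runs
the two-stage clustering (gyration-radius slices -> proportional
budget -> hierarchical seeding -> k-means refinement), and prints the
representative frames with their CV values.
"""

import numpy as np

from pocketcv import (
    TrajectorySpec,
    build_binding_site_cvs,
    cluster_ensemble,
    evaluate_cv_series,
    make_hinged_toy_protein,
    make_open_close_trajectory,
)

toy = make_hinged_toy_protein()
schedule = tuple(np.linspace(0.0, 1.0, 60))
traj = make_open_close_trajectory(
    toy, TrajectorySpec(schedule=schedule, noise_sigma=0.1, seed=11)
)

rog_cv, cip_cvs, _frame, _audit = build_binding_site_cvs(toy.structure, toy.site)
series = evaluate_cv_series(traj.coords, [rog_cv, *cip_cvs], times=traj.times)

result, manifest, allocation, slices = cluster_ensemble(
    series, base_n_c=12, n_slices=10
)

print(f"{series.n_frames} frames sliced into {slices.n_slices} "
      f"gyration-radius bins of width "
      f"{slices.boundaries[1] - slices.boundaries[0]:.2f} Å")
print(f"cluster budget: {allocation.base_n_c} requested, "
      f"{allocation.final_n_c} after the >=2-per-slice rule, "
      f"{result.n_clusters} clusters produced")
print("\nrepresentatives (frame, cluster size, site RoG in Å):")
print(manifest[["cluster", "frame", "size", "rog_bs"]].round(2).to_string(index=False))

rog = series.column("rog_bs")
reps = rog[result.representatives]
print(f"\nrepresentative RoG values span "
      f"{100 * (reps.max() - reps.min()) / (rog.max() - rog.min()):.0f}% "
      "of the sampled range — the ensemble keeps rare contracted states.")
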