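"""Score candidate structures against a closed (holo-like) reference.

Uses the toy protein's fully closed state as the "holo" reference and
measures, for a set of partially closed models: binding-site RMSD
after site superposition, the number of residues individually in a
holo-like conformation, and the ensemble summary table.
"""

import numpy as np

from pocketcv import (
    binding_site_rmsd,
    classify_residue_charge,
    ensemble_summary,
    make_hinged_toy_protein,
    per_residue_holo_flags,
    rmsd_distribution,
)

toy = make_hinged_toy_protein()
reference = toy.structure.with_coords(toy.coords_at(1.0))  # closed = "holo"
charged, _ = classify_residue_charge(toy.structure, toy.site)

print("closure  RMSD_bs(heavy)  RMSD_bs(CA)  holo residues (charged)")
heavy_rmsds = []
for closure in (0.0, 0.5, 0.8, 0.95, 1.0):
    model = toy.structure.with_coords(toy.coords_at(closure))
    heavy = binding_site_rmsd(model, reference, toy.site, "heavy")
    ca = binding_site_rmsd(model, reference, toy.site, "CA")
    _table, n_holo, n_charged = per_residue_holo_flags(
        model, reference, toy.site, charged_residues=charged)
    heavy_rmsds.append(heavy)
    print(f"  {closure:4.2f}   {heavy:10.2f} Å  {ca:9.2f} Å   "
          f"{n_holo:2d} / {len(toy.site)}  ({n_charged} / {len(charged)})")

summary = ensemble_summary({"bs_heavy": np.array(heavy_rmsds)})
print("\nensemble summary (percentage of models under each threshold):")
print(summary.table.to_string(index=False))

grid, density = rmsd_distribution(np.array(heavy_rmsds), bin_width=0.2)
print(f"\nRMSD density curve: {len(grid)} points at 0.05 Å spacing, "
      f"area {np.trapezoid(density, grid):.3f}")
# A fully closed model scores RMSD 0 with every residue holo-like; the
# half-closed models show how the site-level and residue-level metrics
# degrade together as the pocket opens.
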