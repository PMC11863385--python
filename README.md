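# pocketcv

Toolkit for **pocket-shape enhanced sampling and ensemble docking
post-processing**: given only the unbound (apo) structure of a protein and a
binding-site residue list, it automates everything around a bias-exchange
well-tempered metadynamics campaign that drives the pocket through closed,
holo-like shapes — CV construction, input-deck generation, trajectory
distillation into a maximally diverse receptor ensemble, and quantitative
scoring of the resulting structures and docking poses against holo
references.

It is aimed at structural bioinformaticians and computational chemists who
run ensemble docking against flexible, multi-domain receptors (the motivating
system is a hinged kinase-like enzyme whose two sub-pockets open and close by
quasi-rigid domain motion), and who need the setup and analysis around the MD
engine to be reproducible and auditable. The package does **not** run MD or
docking itself.

## The collective variables

Four CV families describe the shape and closure of a binding site *S*:

- **RoG_BS** — the mass-weighted radius of gyration of the site's backbone
  atoms, `RoG = sqrt( Σᵢ wᵢ |rᵢ − r̄|² / Σᵢ wᵢ )`, a measure of pocket
  compactness;
- **CIP₁…₃** — *contacts across inertia planes*: the site's heavy atoms
  define three principal inertia axes; each plane orthogonal to an axis
  (through the site's geometric center) splits the site residues into two
  groups, and the CV is the smooth contact count between them,
  `C = Σ_{i∈A, j∈B} s(r_ij)` with the rational switch
  `s(r) = (1 − x^n)/(1 − x^m)`, `x = (r − d₀)/r₀` (defaults r₀ = 4.5 Å,
  n = 6, m = 12);
- **cRD** — *contacts between quasi-rigid domains*: the same contact count
  between site residues of a mobile domain and of the core domain at their
  interface (residues within 8 Å of the partner domain, at least 4 per side);
- when more than 25% of the site's residues are charged and every resulting
  group keeps ≥ 2 non-adjacent residues, each cRD CV is split into a charged
  (`…c`) and an uncharged (`…o`) variant.

The emitted deck biases these CVs with 0.6 kcal/mol Gaussian hills every
2.5 ps (bias factor 10, replica exchange every 50 ps; widths from the
fluctuations of a ~200 ps unbiased run) and steers RoG_BS with a staged
upper wall whose center descends to 85% of the apo value.

Trajectories are distilled by a two-stage CV-space clustering: frames are
binned into 30 equal-width RoG_BS slices, each slice receives a proportional
share `x_i = (N_i/N_tot)·N_c` of the cluster budget (inflated in steps of 10
until every populated slice keeps ≥ 2 clusters), hierarchical clustering
inside each slice seeds a deterministic k-means refinement, and one
representative frame per cluster is extracted. Docking poses are aligned by
binding-site superposition, clustered at the size-adaptive cutoff
`d_c = 0.067 Å · N_nh` (N_nh = ligand heavy atoms) and ranked by best score;
structures are scored by site RMSD, per-residue holo-like flags and the
fraction of native contacts F_nat (5 Å shell).

## Worked example

`examples/04_cluster_docking_poses.py` clusters three planted bundles of
poses of an AMP-sized ligand:

```
ligand with 23 heavy atoms -> clustering cutoff d_c = 1.5 Å

20 poses -> 3 clusters (ordered by best score within each cluster):
 rank  size  best_score best_pose  cutoff
    1     6    0.014610      b1p2     1.5
    2     8    1.173927      b0p5     1.5
    3     6    3.069164      b2p2     1.5
```

The 23-heavy-atom ligand yields the 1.5 Å adaptive cutoff; the three planted
bundles are recovered exactly, and the rank-1 cluster is the one containing
the globally best (lowest) docking score. The other examples build a full
metadynamics deck from the hinged toy protein (8 CVs including the split
charged/uncharged interface contacts, restraint target
`0.85 × 41.84 = 35.56 Å`), distill an open→close trajectory into a
slice-stratified ensemble, and score partially closed models against the
closed reference.

A thin CLI mirrors the stages:

```sh
pocketcv fixtures --out-dir fix          # toy structure, trajectory, lists
pocketcv setup --structure fix/toy_open.pdb --site fix/site.txt \
    --domains fix/domains.tsv --unbiased-traj fix/toy_unbiased.pdb \
    --out plumed.dat
pocketcv cluster --series fix/cv_series.tsv --trajectory fix/toy_trajectory.pdb \
    --out-dir clusters
```

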