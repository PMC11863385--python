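# Methods

This note documents the models and procedures implemented in `pocketcv`,
the defaults they ship with, and the design decisions taken where the
problem is genuinely open. It describes what the code computes; every
number quoted here is produced by the test suite or the example scripts.

## Scope and assumptions

`pocketcv` prepares and post-processes pocket-shape enhanced-sampling
campaigns; it never evaluates forces or runs dynamics. The working
assumptions are:

- the receptor is a (multi-domain) protein whose ligand binding is
  accompanied by a *contraction* of the binding site — hinge-like closure
  of quasi-rigid domains over the pocket;
- a binding-site residue list is available, either from a bound reference
  complex (3.5 Å heavy-atom shell around the ligand), from merged pocket
  predictions (union of predictions with confidence ≥ 0.01), or from the
  user;
- for the inter-domain CVs, a residue → quasi-rigid-domain map is
  available with one designated core domain.

Structures are read from single-model PDB files (first model of
multi-model files; highest-occupancy altloc conformer only; 1-based
author numbering kept verbatim, insertion codes carried). No structure
repair, protonation assignment or symmetry expansion is attempted.
Inter-residue distance always means the minimum over heavy-atom pairs —
the least biased convention when no atom subset is prescribed.

## Collective variables

**Site gyration radius (`rog_bs`).** Computed over the site's backbone
atoms (N, CA, C, O), mass-weighted by default (a flag disables the
weighting, since gyration routines in MD engines differ on this point).

**Contacts across inertia planes (`cip_1..3`).** The inertia tensor of
the site's heavy atoms (masses as weights) is diagonalized about the
site's *unweighted* geometric center; "geometric center" is taken
literally — a mass-weighted center would be an inertia center, a
different object. Axes are sorted by ascending moment. Sign convention:
each eigenvector is flipped so its largest-magnitude component is
positive, then the largest-moment axis is flipped if needed to make the
frame right-handed — this makes degenerate (symmetric) cases
deterministic. Each plane partitions the site *by residue* (heavy-atom
geometric center projection; a residue exactly on the plane joins the
negative-side group), and the CV is the switching-function contact count
between the heavy atoms of the two groups. Collinear sites are rejected:
two of the three axes would be undetermined.

The inertia frame is computed once on the input (apo) structure and
frozen into the CV atom groups. Biasing requires fixed atom groups;
recomputing the frame per trajectory frame would change the CV
definition mid-simulation.

**Switching function.** Rational form `s(r) = (1 − x^n)/(1 − x^m)`,
`x = (r − d₀)/r₀`, clamped to 1 for r ≤ d₀, with the removable
singularity at x = 1 filled with n/m. Defaults r₀ = 4.5 Å, d₀ = 0,
n = 6, m = 12 — the conventional exponents of the rational switch and a
standard heavy-atom contact radius. All four parameters are settable per
CV, and hill widths are always re-estimated from the user's own unbiased
run, so these defaults are starting points, not claims.

**Inter-domain contacts (`crd_<domain>`).** For each mobile domain, the
interface residue list is the union of (i) site residues of the mobile
domain within 8 Å (minimum heavy-atom distance) of *any* residue of the
core domain and (ii) the specular core-side selection. Two conditions
are enforced as hard errors rather than warnings, with the message
recommending a cutoff adjustment: no site residue may fall into two
interface CVs, and each domain side must contribute at least 4 residues
(biasing a thinner interface risks tearing secondary structure). The CV
is the heavy-atom contact count between the mobile-side and core-side
residue groups.

**Charged split.** When the site's charged fraction exceeds 25% and
every resulting group (charged and uncharged, on both sides of each
interface) keeps at least 2 non-adjacent residues, each inter-domain CV
is split into a charged-only and an uncharged-only variant. Charged
side chains face smaller barriers for local rearrangement; biasing them
separately prevents their sampling from being dominated by the bulkier
neutral residues. "Non-adjacent" means sequence numbers differing by
≥ 2 in the same chain — the natural reading of adjacency on a chain.
The charged set defaults to ASP/GLU/LYS/ARG; histidine is excluded
because its protonation near pH 7 is ambiguous (the set is
configurable; termini are not treated as charged). Every split/no-split
decision is recorded in the bundle's audit log.

## Metadynamics parameters and restraint schedule

Defaults: Gaussian hill height 0.6 kcal/mol, bias factor 10, deposition
every 2.5 ps, bias exchange every 50 ps. Hill widths are the per-CV
sample standard deviation over a short (~200 ps) unbiased run, scale
factor 1.0 by default; a constant CV is an error (a zero width is
unusable), and the estimate is taken on the final, post-split CV set.

The gyration-radius restraint has four phases with default durations
(10, 40, 400, 150) ns:

1. unrestrained;
2. upper wall at the apo value RoG_apo, force constant ramping linearly
   10 → 25 kcal mol⁻¹ Å⁻²;
3. wall center descending stepwise (1 ns steps) from RoG_apo to
   0.85 × RoG_apo at constant k = 25;
4. hold at the target.

The schedule is queryable at any time and continuous at phase
boundaries; the center is non-increasing after phase 2. The four
defaults sum to 600 ns; a 550 ns campaign reads the 400 ns descent as
ending at t = 450 ns from the start of the run rather than lasting
400 ns after the ramp — both readings are supported because the
durations are plain configuration.

The emitted deck is PLUMED-dialect text: atom groups as 1-based serial
lists, gyration and coordination directives, a well-tempered
metadynamics directive (pace converted to integer steps from the
integrator timestep — a non-integer conversion is an error naming the
fix), and a moving-restraint directive whose knots realize the schedule
(the deck's restraint interpolates linearly; the 1 ns stepping of phase
3 is a schedule-query detail below the deposition granularity).
Emission is deterministic: identical inputs give byte-identical text,
and emit → parse → emit is the identity.

## Ensemble selection

Clustering runs in CV space, never on coordinates: CV-space diversity
is what ensemble docking needs, and coordinate RMSD would re-mix the
shape information the CVs isolate. Columns are standardized to zero
mean / unit variance over the whole series before any distance is
computed — the CVs mix Å and dimensionless contact counts, and raw
Euclidean distance would weight them arbitrarily.

1. **Slicing.** Frames are binned into 30 equal-width slices of the
   gyration-radius column (half-open on the right, last slice closed),
   so rare contracted pocket states survive the budget allocation.
2. **Allocation.** Slice *i* receives
   `x_i = round((N_i/N_tot)·N_c)` clusters (round half away from zero,
   clipped to the slice size); if any slice with ≥ 2 frames receives
   fewer than 2, N_c grows by 10 and the allocation is recomputed.
   Slices with < 2 frames are exempt (one cluster per frame) — without
   the exemption the iteration could never terminate; the guard is
   logged as a warning. With slice sizes (980, 10, 10) and N_c = 100
   the rule inflates to N_c = 150 and allocates (147, 2, 2).
3. **Seeding.** Complete-linkage agglomerative clustering within each
   slice, cut at x_i clusters (capped at the number of distinct CV
   vectors — exact duplicates cannot be separated by any distance cut).
4. **Refinement.** Deterministic Lloyd k-means from the seed centroids,
   maximum 10,000 iterations, ties to the lowest cluster index, empty
   clusters re-seeded with the frame farthest from its assigned
   centroid so the cluster count is preserved.
5. **Representatives.** Per cluster, the member frame nearest its
   centroid in the standardized space; ties break to the earliest
   frame.

The pipeline contains no randomized initialization: identical series
give identical labels, centroids and representatives.

## Evaluation metrics

- **Site RMSD**: superpose the site selection (Cα or heavy atoms,
  matched by residue + atom name) onto the reference, report the RMSD
  of the same selection. Kabsch fit with reflection correction;
  symmetric to 1e-9 by construction.
- **Per-residue holo-like flags**: one global superposition of all site
  heavy atoms, then per-residue heavy-atom RMSD in that fixed frame
  against a per-residue threshold (default 2.0 Å for every residue,
  overridable residue-by-residue — the structure-level 2.0/2.5 Å bands
  are the only anchor available for the default). Reported as a table
  plus simultaneous counts, total and charged.
- **RMSD distributions**: 0.2 Å bins, unit-area normalization, cubic
  spline sampled at 20 points per Å; negative spline overshoot is
  clipped to zero and the curve renormalized (the clipped curve still
  integrates to 1 ± 1e-3 on its grid).
- **Ensemble summary**: per metric, the percentage of frames below 2.0
  and 2.5 Å (both thresholds are computed for both the protein-Cα and
  site-heavy metrics; reporting conventions differ on which applies to
  which) and the minimum, each to one decimal.
- **F_nat**: the reference contact set is every (ligand heavy atom,
  protein heavy atom) pair within 5 Å in the reference complex; a model
  recovers a contact when the same atom pair is within the same cutoff.
  Atom-pair (not residue-pair) granularity is the stricter, CAPRI-style
  reading. An empty reference set defines F_nat = 0 with a warning.

## Docking pose post-processing

Receptor conformations are superposed onto a reference over the site's
heavy atoms and each transform is applied to its ligand pose, bringing
all poses into one frame. Pose-pose distance is the *no-fit* coordinate
RMSD in that common frame: the site alignment exists precisely so that
ligand displacement within the pocket is meaningful, and refitting each
pair (or using internal-distance RMSD) would discard it. Average-linkage
agglomerative clustering is cut at `d_c = 0.067 Å × N_nh`; the
unrounded value is used internally and the one-decimal rounding (half
away from zero) is what gets reported, matching how such cutoffs are
quoted. Clusters are ordered by their best (lowest) score, poses within
a cluster by score, ties by pose identifier — the output is invariant
to input order up to that tie rule.

## Synthetic fixtures

The toy system is a hinged three-domain protein: a 20-residue straight
CORE with two rigid arms (LID-like and NMP-like) hinged at its ends.
Each arm is a 4-residue patch hugging the core end (3-7 Å away — a
genuine 8 Å interface in the open state) plus an 8-residue lever
extending up and outward at 60°; closing rotates each arm by 100°
about its hinge, folding the levers back over the core. Residues carry
five heavy atoms (N, CA, C, O, CB) so heavy/backbone/Cα selections are
all distinct without full chemistry. The default binding site spans
both interfaces: 4 core residues per end plus all 24 arm residues = 32
residues, 11 of them charged (34%), with interface groups alternating
charged/neutral so the charged-split rule is exercised end to end.

On closing, the fixture reproduces qualitatively every signal the
pipeline must detect: the site's backbone gyration radius drops by
~37% (well beyond the ≥ 20% contraction the protocol targets),
interface contacts rise, and the inertia-plane contacts change.
Trajectory, CV-mixture and pose-bundle generators are pure functions of
their spec and seed.

What the fixtures do *not* emulate: side-chain chemistry and packing,
sterics, solvent, force-field energetics, and the gradual correlated
fluctuations of real MD (noise is i.i.d. Gaussian on coordinates).
Passing tests therefore demonstrate the correctness of the geometry,
the rules and the statistics — not that any particular real protein
will yield holo-like ensembles.

## Problem sizes and numerical choices

The test suite runs desk-scale problems: trajectories of 25-60 frames,
CV mixtures of a few hundred frames, pose sets of ~20; property checks
use 1000 random allocation vectors and 100 random instances for the
coordination/superposition oracles. Degenerate inputs are first-class:
constant CV columns, singleton slices, duplicate frames, empty contact
sets and collinear point sets all have defined behavior (error or
documented convention) and tests.

Two checks compare against the real open/closed adenylate kinase pair
(4AKE/1AKE: site Cα/heavy RMSD and site-RoG contraction) and fetch the
entries from the RCSB at run time; without network access they fail
with an explicit message. They are deliberately not skipped: an
environment that cannot reach the data should see a red check, not a
silently green one.

## Known limitations

- Hill-width defaults and switching parameters are calibration points,
  not validated optima; real campaigns must re-estimate widths from
  their own unbiased runs.
- The inertia frame is frozen at setup; for sites that reorient
  internally during sampling the CIP partition may become less
  informative (the audit log records the frame used).
- Pose "dRMSD" assumes a consistent ligand atom order across poses; no
  graph matching or symmetry correction is attempted.
- PDB handling is deliberately minimal (no mmCIF, no chain-mapping
  heuristics); selections match atoms by residue id + atom name and
  error on asymmetric atom sets rather than guessing.
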