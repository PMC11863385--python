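"""Deterministic synthetic systems for exercising the full pipeline.

The central fixture is a hinged three-domain toy protein: a straight
CORE slab with two arms (LID-like and NMP-like) attached at its ends by
hinges.  Closing the hinges folds the arms back over the core, so a
binding site spanning the two arm/core interfaces contracts — its
gyration radius drops by well over 20% — mimicking an open -> closed
pocket transition.  Residues are minimal (backbone N/CA/C/O plus one
CB pseudo side chain) so heavy-atom, backbone and C-alpha selections
are all distinct without full chemistry.

All generators are pure functions of their spec and seed.  None of this
is physically realistic (no force field, no sterics); it exists to give
every geometric and statistical operation a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .cvs import CVSeries
from .structures import DomainMap, SiteDefinition, Structure
from .trajectory import Trajectory
from .poses import Pose

__all__ = [
    "ToyProteinSpec",
    "ToyProtein",
    "TrajectorySpec",
    "make_hinged_toy_protein",
    "make_open_close_trajectory",
    "make_labeled_cv_series",
    "make_perturbed_pose_set",
]

_CA_SPACING = 3.8  # Å, consecutive C-alpha distance
_CHARGED_NAMES = ("ASP", "LYS", "GLU", "ARG")
_NEUTRAL_NAMES = ("GLY", "ALA", "SER", "LEU", "THR", "VAL")


@dataclass(frozen=True)
class ToyProteinSpec:
    """Geometry and composition of the hinged toy protein.

    Each arm is one rigid body made of a 4-residue *patch* that hugs a
    core end (the arm/core interface, within ~3-7 Å of the core in the
    open state) and an ``n_lever``-residue lever extending up and
    outward at ``open_angle_deg``.  Closing rotates the whole arm by
    ``sweep_deg`` about its hinge, folding the lever back over the
    core.  The binding site spans both interfaces: the outermost
    ``n_interface_core`` core residues at each end plus every arm
    residue (default 4 + 4 + 2 x 12 = 32 residues).
    """

    n_core: int = 20
    n_lever: int = 8
    core_label: str = "CORE"
    arm_labels: tuple[str, ...] = ("LID", "NMP")
    open_angle_deg: float = 60.0   # lever elevation in the open state
    sweep_deg: float = 100.0       # hinge rotation from open to closed
    n_interface_core: int = 4      # core residues per end included in the site
    charged_fraction: float = 11 / 32

    @property
    def n_arm(self) -> int:
        return 4 + self.n_lever

    def __post_init__(self) -> None:
        if self.n_core < 2 * self.n_interface_core + 4:
            raise ValueError("core too short for two disjoint interfaces")
        if self.n_lever < 2:
            raise ValueError("lever needs at least 2 residues")
        if len(self.arm_labels) not in (1, 2):
            raise ValueError("one or two arms supported")
        if not (0 <= self.charged_fraction <= 1):
            raise ValueError("charged fraction must be in [0, 1]")


@dataclass(frozen=True)
class TrajectorySpec:
    """Closure schedule and noise for a toy open->close trajectory."""

    schedule: tuple[float, ...]  # per-frame hinge closure fraction in [0, 1]
    noise_sigma: float = 0.0     # Å, isotropic Gaussian coordinate noise
    seed: int = 0
    dt_ps: float = 10.0

    def __post_init__(self) -> None:
        if any(not (0.0 <= f <= 1.0) for f in self.schedule):
            raise ValueError("closure schedule values must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass
class ToyProtein:
    """Open-state structure plus the hinge geometry needed to close it."""

    structure: Structure
    domains: DomainMap
    site: SiteDefinition
    spec: ToyProteinSpec
    hinges: dict[str, tuple[np.ndarray, np.ndarray, float]] = field(
        default_factory=dict
    )  # label -> (pivot, axis, closing angle rad)

    def coords_at(self, closure: float) -> np.ndarray:
        """Coordinates with every hinge closed by ``closure`` in [0, 1]."""
        if not (0.0 <= closure <= 1.0):
            raise ValueError("closure fraction must be in [0, 1]")
        coords = self.structure.coords.copy()
        for label, (pivot, axis, angle) in self.hinges.items():
            idx = self.structure.heavy_indices(self.domains.residues_of(label))
            rot = Rotation.from_rotvec(axis * angle * closure)
            coords[idx] = rot.apply(coords[idx] - pivot) + pivot
        return coords


def _residue_atoms(ca: np.ndarray, direction: np.ndarray):
    """Five heavy atoms (N, CA, C, O, CB) around a C-alpha position."""
    d = direction / np.linalg.norm(direction)
    up = np.array([0.0, 0.0, 1.0])
    side = np.cross(d, up)
    return {
        "N": ca - 1.4 * d + 0.4 * up,
        "CA": ca,
        "C": ca + 1.4 * d - 0.3 * up,
        "O": ca + 1.4 * d - 0.3 * up + 1.2 * side,
        "CB": ca + 1.5 * up + 0.4 * side,
    }


# patch CA offsets relative to the hinge pivot (x toward the core, y up);
# chosen so all four residues sit 3-7 Å from the core in the open state
_PATCH_OFFSETS = ((-4.0, 3.0), (-1.5, 3.5), (2.0, 3.0), (-2.0, 6.5))
_LEVER_BASE = (2.0, 3.0)


def _assign_charges(site_rows, residues, spec: ToyProteinSpec) -> set[int]:
    """Pick which site residues get charged names.

    When the budget allows, interface groups (core ends and patches)
    alternate charged/neutral so every group that a charged/uncharged
    split would create contains two non-adjacent charged and two
    non-adjacent neutral residues; the remaining budget is spread over
    the levers.  Smaller budgets fall back to even spacing.
    """
    n_charged = int(round(spec.charged_fraction * len(site_rows)))
    interface_rows = []
    for idx in site_rows:
        dom, _ca, _d, part = residues[idx]
        if part in ("core_end", "patch"):
            interface_rows.append(idx)
    # alternate within each consecutive group of 4 interface residues
    alternating = [r for k, r in enumerate(interface_rows) if k % 2 == 0]
    if n_charged >= len(alternating):
        chosen = set(alternating)
        lever_rows = [idx for idx in site_rows
                      if residues[idx][3] == "lever"]
        extra = n_charged - len(chosen)
        if extra > 0:
            pos = np.linspace(0, len(lever_rows) - 1, extra + 2)[1:-1]
            for p in pos:
                chosen.add(lever_rows[int(round(p))])
        return chosen
    pos = np.linspace(0, len(site_rows) - 1, n_charged) if n_charged else []
    return {site_rows[int(round(p))] for p in pos}


def make_hinged_toy_protein(spec: ToyProteinSpec | None = None) -> ToyProtein:
    """Build the open-state hinged toy protein.

    The default spec yields a 32-residue interface-spanning site with
    11 charged residues (a ~34% charged fraction), i.e. a pocket whose
    composition triggers the charged-split rule.
    """
    spec = spec or ToyProteinSpec()
    core_len = (spec.n_core - 1) * _CA_SPACING
    # (domain, CA position, chain direction, part tag)
    residues: list[tuple[str, np.ndarray, np.ndarray, str]] = []
    for i in range(spec.n_core):
        near_end = (i < spec.n_interface_core
                    or i >= spec.n_core - spec.n_interface_core)
        residues.append((spec.core_label,
                         np.array([i * _CA_SPACING, 0.0, 0.0]),
                         np.array([1.0, 0.0, 0.0]),
                         "core_end" if near_end else "core"))
    alpha = np.deg2rad(spec.open_angle_deg)
    arm_defs = []
    if len(spec.arm_labels) >= 1:  # arm hinged at the far (x = L) end
        arm_defs.append((spec.arm_labels[0], np.array([core_len, 0.0, 0.0]), +1.0))
    if len(spec.arm_labels) == 2:  # mirrored arm hinged at the x = 0 end
        arm_defs.append((spec.arm_labels[1], np.zeros(3), -1.0))
    for label, pivot, sign in arm_defs:
        for (dx, dy) in _PATCH_OFFSETS:
            ca = pivot + np.array([sign * dx, dy, 0.0])
            residues.append((label, ca, np.array([sign, 0.0, 0.0]), "patch"))
        base = pivot + np.array([sign * _LEVER_BASE[0], _LEVER_BASE[1], 0.0])
        direction = np.array([sign * np.cos(alpha), np.sin(alpha), 0.0])
        for j in range(1, spec.n_lever + 1):
            residues.append((label, base + j * _CA_SPACING * direction,
                             direction, "lever"))

    site_rows = [idx for idx, (_dom, _ca, _d, part) in enumerate(residues)
                 if part in ("core_end", "patch", "lever")]
    charged_rows = _assign_charges(site_rows, residues, spec)

    names, elements, rids, rnames, xyz = [], [], [], [], []
    mapping = {}
    elem_of = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    c_cycle = n_cycle = 0
    for idx, (dom, ca, d, _part) in enumerate(residues):
        rid = f"A:{idx + 1}"
        mapping[rid] = dom
        if idx in charged_rows:
            rname = _CHARGED_NAMES[c_cycle % len(_CHARGED_NAMES)]
            c_cycle += 1
        else:
            rname = _NEUTRAL_NAMES[n_cycle % len(_NEUTRAL_NAMES)]
            n_cycle += 1
        for atom, pos in _residue_atoms(ca, d).items():
            names.append(atom)
            elements.append(elem_of[atom])
            rids.append(rid)
            rnames.append(rname)
            xyz.append(pos)
    masses = {"N": 14.007, "C": 12.011, "O": 15.999}
    structure = Structure(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_ids=np.array(rids, dtype=object),
        res_names=np.array(rnames, dtype=object),
        coords=np.asarray(xyz, dtype=float),
        masses=np.array([masses[e] for e in elements]),
        is_hydrogen=np.zeros(len(names), dtype=bool),
        is_hetatm=np.zeros(len(names), dtype=bool),
    )
    domains = DomainMap(mapping)
    site = SiteDefinition(tuple(f"A:{r + 1}" for r in site_rows), provenance="user")
    hinges = {}
    for label, pivot, sign in arm_defs:
        # rotate about z, sign chosen so the lever folds back over the core
        hinges[label] = (pivot, np.array([0.0, 0.0, sign]),
                         np.deg2rad(spec.sweep_deg))
    return ToyProtein(structure=structure, domains=domains, site=site,
                      spec=spec, hinges=hinges)


def make_open_close_trajectory(toy: ToyProtein,
                               traj: TrajectorySpec) -> Trajectory:
    """Frames following the closure schedule, with seeded Gaussian noise."""
    rng = np.random.default_rng(traj.seed)
    frames = np.empty((len(traj.schedule), toy.structure.n_atoms, 3))
    for f, closure in enumerate(traj.schedule):
        coords = toy.coords_at(closure)
        if traj.noise_sigma > 0:
            coords = coords + rng.normal(0.0, traj.noise_sigma, coords.shape)
        frames[f] = coords
    times = np.arange(len(traj.schedule)) * traj.dt_ps
    return Trajectory(toy.structure, frames, times)


def make_labeled_cv_series(n_frames: int, means, covariances, weights,
                           seed: int = 0, names=None, dt_ps: float = 10.0):
    """Gaussian-mixture CV series with recorded component labels.

    Ground truth for clustering-recovery tests: ``means`` is a
    (k, n_cvs) array of planted mode centers, ``covariances`` one
    covariance matrix (or scalar variance) per mode, ``weights`` the
    mixture weights (must sum to 1).
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    if len(weights) != len(means):
        raise ValueError("one weight per mode required")
    k, n_cvs = means.shape
    covs = []
    for c in covariances:
        c = np.asarray(c, dtype=float)
        covs.append(c * np.eye(n_cvs) if c.ndim == 0 else c)
    rng = np.random.default_rng(seed)
    labels = rng.choice(k, size=n_frames, p=weights)
    values = np.empty((n_frames, n_cvs))
    for mode in range(k):
        rows = labels == mode
        if rows.any():
            values[rows] = rng.multivariate_normal(
                means[mode], covs[mode], size=int(rows.sum())
            )
    if names is None:
        names = ["rog_bs"] + [f"cv_{j}" for j in range(1, n_cvs)]
    series = CVSeries(values=values, names=list(names),
                      times=np.arange(n_frames) * dt_ps)
    return series, labels


def make_perturbed_pose_set(reference_coords, counts, offsets,
                            jitter: float = 0.2, seed: int = 0,
                            best_bundle: int = 0):
    """Bundles of ligand poses displaced about distinct centers.

    ``counts[b]`` poses are generated around ``reference + offsets[b]``
    with isotropic Gaussian jitter; within-bundle spread (~``jitter``)
    is far smaller than the bundle separations by construction.
    Synthetic scores are drawn so that ``best_bundle`` holds the global
    best (lowest) score.

    Returns ``(poses, true_labels)``.
    """
    reference = np.asarray(reference_coords, dtype=float)
    offsets = [np.asarray(o, dtype=float) if np.ndim(o) else
               np.array([float(o), 0.0, 0.0]) for o in offsets]
    if len(counts) != len(offsets):
        raise ValueError("one offset per bundle required")
    rng = np.random.default_rng(seed)
    poses, labels = [], []
    for b, (count, offset) in enumerate(zip(counts, offsets)):
        base = 0.0 if b == best_bundle else 1.0 + b
        for i in range(count):
            coords = reference + offset
            if jitter > 0:
                coords = coords + rng.normal(0.0, jitter, coords.shape)
            score = base + rng.uniform(0.0, 0.9)
            poses.append(Pose(pose_id=f"b{b}p{i}", coords=coords,
                              score=float(score), receptor_id=f"r{b}_{i}"))
            labels.append(b)
    return poses, np.asarray(labels)
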