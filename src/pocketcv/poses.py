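"""Ensemble-docking pose post-processing.

After docking one ligand against many receptor conformations, the top
pose of each run is brought into a common frame by superposing each
receptor's binding site onto a reference receptor, the ligand poses are
clustered by pairwise no-fit RMSD with a size-adaptive cutoff
``d_c = 0.067 Å x N_nh`` (N_nh = ligand heavy atoms), and the clusters
are ranked by the best (lowest) docking score they contain.

The no-fit convention is deliberate: the binding sites are aligned
precisely so that ligand displacement within the pocket is meaningful;
refitting each ligand pair would erase that information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structures import SiteDefinition, Structure, superpose

__all__ = [
    "Pose",
    "PoseCluster",
    "PoseClusterSet",
    "adaptive_cutoff",
    "align_poses_by_site",
    "pose_distance_matrix",
    "cluster_and_rank_poses",
]


@dataclass(frozen=True)
class Pose:
    """One docked ligand pose (heavy-atom coordinates) with its score."""

    pose_id: str
    coords: np.ndarray          # (n_heavy, 3), Å
    score: float                # lower = better
    receptor_id: str = ""

    @property
    def n_heavy(self) -> int:
        return len(self.coords)


def adaptive_cutoff(n_heavy: int) -> float:
    """Size-adaptive clustering cutoff 0.067 Å per ligand heavy atom.

    Reported rounded to one decimal (half away from zero), matching the
    convention used to quote such cutoffs.
    """
    if n_heavy < 1:
        raise ValueError("ligand must have at least one heavy atom")
    return math.floor(0.067 * n_heavy * 10 + 0.5) / 10


def align_poses_by_site(poses, receptors: dict[str, Structure],
                        site: SiteDefinition, reference: Structure):
    """Superpose each receptor's site onto the reference; move its pose along.

    ``receptors`` maps ``receptor_id`` to the conformation each pose was
    docked into.  Returns new poses with transformed ligand coordinates.
    """
    site.validate(reference)
    ref_idx = reference.heavy_indices(list(site))
    key = [(reference.res_ids[i], reference.atom_names[i]) for i in ref_idx]
    aligned = []
    fits = {}
    for pose in poses:
        rec = receptors[pose.receptor_id]
        if pose.receptor_id not in fits:
            site.validate(rec)
            idx = rec.heavy_indices(list(site))
            lookup = {(rec.res_ids[i], rec.atom_names[i]): i for i in idx}
            missing = [k for k in key if k not in lookup]
            if missing:
                raise ValueError(
                    f"receptor {pose.receptor_id!r} lacks site atoms: {missing[:5]}"
                )
            mob = rec.coords[[lookup[k] for k in key]]
            fits[pose.receptor_id] = superpose(mob, reference.coords[ref_idx])
        fit = fits[pose.receptor_id]
        aligned.append(Pose(pose.pose_id, fit.apply(pose.coords),
                            pose.score, pose.receptor_id))
    return aligned


def pose_distance_matrix(poses) -> np.ndarray:
    """Pairwise no-fit coordinate RMSD between aligned poses, Å."""
    if len(poses) < 2:
        raise ValueError("need at least two poses")
    n_heavy = poses[0].n_heavy
    if any(p.n_heavy != n_heavy for p in poses):
        raise ValueError("poses differ in heavy-atom count or atom order")
    stack = np.stack([np.asarray(p.coords, dtype=float) for p in poses])
    diff = stack[:, None] - stack[None]                    # (P, P, N, 3)
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=-1), axis=-1))


@dataclass(frozen=True)
class PoseCluster:
    rank: int                   # 1-based, by best score
    members: tuple[str, ...]    # pose ids ordered by ascending score
    best_score: float
    best_pose_id: str

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PoseClusterSet:
    clusters: tuple[PoseCluster, ...]
    cutoff: float
    labels: dict[str, int] = field(default_factory=dict)  # pose id -> rank

    def __len__(self) -> int:
        return len(self.clusters)

    def report(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"rank": c.rank, "size": c.size, "best_score": c.best_score,
             "best_pose": c.best_pose_id, "cutoff": self.cutoff}
            for c in self.clusters
        ])


def cluster_and_rank_poses(matrix: np.ndarray, cutoff: float, poses,
                           method: str = "average") -> PoseClusterSet:
    """Agglomerative clustering cut at ``cutoff``, ranked by best score.

    Ties in score are broken by pose order; output is invariant to the
    input ordering up to that tie rule.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != matrix.shape[1] or not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix must be square and symmetric")
    if matrix.shape[0] != len(poses):
        raise ValueError("matrix size does not match number of poses")
    link = linkage(squareform(matrix, checks=False), method=method)
    flat = fcluster(link, t=cutoff, criterion="distance")
    clusters = []
    for label in np.unique(flat):
        members = [poses[i] for i in np.flatnonzero(flat == label)]
        members.sort(key=lambda p: (p.score, p.pose_id))
        clusters.append(members)
    clusters.sort(key=lambda ms: (ms[0].score, ms[0].pose_id))
    out = []
    labels = {}
    for rank, members in enumerate(clusters, start=1):
        out.append(PoseCluster(
            rank=rank,
            members=tuple(p.pose_id for p in members),
            best_score=members[0].score,
            best_pose_id=members[0].pose_id,
        ))
        for p in members:
            labels[p.pose_id] = rank
    return PoseClusterSet(clusters=tuple(out), cutoff=cutoff, labels=labels)
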