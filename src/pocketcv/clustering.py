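"""Two-stage CV-space cluster analysis for ensemble selection.

The goal is a maximally diverse, bounded-size set of receptor
conformations: frames are first binned into equal-width slices of the
site gyration radius so that rare, strongly contracted pocket states
cannot be swallowed by the bulk of the trajectory; a proportional
cluster budget x_i = (N_i / N_tot) * N_c is allocated per slice (with
the total inflated in +10 steps until every populated slice keeps at
least two clusters); hierarchical agglomerative clustering inside each
slice seeds a global k-means refinement; finally one representative
frame per cluster is extracted.

All distances are computed on standardized CV columns (zero mean, unit
variance over the whole series) because the CVs mix Å and dimensionless
contact counts.  The pipeline contains no randomized initialization:
identical input series give identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .cvs import CVSeries

__all__ = [
    "SliceAssignment",
    "ClusterAllocation",
    "ClusterResult",
    "standardize",
    "slice_by_rog",
    "allocate_cluster_counts",
    "hierarchical_seed_clusters",
    "kmeans_refine",
    "extract_representatives",
    "cluster_ensemble",
]


def standardize(values: np.ndarray) -> np.ndarray:
    """Z-score each column over all frames; constant columns become 0."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (values - mean) / std


@dataclass(frozen=True)
class SliceAssignment:
    slice_of_frame: np.ndarray   # int in [1, n_slices] per frame
    boundaries: np.ndarray       # (n_slices + 1,) edges in RoG Å

    @property
    def n_slices(self) -> int:
        return len(self.boundaries) - 1

    def frames_in(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.slice_of_frame == s)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(self.frames_in(s)) for s in range(1, self.n_slices + 1)])


def slice_by_rog(series: CVSeries, rog_column: str | int = 0,
                 n_slices: int = 30) -> SliceAssignment:
    """Bin frames into equal-width slices of the gyration-radius column.

    Bins are half-open on the right except the last, which is closed so
    the maximum is assigned.  A frame exactly on an internal boundary
    goes to the higher slice.
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    rog = (series.column(rog_column) if isinstance(rog_column, str)
           else series.values[:, rog_column])
    lo, hi = float(rog.min()), float(rog.max())
    if hi <= lo:
        raise ValueError("gyration-radius column is constant; cannot slice")
    edges = np.linspace(lo, hi, n_slices + 1)
    idx = np.minimum(np.searchsorted(edges, rog, side="right"), n_slices)
    return SliceAssignment(slice_of_frame=idx.astype(int), boundaries=edges)


@dataclass(frozen=True)
class ClusterAllocation:
    base_n_c: int
    final_n_c: int
    counts: np.ndarray        # x_i per slice
    sizes: np.ndarray         # N_i per slice
    exempt: np.ndarray        # slices too small for the >=2 rule

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def allocate_cluster_counts(sizes, base_n_c: int = 100,
                            increment: int = 10) -> ClusterAllocation:
    """Proportional per-slice cluster budget with >=2-per-slice inflation.

    x_i = round((N_i / N_tot) * N_c), clipped to the slice size.  If any
    slice with at least two frames receives fewer than two clusters, N_c
    grows by ``increment`` and the allocation is recomputed.  Slices
    with fewer than two frames are exempt (they get one cluster per
    frame); without this guard the iteration could never terminate.
    """
    sizes = np.asarray(sizes, dtype=int)
    n_tot = int(sizes.sum())
    if n_tot < 1:
        raise ValueError("no frames to allocate")
    exempt = sizes < 2
    if exempt.any() and (sizes[exempt] > 0).any():
        warnings.warn(
            f"{int((sizes[exempt] > 0).sum())} slice(s) hold a single frame; "
            "exempt from the >=2-clusters rule"
        )
    n_c = base_n_c
    while True:
        counts = _round_half_away(sizes / n_tot * n_c).astype(int)
        counts = np.minimum(counts, sizes)
        counts[exempt] = sizes[exempt]
        if np.all(counts[~exempt] >= 2) or not (~exempt).any():
            return ClusterAllocation(base_n_c=base_n_c, final_n_c=n_c,
                                     counts=counts, sizes=sizes, exempt=exempt)
        n_c += increment


@dataclass
class ClusterResult:
    labels: np.ndarray                 # per-frame cluster label, 0-based
    centroids: np.ndarray              # (n_clusters, n_cvs) standardized space
    stage: str                         # "hierarchical" | "kmeans"
    representatives: np.ndarray | None = None  # frame index per cluster
    meta: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def hierarchical_seed_clusters(series: CVSeries, slices: SliceAssignment,
                               allocation: ClusterAllocation,
                               method: str = "complete") -> ClusterResult:
    """Per-slice agglomerative clustering in standardized CV space."""
    z = standardize(series.values)
    labels = np.full(series.n_frames, -1, dtype=int)
    centroids = []
    offset = 0
    for s in range(1, slices.n_slices + 1):
        frames = slices.frames_in(s)
        if len(frames) == 0:
            continue
        want = int(allocation.counts[s - 1])
        if want > len(frames):
            warnings.warn(f"slice {s}: requested {want} clusters for "
                          f"{len(frames)} frames; clipped")
            want = len(frames)
        # exact duplicates cannot be separated by any distance cut
        n_distinct = len(np.unique(z[frames], axis=0))
        want = min(want, n_distinct)
        if len(frames) == 1 or want <= 1:
            local = np.zeros(len(frames), dtype=int)
            n_local = 1
        else:
            link = linkage(z[frames], method=method)
            local = fcluster(link, t=want, criterion="maxclust") - 1
            n_local = local.max() + 1
        labels[frames] = local + offset
        for c in range(n_local):
            centroids.append(z[frames[local == c]].mean(axis=0))
        offset += n_local
    return ClusterResult(labels=labels, centroids=np.asarray(centroids),
                         stage="hierarchical")


def kmeans_refine(series: CVSeries, seeds: ClusterResult,
                  max_iter: int = 10_000) -> ClusterResult:
    """Deterministic Lloyd iterations from the hierarchical seed centroids.

    The cluster count is preserved: a cluster left empty by an
    assignment step is re-seeded with the frame farthest from its
    current centroid.  Ties in the nearest-centroid assignment go to
    the lowest cluster index.
    """
    z = standardize(series.values)
    centroids = np.array(seeds.centroids, dtype=float, copy=True)
    k = len(centroids)
    labels = np.full(series.n_frames, -1, dtype=int)
    for _ in range(max_iter):
        d = cdist(z, centroids)
        new_labels = np.argmin(d, axis=1)
        for c in range(k):  # empty-cluster repair, deterministic order
            if not np.any(new_labels == c):
                taken = d[np.arange(len(z)), new_labels]
                far = int(np.argmax(taken))
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = z[labels == c].mean(axis=0)
    return ClusterResult(labels=labels, centroids=centroids, stage="kmeans",
                         meta=dict(seeds.meta))


def extract_representatives(result: ClusterResult, series: CVSeries,
                            trajectory=None):
    """Pick, per cluster, the member frame nearest its centroid.

    Ties are broken by earliest frame index.  Returns ``(result,
    manifest)`` where the manifest is a DataFrame with one row per
    cluster (frame index, cluster size, raw CV values); when a
    trajectory is supplied its frames are returned alongside as
    structures.
    """
    z = standardize(series.values)
    reps = np.empty(result.n_clusters, dtype=int)
    sizes = np.empty(result.n_clusters, dtype=int)
    for c in range(result.n_clusters):
        members = np.flatnonzero(result.labels == c)
        d = np.linalg.norm(z[members] - result.centroids[c], axis=1)
        reps[c] = members[int(np.argmin(d))]  # argmin takes the earliest tie
        sizes[c] = len(members)
    result.representatives = reps
    manifest = pd.DataFrame({
        "cluster": np.arange(result.n_clusters),
        "frame": reps,
        "size": sizes,
        "time": series.times[reps],
    })
    for k, name in enumerate(series.names):
        manifest[name] = series.values[reps, k]
    if trajectory is not None:
        structures = [trajectory.frame(int(i)) for i in reps]
        return result, manifest, structures
    return result, manifest


def cluster_ensemble(series: CVSeries, rog_column: str | int = 0,
                     n_slices: int = 30, base_n_c: int = 100,
                     increment: int = 10, linkage_method: str = "complete",
                     max_iter: int = 10_000):
    """Full pipeline: slice -> allocate -> seed -> refine -> representatives.

    Returns ``(result, manifest, allocation, slices)``.
    """
    slices = slice_by_rog(series, rog_column, n_slices)
    allocation = allocate_cluster_counts(slices.sizes, base_n_c, increment)
    seeds = hierarchical_seed_clusters(series, slices, allocation, linkage_method)
    refined = kmeans_refine(series, seeds, max_iter)
    refined, manifest = extract_representatives(refined, series)
    return refined, manifest, allocation, slices
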