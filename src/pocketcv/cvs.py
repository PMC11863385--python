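"""Binding-site shape collective variables.

Three CV families describe the shape and the degree of closure of a
binding pocket:

* ``ROG`` — mass-weighted radius of gyration of the site's backbone
  atoms (pocket compactness);
* ``CIP`` — contacts across an inertia plane: a smooth coordination
  number between the two residue groups lying on opposite sides of a
  plane orthogonal to one principal inertia axis of the site, passing
  through its geometric center;
* ``CRD`` — contacts between quasi-rigid domains: the same coordination
  number evaluated between site residues of a mobile domain and of the
  core domain at their interface.

Contacts are counted with the rational switching function
``s(r) = (1 - x^n) / (1 - x^m)`` with ``x = (r - d0)/r0``, the standard
smooth contact counter of biased-MD engines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import SiteDefinition, Structure

__all__ = [
    "SwitchingParams",
    "CVDefinition",
    "InertiaFrame",
    "CVSeries",
    "radius_of_gyration",
    "principal_inertia_frame",
    "partition_residues_across_plane",
    "switching_value",
    "coordination_number",
    "evaluate_cv",
    "evaluate_cv_series",
]


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function parameters (distances in Å)."""

    r0: float = 4.5
    n: int = 6
    m: int = 12
    d0: float = 0.0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (0 < self.n < self.m):
            raise ValueError("exponents must satisfy m > n > 0")
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")


def switching_value(r, params: SwitchingParams):
    """Evaluate the rational switch at distance(s) ``r``.

    Continuous and non-increasing in r; equals 1 for r <= d0, n/m at
    the removable singularity x = 1, and decays to 0 as r grows.
    """
    r = np.asarray(r, dtype=float)
    x = np.maximum((r - params.d0) / params.r0, 0.0)
    out = np.empty_like(x)
    near_one = np.abs(x - 1.0) < 1e-10
    out[near_one] = params.n / params.m
    safe = ~near_one
    xs = x[safe]
    out[safe] = (1.0 - xs ** params.n) / (1.0 - xs ** params.m)
    return out if out.ndim else float(out)


def coordination_number(coords_a, coords_b, params: SwitchingParams) -> float:
    """Sum of switching values over all A x B atom pairs."""
    coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if coords_a.size == 0 or coords_b.size == 0:
        warnings.warn("empty group in coordination number; returning 0")
        return 0.0
    return float(np.sum(switching_value(cdist(coords_a, coords_b), params)))


def radius_of_gyration(coords, weights=None) -> float:
    """Weighted radius of gyration, Å: sqrt(sum w |r - r_c|^2 / sum w)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("radius of gyration of an empty atom set")
    if weights is None:
        weights = np.ones(len(coords))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    center = np.average(coords, axis=0, weights=weights)
    sq = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=weights)))


@dataclass(frozen=True)
class InertiaFrame:
    """Principal inertia axes of an atom set about its geometric center.

    ``axes[k]`` is the unit eigenvector for ``moments[k]`` (ascending).
    Signs are fixed so each axis's largest-magnitude component is
    positive; the largest-moment axis is then flipped if needed to make
    the frame right-handed.
    """

    center: np.ndarray
    axes: np.ndarray      # (3, 3), rows are unit axes
    moments: np.ndarray   # (3,), ascending


def principal_inertia_frame(coords, weights=None) -> InertiaFrame:
    """Diagonalize the inertia tensor of a point set.

    The center is the *unweighted* geometric center; the tensor uses the
    given weights (masses).  Collinear or near-collinear sets are
    rejected because two of the three axes would be undetermined.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(coords) < 3:
        raise ValueError("need at least 3 atoms for an inertia frame")
    if weights is None:
        weights = np.ones(len(coords))
    weights = np.asarray(weights, dtype=float)
    center = coords.mean(axis=0)
    rel = coords - center
    sv = np.linalg.svd(rel, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) atom set: inertia axes undetermined")
    r2 = np.sum(rel ** 2, axis=1)
    tensor = np.einsum("i,i,jk->jk", weights, r2, np.eye(3)) - np.einsum(
        "i,ij,ik->jk", weights, rel, rel
    )
    moments, vecs = np.linalg.eigh(tensor)  # ascending
    axes = vecs.T.copy()
    for k in range(3):
        j = int(np.argmax(np.abs(axes[k])))
        if axes[k, j] < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:  # restore right-handedness via the last axis
        axes[2] = -axes[2]
    return InertiaFrame(center=center, axes=axes, moments=np.maximum(moments, 0.0))


def partition_residues_across_plane(structure: Structure, site: SiteDefinition,
                                    axis, center):
    """Split site residues by the side of a plane their center falls on.

    A residue goes to group A when the signed projection of its
    heavy-atom geometric center onto ``axis`` (relative to ``center``)
    is <= 0, to group B otherwise; a residue exactly on the plane is
    assigned to A.
    """
    axis = np.asarray(axis, dtype=float)
    if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-6):
        raise ValueError("axis must be a unit vector")
    center = np.asarray(center, dtype=float)
    group_a, group_b = [], []
    for rid in site:
        proj = float(np.dot(structure.residue_heavy_center(rid) - center, axis))
        (group_a if proj <= 0 else group_b).append(rid)
    if not group_a or not group_b:
        warnings.warn("inertia plane leaves one side empty")
    return group_a, group_b


@dataclass(frozen=True)
class CVDefinition:
    """One collective variable bound to fixed atom groups of a topology."""

    name: str
    kind: str                              # ROG | CIP | CRD
    group_a: np.ndarray                    # atom indices
    group_b: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    weights: np.ndarray | None = None      # ROG only
    switching: SwitchingParams | None = None
    residues_a: tuple[str, ...] = ()
    residues_b: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("ROG", "CIP", "CRD"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if len(self.group_a) == 0:
            raise ValueError(f"CV {self.name}: group A is empty")
        if self.kind == "ROG":
            if len(self.group_b):
                raise ValueError("ROG takes a single atom group")
        else:
            if self.switching is None:
                raise ValueError(f"CV {self.name}: contact CV needs switching params")
            if np.intersect1d(self.group_a, self.group_b).size:
                raise ValueError(f"CV {self.name}: groups A and B overlap")

    @property
    def max_atom_index(self) -> int:
        idx = int(self.group_a.max())
        if len(self.group_b):
            idx = max(idx, int(self.group_b.max()))
        return idx


def evaluate_cv(coords: np.ndarray, cv: CVDefinition) -> float:
    """Evaluate one CV on a single coordinate frame (n_atoms, 3)."""
    coords = np.asarray(coords, dtype=float)
    if cv.kind == "ROG":
        return radius_of_gyration(coords[cv.group_a], cv.weights)
    return coordination_number(coords[cv.group_a], coords[cv.group_b], cv.switching)


@dataclass
class CVSeries:
    """Frames x CVs value matrix with frame times in ps."""

    values: np.ndarray
    names: list[str]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a frames x CVs matrix")
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count does not match CV names")
        if self.values.shape[0] != len(self.times):
            raise ValueError("row count does not match frame times")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CV series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "time", self.times)
        return df

    def write_tsv(self, path) -> None:
        """COLVAR-style tab-separated file: time column then one per CV."""
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read_tsv(cls, path) -> "CVSeries":
        df = pd.read_csv(path, sep="\t")
        if "time" not in df.columns:
            raise ValueError("CV series file lacks a 'time' column")
        names = [c for c in df.columns if c != "time"]
        return cls(values=df[names].to_numpy(), names=names,
                   times=df["time"].to_numpy())


def evaluate_cv_series(frames: np.ndarray, cvs, times=None) -> CVSeries:
    """Evaluate a CV set on every frame of a coordinate stack.

    ``frames`` is (n_frames, n_atoms, 3); atom order must match the CV
    atom indices (checked against the largest index before any frame is
    processed).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
    n_atoms = frames.shape[1]
    for cv in cvs:
        if cv.max_atom_index >= n_atoms:
            raise ValueError(
                f"CV {cv.name} references atom {cv.max_atom_index} but the "
                f"trajectory has only {n_atoms} atoms"
            )
    if times is None:
        times = np.arange(frames.shape[0], dtype=float)
    values = np.empty((frames.shape[0], len(cvs)))
    for f in range(frames.shape[0]):
        for k, cv in enumerate(cvs):
            values[f, k] = evaluate_cv(frames[f], cv)
    return CVSeries(values=values, names=[cv.name for cv in cvs], times=times)
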