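"""Holo-likeness metrics for structures, ensembles and complexes.

All RMSD metrics superpose on the selection being measured (the
binding-site atoms), so a pocket can be judged on its own geometry
independently of global domain motion.  Per-residue flags use one
whole-site superposition followed by per-residue heavy-atom RMSDs in
that common frame — a residue cannot "rescue" itself with a private
fit.  The fraction of native contacts F_nat follows the CAPRI-style
atom-pair convention with a 5 Å shell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .structures import SiteDefinition, Structure, superpose

__all__ = [
    "HoloCriteria",
    "ContactSet",
    "EnsembleSummary",
    "binding_site_rmsd",
    "per_residue_holo_flags",
    "rmsd_distribution",
    "native_contact_set",
    "fraction_native_contacts",
    "ensemble_summary",
]


@dataclass(frozen=True)
class HoloCriteria:
    """Per-residue heavy-atom RMSD thresholds for calling a residue holo-like."""

    default_threshold: float = 2.0
    per_residue: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.default_threshold <= 0 or any(
            t <= 0 for t in self.per_residue.values()
        ):
            raise ValueError("thresholds must be positive")

    def threshold(self, res_id: str) -> float:
        return self.per_residue.get(res_id, self.default_threshold)


def _matched_atoms(model: Structure, reference: Structure, site,
                   subset: str) -> tuple[np.ndarray, np.ndarray, list]:
    """Atom correspondence over the site by (residue, atom name)."""
    if subset == "CA":
        sel_m = model.ca_indices(list(site))
        sel_r = reference.ca_indices(list(site))
    elif subset == "heavy":
        sel_m = model.heavy_indices(list(site))
        sel_r = reference.heavy_indices(list(site))
    else:
        raise ValueError("subset must be 'CA' or 'heavy'")
    key_m = {(model.res_ids[i], model.atom_names[i]): i for i in sel_m}
    key_r = {(reference.res_ids[i], reference.atom_names[i]): i for i in sel_r}
    common = [k for k in key_m if k in key_r]
    missing = sorted(set(key_m) ^ set(key_r))
    if missing:
        raise ValueError(f"atoms present in only one structure: {missing[:8]}")
    if not common:
        raise ValueError("no matching site atoms between structures")
    idx_m = np.array([key_m[k] for k in common])
    idx_r = np.array([key_r[k] for k in common])
    return idx_m, idx_r, common


def binding_site_rmsd(model: Structure, reference: Structure,
                      site: SiteDefinition | list, subset: str = "heavy") -> float:
    """Site RMSD after optimal superposition of the same selection, Å."""
    idx_m, idx_r, _ = _matched_atoms(model, reference, site, subset)
    fit = superpose(model.coords[idx_m], reference.coords[idx_r])
    return fit.rmsd


def per_residue_holo_flags(model: Structure, reference: Structure,
                           site: SiteDefinition,
                           criteria: HoloCriteria | None = None,
                           charged_residues=()):
    """Flag residues whose conformation is holo-like.

    One global superposition of all site heavy atoms onto the
    reference; per-residue heavy-atom RMSDs are then measured in that
    fixed frame and compared to the per-residue thresholds.

    Returns a DataFrame (residue, rmsd, threshold, holo_like, charged)
    plus the simultaneous counts (total flagged, charged flagged).
    """
    criteria = criteria or HoloCriteria()
    idx_m, idx_r, keys = _matched_atoms(model, reference, site, "heavy")
    fit = superpose(model.coords[idx_m], reference.coords[idx_r])
    moved = fit.apply(model.coords[idx_m])
    charged = set(charged_residues)
    rows = []
    for rid in site:
        sel = [j for j, (r, _n) in enumerate(keys) if r == rid]
        rmsd = float(np.sqrt(np.mean(np.sum(
            (moved[sel] - reference.coords[idx_r][sel]) ** 2, axis=1))))
        thr = criteria.threshold(rid)
        rows.append((rid, rmsd, thr, rmsd <= thr, rid in charged))
    table = pd.DataFrame(rows, columns=["residue", "rmsd", "threshold",
                                        "holo_like", "charged"])
    n_holo = int(table["holo_like"].sum())
    n_holo_charged = int((table["holo_like"] & table["charged"]).sum())
    return table, n_holo, n_holo_charged


def rmsd_distribution(values, bin_width: float = 0.2,
                      points_per_angstrom: int = 20):
    """Histogram + cubic-spline density of an RMSD sample.

    Values are grouped into ``bin_width``-wide bins, normalized to unit
    area, and interpolated with a cubic spline evaluated every
    ``1 / points_per_angstrom`` Å.  Negative spline overshoot is
    clipped to zero and the curve renormalized.

    Returns ``(grid, density)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty RMSD sample")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = max(np.ceil(values.max() / bin_width) * bin_width, lo + bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist, edges = np.histogram(values, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # pad with empty bins so the spline is anchored at zero on both sides
    pad = 2
    centers = np.concatenate([
        centers[0] - bin_width * np.arange(pad, 0, -1), centers,
        centers[-1] + bin_width * np.arange(1, pad + 1),
    ])
    hist = np.concatenate([np.zeros(pad), hist, np.zeros(pad)])
    spline = CubicSpline(centers, hist)
    step = 1.0 / points_per_angstrom
    grid = np.arange(centers[0], centers[-1] + step / 2, step)
    density = np.clip(spline(grid), 0.0, None)
    area = np.trapezoid(density, grid)
    if area > 0:
        density = density / area
    return grid, density


@dataclass(frozen=True)
class ContactSet:
    """Reference ligand-protein heavy-atom contacts within a cutoff shell."""

    pairs: tuple[tuple[tuple[str, str], tuple[str, str]], ...]
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)


def _atom_key_index(structure: Structure, indices) -> dict:
    return {(structure.res_ids[i], structure.atom_names[i]): i for i in indices}


def native_contact_set(reference: Structure, ligand_res: str,
                       cutoff: float = 5.0) -> ContactSet:
    """All (ligand heavy atom, protein heavy atom) pairs within the shell."""
    lig_idx = reference.heavy_indices([ligand_res])
    if len(lig_idx) == 0:
        raise KeyError(f"ligand residue {ligand_res!r} has no heavy atoms")
    prot_res = reference.protein_residues
    prot_idx = reference.heavy_indices(prot_res)
    d = np.linalg.norm(
        reference.coords[lig_idx][:, None, :] - reference.coords[prot_idx][None],
        axis=-1,
    )
    pairs = []
    for a, b in zip(*np.nonzero(d <= cutoff)):
        i, j = lig_idx[a], prot_idx[b]
        pairs.append((
            (str(reference.res_ids[i]), str(reference.atom_names[i])),
            (str(reference.res_ids[j]), str(reference.atom_names[j])),
        ))
    if not pairs:
        warnings.warn(f"no contacts within {cutoff} Å of {ligand_res}")
    return ContactSet(pairs=tuple(pairs), cutoff=cutoff)


def fraction_native_contacts(model: Structure, contacts: ContactSet) -> float:
    """Fraction of reference contacts preserved in the model complex."""
    if len(contacts) == 0:
        warnings.warn("empty reference contact set; F_nat defined as 0")
        return 0.0
    keys = _atom_key_index(model, range(model.n_atoms))
    kept = 0
    for (lig_key, prot_key) in contacts.pairs:
        try:
            i, j = keys[lig_key], keys[prot_key]
        except KeyError as exc:
            raise ValueError(f"model lacks atom {exc.args[0]}") from None
        if np.linalg.norm(model.coords[i] - model.coords[j]) <= contacts.cutoff:
            kept += 1
    return kept / len(contacts)


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-metric percentage of frames under each threshold, plus the minimum."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.1f")


def ensemble_summary(values_by_metric: dict[str, np.ndarray],
                     thresholds=(2.0, 2.5)) -> EnsembleSummary:
    """Summarize per-frame RMSD samples the way ensemble reports tabulate them.

    For each metric: the percentage of frames with RMSD below each
    threshold (one decimal) and the minimum value (one decimal).
    """
    rows = []
    for metric, values in values_by_metric.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError(f"metric {metric!r} has no values")
        row = {"metric": metric}
        for thr in thresholds:
            row[f"pct_below_{thr:g}"] = round(
                100.0 * float(np.mean(values < thr)), 1
            )
        row["min"] = round(float(values.min()), 1)
        rows.append(row)
    return EnsembleSummary(pd.DataFrame(rows))
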