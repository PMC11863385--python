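"""Structures, residue selections, and rigid-body superposition.

The in-memory :class:`Structure` is a flat, array-backed container over the
atoms of a single PDB model: enough to define atom-subset selections
(heavy / backbone / C-alpha), residue-level geometry, and binding-site
definitions, without carrying a full entity hierarchy around.

Residues are identified throughout by strings of the form ``"A:15"``
(chain, colon, author residue number, optional insertion code appended,
e.g. ``"A:15B"``).  Numbering is taken verbatim from the PDB record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.SVDSuperimposer import SVDSuperimposer

__all__ = [
    "Structure",
    "SiteDefinition",
    "DomainMap",
    "SuperpositionResult",
    "read_structure",
    "write_structure",
    "superpose",
    "select_site_by_ligand",
    "merge_site_predictions",
    "classify_residue_charge",
    "min_residue_distance",
    "read_residue_list",
    "write_residue_list",
    "read_domain_map",
    "write_domain_map",
    "STANDARD_AMINO_ACIDS",
    "DEFAULT_CHARGED_RESIDUES",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL MSE".split()
)

# Titratable side chains at physiological pH; HIS excluded by default because
# its protonation state is ambiguous near pH 7.
DEFAULT_CHARGED_RESIDUES = frozenset({"ASP", "GLU", "LYS", "ARG"})

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O"})

_ELEMENT_MASS = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "SE": 78.971, "NA": 22.990, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "MN": 54.938, "FE": 55.845, "ZN": 65.38, "CU": 63.546,
}


def _mass_of(element: str, atom_name: str) -> float:
    el = element.strip().upper()
    if el in _ELEMENT_MASS:
        return _ELEMENT_MASS[el]
    guess = atom_name.strip().lstrip("0123456789")[:1].upper()
    return _ELEMENT_MASS.get(guess, 12.011)


def residue_sort_key(res_id: str) -> tuple[str, int, str]:
    """Sort key (chain, residue number, insertion code) for ``"A:15B"`` ids."""
    chain, _, num = res_id.partition(":")
    digits = num
    icode = ""
    while digits and not digits[-1].isdigit():
        icode = digits[-1] + icode
        digits = digits[:-1]
    return (chain, int(digits) if digits else 0, icode)


@dataclass
class Structure:
    """Array-backed single-model structure.

    All per-atom arrays share the same length and order; ``residue_ids``
    lists the distinct residues in file order.
    """

    atom_names: np.ndarray            # str per atom
    elements: np.ndarray              # str per atom
    res_ids: np.ndarray               # str per atom, "chain:resnum[icode]"
    res_names: np.ndarray             # str per atom
    coords: np.ndarray                # (n_atoms, 3) float, Å
    masses: np.ndarray                # (n_atoms,) float, Da
    is_hydrogen: np.ndarray           # bool per atom
    is_hetatm: np.ndarray             # bool per atom
    residue_ids: list[str] = field(default_factory=list)
    _res_atoms: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.coords) == 0:
            raise ValueError("structure has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not np.all(self.masses > 0):
            raise ValueError("non-positive atom mass")
        if not self.residue_ids:
            seen: dict[str, list[int]] = {}
            order: list[str] = []
            for i, rid in enumerate(self.res_ids):
                if rid not in seen:
                    seen[rid] = []
                    order.append(rid)
                seen[rid].append(i)
            self.residue_ids = order
            self._res_atoms = {r: np.asarray(ix, dtype=int) for r, ix in seen.items()}

    # ------------------------------------------------------------------ basic
    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def has_residue(self, res_id: str) -> bool:
        return res_id in self._res_atoms

    def residue_atoms(self, res_id: str) -> np.ndarray:
        try:
            return self._res_atoms[res_id]
        except KeyError:
            raise KeyError(f"residue {res_id!r} not in structure") from None

    def residue_name(self, res_id: str) -> str:
        return str(self.res_names[self.residue_atoms(res_id)[0]])

    def is_protein_residue(self, res_id: str) -> bool:
        return self.residue_name(res_id) in STANDARD_AMINO_ACIDS

    @property
    def protein_residues(self) -> list[str]:
        return [r for r in self.residue_ids if self.is_protein_residue(r)]

    # ------------------------------------------------------------- selections
    def _restrict(self, mask: np.ndarray, res_ids=None) -> np.ndarray:
        if res_ids is not None:
            wanted = set(res_ids)
            for r in wanted:
                self.residue_atoms(r)  # existence check
            in_sel = np.fromiter((r in wanted for r in self.res_ids), bool, self.n_atoms)
            mask = mask & in_sel
        return np.flatnonzero(mask)

    def heavy_indices(self, res_ids=None) -> np.ndarray:
        """Non-hydrogenous atom indices, optionally restricted to residues."""
        return self._restrict(~self.is_hydrogen, res_ids)

    def backbone_indices(self, res_ids=None) -> np.ndarray:
        """Protein backbone (N, CA, C, O) heavy-atom indices."""
        bb = np.isin(self.atom_names, list(BACKBONE_ATOM_NAMES)) & ~self.is_hydrogen
        prot = np.fromiter(
            (rn in STANDARD_AMINO_ACIDS for rn in self.res_names), bool, self.n_atoms
        )
        return self._restrict(bb & prot, res_ids)

    def ca_indices(self, res_ids=None) -> np.ndarray:
        return self._restrict((self.atom_names == "CA") & ~self.is_hydrogen, res_ids)

    def residue_heavy_center(self, res_id: str) -> np.ndarray:
        """Unweighted geometric center of the residue's heavy atoms."""
        idx = self.heavy_indices([res_id])
        if len(idx) == 0:
            idx = self.residue_atoms(res_id)
        return self.coords[idx].mean(axis=0)

    # ------------------------------------------------------------- transforms
    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Copy with coordinates mapped through ``x -> R x + t``."""
        new = self.copy()
        new.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return new

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ValueError("coordinate array shape mismatch")
        new = self.copy()
        new.coords = coords.copy()
        return new

    def copy(self) -> "Structure":
        return Structure(
            atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            res_ids=self.res_ids.copy(),
            res_names=self.res_names.copy(),
            coords=self.coords.copy(),
            masses=self.masses.copy(),
            is_hydrogen=self.is_hydrogen.copy(),
            is_hetatm=self.is_hetatm.copy(),
            residue_ids=list(self.residue_ids),
            _res_atoms={k: v.copy() for k, v in self._res_atoms.items()},
        )


@dataclass(frozen=True)
class SiteDefinition:
    """Ordered list of binding-site residues with a provenance tag."""

    residues: tuple[str, ...]
    provenance: str = "user"  # ligand-derived | merged-prediction | user

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residues in site definition")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def validate(self, structure: Structure) -> None:
        missing = [r for r in self.residues if not structure.has_residue(r)]
        if missing:
            raise ValueError(f"site residues not in structure: {missing}")


@dataclass(frozen=True)
class DomainMap:
    """Residue -> quasi-rigid domain label (e.g. CORE, LID, NMP)."""

    mapping: dict[str, str]

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.mapping.values():
            if lab not in seen:
                seen.append(lab)
        return seen

    def domain_of(self, res_id: str) -> str:
        try:
            return self.mapping[res_id]
        except KeyError:
            raise KeyError(f"residue {res_id!r} has no domain assignment") from None

    def residues_of(self, label: str) -> list[str]:
        return [r for r, lab in self.mapping.items() if lab == label]

    def validate(self, structure: Structure) -> None:
        missing = [r for r in structure.protein_residues if r not in self.mapping]
        if missing:
            raise ValueError(f"protein residues without domain label: {missing[:5]}...")


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit ``mobile -> reference`` (``y = R x + t``)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------- I/O

def _atoms_of_first_model(path):
    parser = PDBParser(QUIET=True)
    try:
        entity = parser.get_structure("s", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    models = list(entity.get_models())
    if not models:
        raise ValueError(f"no models in {path}")
    return models


def _model_to_arrays(model):
    names, elements, rids, rnames, xyz, occ, het = [], [], [], [], [], [], []
    for chain in model:
        chain_id = chain.id.strip() or "_"
        for residue in chain:
            hetflag, resseq, icode = residue.id
            rid = f"{chain_id}:{resseq}{icode.strip()}"
            # altloc: keep the highest-occupancy conformer per atom name
            best: dict[str, object] = {}
            for atom in residue.get_unpacked_list():
                o = atom.get_occupancy()
                o = 1.0 if o is None else o
                prev = best.get(atom.get_name())
                if prev is None or o > prev[1]:
                    best[atom.get_name()] = (atom, o)
            for name, (atom, _o) in best.items():
                names.append(name)
                elements.append((atom.element or "").strip().upper())
                rids.append(rid)
                rnames.append(residue.get_resname().strip())
                xyz.append(atom.get_coord())
                het.append(hetflag.strip() != "")
    return names, elements, rids, rnames, xyz, het


def read_structure(path) -> Structure:
    """Read the first model of a PDB file into a :class:`Structure`.

    HETATM records (ligands, ions, waters) are retained as distinct
    residues.  For disordered atoms only the highest-occupancy altloc
    conformer is kept.
    """
    models = _atoms_of_first_model(path)
    names, elements, rids, rnames, xyz, het = _model_to_arrays(models[0])
    if not names:
        raise ValueError(f"structure {path} contains no atoms")
    elements_arr = np.array(elements, dtype=object)
    names_arr = np.array(names, dtype=object)
    masses = np.array([_mass_of(e, n) for e, n in zip(elements, names)])
    is_h = np.array([(e or n[:1]).upper() in ("H", "D") for e, n in zip(elements, names)])
    return Structure(
        atom_names=names_arr,
        elements=elements_arr,
        res_ids=np.array(rids, dtype=object),
        res_names=np.array(rnames, dtype=object),
        coords=np.asarray(xyz, dtype=float),
        masses=masses,
        is_hydrogen=is_h,
        is_hetatm=np.array(het, dtype=bool),
    )


def _format_atom_line(record: str, serial: int, name: str, resname: str,
                      chain: str, resseq: int, icode: str, xyz, element: str) -> str:
    # PDB v3.3 fixed columns; 1-letter-element names start in column 14
    if len(name) < 4 and len(element) <= 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"{record:<6s}{serial:>5d} {name_field} {resname:<3s} {chain:1s}"
        f"{resseq:>4d}{icode:1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def _structure_record_lines(structure: Structure) -> list[str]:
    lines = []
    for serial, i in enumerate(range(structure.n_atoms), start=1):
        rid = structure.res_ids[i]
        chain, _, num = rid.partition(":")
        digits, icode = num, ""
        while digits and not digits[-1].isdigit():
            icode = digits[-1] + icode
            digits = digits[:-1]
        record = "HETATM" if structure.is_hetatm[i] else "ATOM"
        lines.append(
            _format_atom_line(
                record, serial % 100000, str(structure.atom_names[i]),
                str(structure.res_names[i]), chain[:1], int(digits), icode[:1] or " ",
                structure.coords[i], str(structure.elements[i])[:2],
            )
        )
    return lines


def write_structure(structure: Structure, path) -> None:
    """Write a single-model PDB file (fixed-width ATOM/HETATM records)."""
    with open(path, "w") as fh:
        fh.write("\n".join(_structure_record_lines(structure)))
        fh.write("\nEND\n")


def write_multimodel(structure: Structure, frames: np.ndarray, path) -> None:
    """Write a stack of coordinate frames as a multi-model PDB."""
    with open(path, "w") as fh:
        for m, coords in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:>4d}\n")
            fh.write("\n".join(_structure_record_lines(structure.with_coords(coords))))
            fh.write("\nENDMDL\n")
        fh.write("END\n")


# ----------------------------------------------------------- site operations

def select_site_by_ligand(structure: Structure, ligand_res: str,
                          cutoff: float = 3.5) -> SiteDefinition:
    """Protein residues with a heavy atom within ``cutoff`` Å of the ligand.

    The default 3.5 Å heavy-atom shell is the standard first-shell
    definition of a ligand binding site.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_idx = structure.heavy_indices([ligand_res])
    if len(lig_idx) == 0:
        raise KeyError(f"ligand residue {ligand_res!r} has no heavy atoms")
    lig_xyz = structure.coords[lig_idx]
    selected = []
    for rid in structure.residue_ids:
        if rid == ligand_res or not structure.is_protein_residue(rid):
            continue
        idx = structure.heavy_indices([rid])
        if len(idx) == 0:
            continue
        d = np.linalg.norm(structure.coords[idx][:, None, :] - lig_xyz[None], axis=-1)
        if d.min() <= cutoff:
            selected.append(rid)
    if not selected:
        warnings.warn(f"no residues within {cutoff} Å of {ligand_res}")
    return SiteDefinition(tuple(selected), provenance="ligand-derived")


def merge_site_predictions(sites, scores, score_floor: float = 0.01) -> SiteDefinition:
    """Union of predicted sites whose confidence passes the floor.

    Predictions with confidence below ``score_floor`` (default 0.01, the
    conventional floor below which pocket predictions are discarded as
    unreliable) do not contribute.
    """
    if len(sites) != len(scores):
        raise ValueError("sites and scores must have the same length")
    kept = [s for s, c in zip(sites, scores) if c >= score_floor]
    if not kept:
        raise ValueError("no reliable site: all predictions below the score floor")
    residues = sorted({r for s in kept for r in s.residues}, key=residue_sort_key)
    return SiteDefinition(tuple(residues), provenance="merged-prediction")


def classify_residue_charge(structure: Structure, site: SiteDefinition,
                            charged_set=DEFAULT_CHARGED_RESIDUES):
    """Partition site residues into (charged, other) by residue name."""
    charged, other = [], []
    for rid in site:
        name = structure.residue_name(rid)
        if name in charged_set:
            charged.append(rid)
        else:
            if name not in STANDARD_AMINO_ACIDS:
                warnings.warn(f"unknown residue name {name!r} for {rid}; "
                              "classified as uncharged")
            other.append(rid)
    return charged, other


def min_residue_distance(structure: Structure, res_a: str, res_b: str) -> float:
    """Minimum heavy-atom pair distance between two residues, Å."""
    a = structure.coords[structure.heavy_indices([res_a])]
    b = structure.coords[structure.heavy_indices([res_b])]
    if len(a) == 0 or len(b) == 0:
        return np.inf
    return float(np.linalg.norm(a[:, None, :] - b[None], axis=-1).min())


# ------------------------------------------------------------- superposition

def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Kabsch least-squares fit of ``mobile`` onto ``reference``.

    Requires >= 3 non-collinear corresponding points.  A proper rotation
    (det +1) is enforced; reflections are corrected internally.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have matching shapes")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need >= 3 corresponding 3D points")
    for pts, which in ((mobile, "mobile"), (reference, "reference")):
        centered = pts - pts.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise ValueError(f"{which} point set is collinear or degenerate")
    sup = SVDSuperimposer()
    sup.set(reference, mobile)
    sup.run()
    rot, tran = sup.get_rotran()  # row-vector convention: y = x @ rot + tran
    return SuperpositionResult(
        rotation=np.ascontiguousarray(rot.T),
        translation=np.asarray(tran, dtype=float),
        rmsd=float(sup.get_rms()),
    )


# -------------------------------------------------- plain-text list formats

def read_residue_list(path) -> list[str]:
    """Read one ``chain:resnum`` per line, '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def write_residue_list(residues, path) -> None:
    with open(path, "w") as fh:
        for r in residues:
            fh.write(f"{r}\n")


def read_domain_map(path) -> DomainMap:
    """Read ``chain:resnum<TAB>label`` lines into a :class:`DomainMap`."""
    mapping = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            rid, lab = line.split()
            mapping[rid] = lab
    return DomainMap(mapping)


def write_domain_map(domains: DomainMap, path) -> None:
    with open(path, "w") as fh:
        for rid, lab in domains.mapping.items():
            fh.write(f"{rid}\t{lab}\n")
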