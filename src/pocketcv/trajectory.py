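"""Multi-frame coordinate trajectories.

A :class:`Trajectory` pairs a topology :class:`~pocketcv.structures.Structure`
with a (frames, atoms, 3) coordinate stack and frame times in ps.  Plain-text
multi-model PDB is the native format; binary XTC/DCD files are read through
MDAnalysis when that package is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Structure, read_structure, write_multimodel


@dataclass
class Trajectory:
    topology: Structure
    coords: np.ndarray     # (n_frames, n_atoms, 3), Å
    times: np.ndarray      # (n_frames,), ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def write_pdb(self, path) -> None:
        write_multimodel(self.topology, self.coords, path)

    @classmethod
    def from_multimodel_pdb(cls, path, dt_ps: float = 1.0) -> "Trajectory":
        """Read every MODEL of a PDB file; frames are dt_ps apart."""
        from Bio.PDB import PDBParser

        topology = read_structure(path)
        parser = PDBParser(QUIET=True)
        models = list(parser.get_structure("t", str(path)).get_models())
        stacks = []
        for model in models:
            xyz = np.array([a.get_coord() for a in model.get_atoms()], dtype=float)
            if xyz.shape != (topology.n_atoms, 3):
                raise ValueError("models differ in atom count")
            stacks.append(xyz)
        coords = np.stack(stacks)
        return cls(topology, coords, np.arange(len(stacks)) * dt_ps)

    @classmethod
    def from_files(cls, topology_path, trajectory_path) -> "Trajectory":
        """Read an XTC/DCD (or any MDAnalysis-readable) trajectory."""
        import MDAnalysis as mda

        topology = read_structure(topology_path)
        u = mda.Universe(str(topology_path), str(trajectory_path))
        if u.atoms.n_atoms != topology.n_atoms:
            raise ValueError("trajectory atom count does not match topology")
        coords, times = [], []
        for ts in u.trajectory:
            coords.append(ts.positions.astype(float).copy())
            times.append(float(ts.time))
        return cls(topology, np.stack(coords), np.asarray(times))
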