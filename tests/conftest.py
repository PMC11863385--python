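import numpy as np
import pytest

from pocketcv import (
    ToyProteinSpec,
    TrajectorySpec,
    make_hinged_toy_protein,
    make_open_close_trajectory,
)
from pocketcv.structures import Structure


def make_structure(atoms):
    """Build a Structure from (name, element, res_id, res_name, xyz[, het]).

    Small hand-placed systems for oracle tests.
    """
    names, elements, rids, rnames, xyz, het = [], [], [], [], [], []
    for atom in atoms:
        name, element, rid, rname, pos = atom[:5]
        names.append(name)
        elements.append(element)
        rids.append(rid)
        rnames.append(rname)
        xyz.append(pos)
        het.append(bool(atom[5]) if len(atom) > 5 else False)
    masses = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
              "S": 32.06, "P": 30.974}
    return Structure(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_ids=np.array(rids, dtype=object),
        res_names=np.array(rnames, dtype=object),
        coords=np.asarray(xyz, dtype=float),
        masses=np.array([masses.get(e, 12.011) for e in elements]),
        is_hydrogen=np.array([e == "H" for e in elements]),
        is_hetatm=np.array(het),
    )


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture(scope="session")
def toy():
    return make_hinged_toy_protein()


@pytest.fixture(scope="session")
def toy_closed(toy):
    return toy.structure.with_coords(toy.coords_at(1.0))


@pytest.fixture(scope="session")
def open_close_traj(toy):
    schedule = tuple(np.linspace(0.0, 1.0, 40))
    return make_open_close_trajectory(
        toy, TrajectorySpec(schedule=schedule, noise_sigma=0.05, seed=11)
    )


@pytest.fixture(scope="session")
def unbiased_traj(toy):
    spec = TrajectorySpec(schedule=tuple([0.0] * 25), noise_sigma=0.15, seed=7)
    return make_open_close_trajectory(toy, spec)
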