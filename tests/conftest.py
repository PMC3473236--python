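import numpy as np
import pytest

from decoybench import make_helix_fixture, make_pocket_fixture


@pytest.fixture(scope="session")
def helix10():
    return make_helix_fixture(10)


@pytest.fixture(scope="session")
def helix20():
    return make_helix_fixture(20)


@pytest.fixture(scope="session")
def helix60():
    return make_helix_fixture(60)


@pytest.fixture(scope="session")
def pocket_small():
    """40-residue shell with a 3 A void: exposed surface, buried core, one cavity."""
    return make_pocket_fixture(3.0, 7.5, seed=2)


@pytest.fixture(scope="session")
def pocket_standard():
    """The 4 A void / 9 A shell fixture used for cavity volume checks."""
    return make_pocket_fixture(4.0, 9.0, seed=1)


def rigid_transform(rng: np.random.Generator):
    """A random proper rotation and a translation of up to ~20 A."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-20, 20, size=3)


def apply_rigid(structure, R, t):
    """Return a copy of a ChainStructure with x -> R x + t applied to every atom."""
    from decoybench.structure_io import AtomRecord, ChainStructure, Residue

    residues = []
    for res in structure.residues:
        atoms = [
            AtomRecord(a.serial, a.name, a.element, R @ a.coord + t,
                       a.occupancy, a.b_factor, a.alt_loc)
            for a in res.atoms
        ]
        residues.append(Residue(res.id, res.res_name, atoms))
    return ChainStructure(residues, structure.resolution, structure.r_factor,
                          structure.source_id)
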