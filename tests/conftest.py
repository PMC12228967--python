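import numpy as np
import pytest

from ligalign.moltypes import Atom, Bond, Molecule3D
from ligalign.synthetic import ToyWorld, ToyWorldConfig


@pytest.fixture(scope="session")
def world():
    return ToyWorld(ToyWorldConfig(seed=11, n_targets=4))


@pytest.fixture(scope="session")
def aspirin():
    """Aspirin with 2D coordinates, built through RDKit."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    from ligalign._chem import from_rdkit

    m = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
    AllChem.Compute2DCoords(m)
    return from_rdkit(m, name="aspirin")


def random_geom_mol(rng: np.random.Generator, n_atoms: int, with_h: bool = False) -> Molecule3D:
    """Random chain-topology molecule for geometry-only operations.

    Not necessarily chemically sensible; relocation/CoM/decomposition
    geometry contracts do not require chemistry.
    """
    elements = rng.choice(["C", "N", "O", "S"], size=n_atoms).tolist()
    if with_h:
        elements += ["H"] * int(rng.integers(1, 4))
    coords = rng.normal(0.0, 2.0, size=(len(elements), 3))
    atoms = [Atom(e, tuple(map(float, c))) for e, c in zip(elements, coords)]
    bonds = [Bond(i, i + 1, "single") for i in range(n_atoms - 1)]
    if with_h:
        bonds += [Bond(0, n_atoms + k, "single") for k in range(len(elements) - n_atoms)]
    return Molecule3D(atoms=atoms, bonds=bonds, name=f"geom-{n_atoms}").validate()
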