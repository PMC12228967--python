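"""Core chemical data model.

The toolkit moves two in-memory objects between all stages: a small 3D
molecule (:class:`Molecule3D`) and a protein binding pocket
(:class:`ProteinPocket`).  Both are plain dataclasses over NumPy-friendly
Python types; all coordinates are in Angstrom and atom indices are 0-based.

Bond orders use the four explicit categories ``single``, ``double``,
``triple`` and ``aromatic``; the absence of a bond record is the implicit
fifth ("non-bonded") category used by the discrete diffusion process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "BOND_ORDERS",
    "Atom",
    "Bond",
    "Molecule3D",
    "PocketAtom",
    "ProteinPocket",
    "ATOMIC_MASSES",
    "MoleculeError",
]

#: Explicit bond-order vocabulary.  "non-bonded" is represented by the
#: absence of a Bond record, never by an entry in this set.
BOND_ORDERS = ("single", "double", "triple", "aromatic")

# Standard atomic masses (u) for the elements the toolkit touches.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Se": 78.971, "Br": 79.904,
    "I": 126.904,
}


class MoleculeError(ValueError):
    """Raised when a molecule violates the data-model invariants."""


@dataclass(frozen=True)
class Atom:
    element: str
    coords: tuple[float, float, float]
    formal_charge: int = 0


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: str  # one of BOND_ORDERS


@dataclass
class Molecule3D:
    """An element-typed 3D molecule with typed bonds.

    Invariants (checked by :meth:`validate`): finite coordinates, bond
    endpoints are distinct valid atom indices, no duplicate bonds, and bond
    orders drawn from :data:`BOND_ORDERS`.
    """

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(cls, elements, coords, bonds, name="", charges=None):
        charges = charges if charges is not None else [0] * len(elements)
        atoms = [
            Atom(e, (float(c[0]), float(c[1]), float(c[2])), int(q))
            for e, c, q in zip(elements, coords, charges)
        ]
        blist = [Bond(int(i), int(j), str(o)) for i, j, o in bonds]
        mol = cls(atoms=atoms, bonds=blist, name=name)
        mol.validate()
        return mol

    # -- basic accessors ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def coords(self):
        import numpy as np

        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, new_coords) -> "Molecule3D":
        """Copy of the molecule with replaced coordinates (same topology)."""
        atoms = [
            replace(a, coords=(float(c[0]), float(c[1]), float(c[2])))
            for a, c in zip(self.atoms, new_coords)
        ]
        return Molecule3D(atoms=atoms, bonds=list(self.bonds), name=self.name)

    def heavy_indices(self) -> list[int]:
        return [k for k, a in enumerate(self.atoms) if a.element != "H"]

    # -- invariants -----------------------------------------------------------

    def validate(self) -> "Molecule3D":
        for k, a in enumerate(self.atoms):
            if not all(math.isfinite(c) for c in a.coords):
                raise MoleculeError(f"atom {k} has non-finite coordinates")
        seen = set()
        for b in self.bonds:
            if b.order not in BOND_ORDERS:
                raise MoleculeError(f"unknown bond order {b.order!r}")
            if not (0 <= b.i < self.n_atoms and 0 <= b.j < self.n_atoms):
                raise MoleculeError(f"bond ({b.i},{b.j}) endpoint out of range")
            if b.i == b.j:
                raise MoleculeError(f"bond ({b.i},{b.j}) is a self-loop")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise MoleculeError(f"duplicate bond {key}")
            seen.add(key)
        return self


@dataclass(frozen=True)
class PocketAtom:
    element: str
    coords: tuple[float, float, float]
    residue: str  # e.g. "A:GLY:12"
    atom_name: str = ""


@dataclass
class ProteinPocket:
    """Binding-site atoms used as conditioning context.

    Must be non-empty with finite coordinates.
    """

    atoms: list[PocketAtom]
    name: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise MoleculeError("pocket has no atoms")
        for k, a in enumerate(self.atoms):
            if not all(math.isfinite(c) for c in a.coords):
                raise MoleculeError(f"pocket atom {k} has non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self):
        import numpy as np

        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)
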