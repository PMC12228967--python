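"""RDKit bridge: Molecule3D <-> rdkit.Chem.Mol, plus validity checks.

All chemistry that needs valence models, sanitization, QED or SA scoring is
delegated to RDKit through these two conversion functions; the rest of the
package never imports RDKit directly.
"""

from __future__ import annotations

from rdkit import Chem, RDLogger
from rdkit.Geometry import Point3D

from .moltypes import Atom, Bond, Molecule3D, MoleculeError

RDLogger.DisableLog("rdApp.*")

_ORDER_TO_RD = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}
_RD_TO_ORDER = {v: k for k, v in _ORDER_TO_RD.items()}


def to_rdkit(mol: Molecule3D, sanitize: bool = True) -> Chem.Mol:
    """Build an RDKit molecule (with conformer) from a Molecule3D.

    Raises MoleculeError when RDKit cannot sanitize the molecule, which is
    the toolkit-wide definition of "chemically uninterpretable".
    """
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        rw.AddAtom(ra)
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, _ORDER_TO_RD[b.order])
        if b.order == "aromatic":
            rw.GetAtomWithIdx(b.i).SetIsAromatic(True)
            rw.GetAtomWithIdx(b.j).SetIsAromatic(True)
    conf = Chem.Conformer(mol.n_atoms)
    for k, a in enumerate(mol.atoms):
        conf.SetAtomPosition(k, Point3D(*a.coords))
    m = rw.GetMol()
    m.AddConformer(conf)
    if mol.name:
        m.SetProp("_Name", mol.name)
    if sanitize:
        try:
            Chem.SanitizeMol(m)
        except Exception as exc:  # rdkit raises several internal types
            raise MoleculeError(f"molecule {mol.name!r} failed sanitization: {exc}")
    return m


def from_rdkit(m: Chem.Mol, name: str | None = None) -> Molecule3D:
    """Convert an RDKit molecule with a 3D conformer back to Molecule3D."""
    if m.GetNumConformers() == 0:
        raise MoleculeError("RDKit molecule has no conformer")
    conf = m.GetConformer()
    atoms = []
    for a in m.GetAtoms():
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(a.GetSymbol(), (p.x, p.y, p.z), a.GetFormalCharge()))
    bonds = []
    for b in m.GetBonds():
        order = _RD_TO_ORDER.get(b.GetBondType())
        if order is None:
            # fall back on aromatic flag, else treat as single
            order = "aromatic" if b.GetIsAromatic() else "single"
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    if name is None:
        name = m.GetProp("_Name") if m.HasProp("_Name") else ""
    return Molecule3D(atoms=atoms, bonds=bonds, name=name).validate()


def is_valid(mol: Molecule3D) -> bool:
    """Reconstruction-validity check used to exclude failed samples.

    A sample is valid when its heavy-atom graph is connected, it has at
    least two heavy atoms, and RDKit can resolve its valences.
    """
    heavy = mol.heavy_indices()
    if len(heavy) < 2:
        return False
    # connectivity of the heavy-atom graph
    heavy_set = set(heavy)
    adj = {k: set() for k in heavy}
    for b in mol.bonds:
        if b.i in heavy_set and b.j in heavy_set:
            adj[b.i].add(b.j)
            adj[b.j].add(b.i)
    seen = {heavy[0]}
    stack = [heavy[0]]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != len(heavy):
        return False
    try:
        to_rdkit(mol, sanitize=True)
    except MoleculeError:
        return False
    return True
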