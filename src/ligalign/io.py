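"""Readers and writers for the standard formats the toolkit touches.

SDF (V2000/V3000) for ligands and docking poses, and a PDB ATOM/HETATM
subset for protein pockets.  Everything else in the package works on the
in-memory types from :mod:`ligalign.moltypes`.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

from rdkit import Chem

from ._chem import from_rdkit, to_rdkit
from .moltypes import Molecule3D, MoleculeError, PocketAtom, ProteinPocket

log = logging.getLogger(__name__)

__all__ = ["read_sdf", "write_sdf", "read_pocket_pdb", "write_pocket_pdb", "SDFRecordError"]


class SDFRecordError(MoleculeError):
    """A single SDF record could not be parsed; carries the 1-based record index."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"SDF record {record_index}: {message}")


def read_sdf(path, skip_bad: bool = False) -> list[Molecule3D]:
    """Read all records of an SDF file into Molecule3D objects.

    Coordinates and bond orders are preserved; RDKit's aromatic bond type
    maps to the ``aromatic`` category.  Sanitization is NOT applied here so
    that raw generated structures survive the round trip; validity is a
    separate, downstream concern.

    With ``skip_bad=True`` unparsable records are logged and skipped;
    otherwise an :class:`SDFRecordError` naming the record is raised.
    An empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols: list[Molecule3D] = []
    for idx, rd in enumerate(supplier, start=1):
        try:
            if rd is None:
                raise MoleculeError("unparsable record")
            mols.append(from_rdkit(rd))
        except MoleculeError as exc:
            if skip_bad:
                log.warning("skipping SDF record %d of %s: %s", idx, path, exc)
                continue
            raise SDFRecordError(idx, str(exc)) from exc
    return mols


def write_sdf(mols: list[Molecule3D], path) -> None:
    """Write molecules to an SDF file (V2000), one record each, in order."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)  # keep aromatic bond flags as-is
    try:
        for mol in mols:
            mol.validate()
            writer.write(to_rdkit(mol, sanitize=False))
    finally:
        writer.close()


def _infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when the element column is blank."""
    name = atom_name.strip()
    # strip leading digits (e.g. "1HB2")
    core = name.lstrip("0123456789")
    if not core:
        return "X"
    two = core[:2].capitalize()
    if two in ("Cl", "Br", "Se", "Fe", "Zn", "Mg", "Na", "Mn"):
        return two
    return core[0].upper()


def read_pocket_pdb(path, name: str | None = None) -> ProteinPocket:
    """Read ATOM/HETATM records of a PDB file into a ProteinPocket.

    Elements come from the element column when present, otherwise they are
    inferred from the atom name.  Raises MoleculeError when the file
    contains no coordinate records.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(name or path.stem, str(path))
    atoms: list[PocketAtom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                resid = f"{chain.id}:{residue.get_resname()}:{residue.id[1]}"
                for atom in residue:
                    elem = (atom.element or "").strip()
                    if not elem or elem == "X":
                        elem = _infer_element(atom.get_name())
                    x, y, z = atom.coord
                    atoms.append(
                        PocketAtom(elem.capitalize(), (float(x), float(y), float(z)),
                                   resid, atom.get_name())
                    )
        break  # first model only
    if not atoms:
        raise MoleculeError(f"{path}: no ATOM/HETATM records")
    return ProteinPocket(atoms=atoms, name=name or path.stem)


def write_pocket_pdb(pocket: ProteinPocket, path) -> None:
    """Write a pocket as minimal PDB ATOM records (one chain per residue tag)."""
    lines = []
    for i, a in enumerate(pocket.atoms, start=1):
        parts = a.residue.split(":")
        chain = (parts[0] or "A")[0] if parts else "A"
        resname = parts[1][:3] if len(parts) > 1 else "UNK"
        try:
            resseq = int(parts[2]) if len(parts) > 2 else 1
        except ValueError:
            resseq = 1
        atom_name = (a.atom_name or a.element)[:4]
        x, y, z = a.coords
        lines.append(
            f"ATOM  {i:5d} {atom_name:<4s}{resname:>4s} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
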