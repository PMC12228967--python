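"""Data preparation: pose relocation and ligand decomposition.

Generated ligands frequently land far from the target pocket, which breaks
any downstream step that depends on ligand–pocket proximity (arm detection,
sub-pocket extraction).  The fix implemented here is a rigid translation of
the generated ligand so that its center of mass (CoM) coincides with the
CoM of its docking pose, computed after stripping the pose's hydrogens —
docking tools routinely add/remove hydrogens, so only heavy atoms define
the anchor point.

The second half of the module partitions a ligand into peripheral "arms"
(fragments in contact with the pocket) joined by at most one central
"scaffold".  The partition drives the per-fragment Gaussian priors of the
diffusion model.  Contact thresholds (cutoff to the pocket, radius to the
fragment centroid) are relaxed adaptively when a strict setting finds no
arm, and a ligand that never makes contact degrades gracefully to a single
arm with an empty scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .moltypes import ATOMIC_MASSES, Bond, Molecule3D, MoleculeError, ProteinPocket

__all__ = [
    "DecomposedLigand",
    "ExtractionParams",
    "strip_non_heavy",
    "center_of_mass",
    "relocate_to_pose",
    "adaptive_decompose",
]


@dataclass
class DecomposedLigand:
    """Arm/scaffold partition of a ligand's atoms.

    Invariants: at least one arm; at most one scaffold set (may be empty);
    arm sets and scaffold are pairwise disjoint and together cover every
    ligand atom.
    """

    arm_atom_sets: list[set[int]]
    scaffold_atom_set: set[int]
    ligand: Molecule3D

    def __post_init__(self):
        if len(self.arm_atom_sets) < 1:
            raise MoleculeError("decomposition needs at least one arm")
        all_sets = self.arm_atom_sets + [self.scaffold_atom_set]
        union: set[int] = set()
        total = 0
        for s in all_sets:
            union |= s
            total += len(s)
        if total != len(union) or union != set(range(self.ligand.n_atoms)):
            raise MoleculeError("arm/scaffold sets must partition the ligand atoms")

    @property
    def fragments(self) -> list[set[int]]:
        """All fragments, arms first, scaffold last when non-empty."""
        out = list(self.arm_atom_sets)
        if self.scaffold_atom_set:
            out.append(set(self.scaffold_atom_set))
        return out


@dataclass(frozen=True)
class ExtractionParams:
    """Adaptive thresholds for arm detection (all distances in Angstrom)."""

    cutoff: float = 4.0
    radius: float = 6.0
    cutoff_step: float = 0.5
    radius_step: float = 0.5
    max_relaxations: int = 8

    def __post_init__(self):
        if self.cutoff <= 0 or self.radius <= 0:
            raise ValueError("cutoff and radius must be positive")
        if self.cutoff_step <= 0 or self.radius_step <= 0:
            raise ValueError("relaxation steps must be positive")
        if self.max_relaxations < 1:
            raise ValueError("max_relaxations must be >= 1")


def strip_non_heavy(mol: Molecule3D) -> Molecule3D:
    """Remove hydrogens (and their bonds); heavy-atom order is preserved."""
    heavy = mol.heavy_indices()
    if not heavy:
        raise MoleculeError(f"molecule {mol.name!r} has no heavy atoms")
    remap = {old: new for new, old in enumerate(heavy)}
    atoms = [mol.atoms[k] for k in heavy]
    bonds = [
        Bond(remap[b.i], remap[b.j], b.order)
        for b in mol.bonds
        if b.i in remap and b.j in remap
    ]
    return Molecule3D(atoms=atoms, bonds=bonds, name=mol.name).validate()


def center_of_mass(mol: Molecule3D, weighted: bool = True) -> np.ndarray:
    """Mass-weighted mean of the atom coordinates (Angstrom).

    ``weighted=False`` gives the unweighted centroid instead, for pipelines
    that define "CoM" geometrically.
    """
    if mol.n_atoms == 0:
        raise MoleculeError("center of mass of an empty molecule")
    coords = mol.coords()
    if not weighted:
        return coords.mean(axis=0)
    masses = np.array([ATOMIC_MASSES.get(a.element, 12.011) for a in mol.atoms])
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def relocate_to_pose(
    ligand: Molecule3D, pose: Molecule3D, weighted: bool = True
) -> Molecule3D:
    """Rigidly translate ``ligand`` so its CoM matches the pose's heavy-atom CoM.

    The pose is hydrogen-stripped first.  Topology and all internal
    distances are untouched; only a single translation vector is applied.
    """
    clean_pose = strip_non_heavy(pose)
    shift = center_of_mass(clean_pose, weighted) - center_of_mass(ligand, weighted)
    return ligand.with_coords(ligand.coords() + shift)


# --------------------------------------------------------------------------
# arm/scaffold decomposition
# --------------------------------------------------------------------------


def _ring_systems(mol: Molecule3D) -> list[set[int]]:
    """Fused-ring systems as atom-index sets (via RDKit ring perception)."""
    from rdkit import Chem

    from ._chem import to_rdkit

    m = to_rdkit(mol, sanitize=False)
    Chem.FastFindRings(m)
    rings = [set(r) for r in m.GetRingInfo().AtomRings()]
    # merge rings sharing atoms into fused systems
    systems: list[set[int]] = []
    for ring in rings:
        merged = ring
        keep = []
        for s in systems:
            if s & merged:
                merged = merged | s
            else:
                keep.append(s)
        keep.append(merged)
        systems = keep
    return systems


def _components(n: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        comp = {start}
        seen[start] = True
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if not seen[nb]:
                    seen[nb] = True
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps


def _fragment_graph(mol: Molecule3D):
    """Cut the ligand graph into fragments at acyclic single bonds that join
    ring systems, or join a ring system to a chain of >= 2 atoms."""
    systems = _ring_systems(mol)
    in_system = {}
    for si, s in enumerate(systems):
        for a in s:
            in_system[a] = si
    ring_bonds = set()
    for b in mol.bonds:
        si, sj = in_system.get(b.i), in_system.get(b.j)
        if si is not None and si == sj:
            ring_bonds.add((min(b.i, b.j), max(b.i, b.j)))

    all_edges = [(b.i, b.j) for b in mol.bonds]

    def branch_size(drop: tuple[int, int], side: int) -> int:
        edges = [e for e in all_edges if tuple(sorted(e)) != drop]
        for comp in _components(mol.n_atoms, edges):
            if side in comp:
                return len(comp)
        return 1

    cut = []
    for b in mol.bonds:
        key = (min(b.i, b.j), max(b.i, b.j))
        if b.order != "single" or key in ring_bonds:
            continue
        si, sj = in_system.get(b.i), in_system.get(b.j)
        if si is not None and sj is not None and si != sj:
            cut.append(key)  # direct ring-ring junction
        elif si is not None and sj is None:
            if branch_size(key, b.j) >= 2:
                cut.append(key)
        elif sj is not None and si is None:
            if branch_size(key, b.i) >= 2:
                cut.append(key)

    cut_set = set(cut)
    kept = [e for e in all_edges if tuple(sorted(e)) not in cut_set]
    fragments = _components(mol.n_atoms, kept)

    # adjacency between fragments through the cut bonds
    frag_of = {}
    for fi, frag in enumerate(fragments):
        for a in frag:
            frag_of[a] = fi
    degree = [0] * len(fragments)
    for i, j in cut_set:
        degree[frag_of[i]] += 1
        degree[frag_of[j]] += 1
    return fragments, degree


def adaptive_decompose(
    ligand: Molecule3D, pocket: ProteinPocket, params: ExtractionParams | None = None
) -> DecomposedLigand:
    """Partition a (pocket-proximal) ligand into arms and at most one scaffold.

    Fragments linking two or more other fragments are scaffold material; the
    remaining peripheral fragments become arms when they touch the pocket —
    i.e. some atom lies within ``cutoff`` of a pocket atom and within
    ``radius`` of the fragment's own centroid.  If no arm qualifies, both
    thresholds are relaxed by their step sizes up to ``max_relaxations``
    times; if contact is never found the entire ligand becomes one arm.
    """
    params = params or ExtractionParams()
    ligand.validate()
    fragments, degree = _fragment_graph(ligand)
    coords = ligand.coords()
    pocket_xyz = pocket.coords()

    candidates = [fi for fi in range(len(fragments)) if degree[fi] < 2]
    connectors = [fi for fi in range(len(fragments)) if degree[fi] >= 2]

    def contact(frag: set[int], cutoff: float, radius: float) -> bool:
        idx = sorted(frag)
        xyz = coords[idx]
        centroid = xyz.mean(axis=0)
        d_pocket = np.linalg.norm(xyz[:, None, :] - pocket_xyz[None, :, :], axis=-1).min(axis=1)
        d_centroid = np.linalg.norm(xyz - centroid, axis=-1)
        return bool(np.any((d_pocket <= cutoff) & (d_centroid <= radius)))

    arms: list[int] = []
    for attempt in range(params.max_relaxations + 1):
        cutoff = params.cutoff + attempt * params.cutoff_step
        radius = params.radius + attempt * params.radius_step
        arms = [fi for fi in candidates if contact(fragments[fi], cutoff, radius)]
        if arms:
            break

    if not arms:
        # relaxation exhausted: whole ligand is a single arm, no scaffold
        return DecomposedLigand(
            arm_atom_sets=[set(range(ligand.n_atoms))],
            scaffold_atom_set=set(),
            ligand=ligand,
        )

    arm_sets = [set(fragments[fi]) for fi in arms]
    scaffold: set[int] = set()
    for fi in connectors + [fi for fi in candidates if fi not in arms]:
        scaffold |= fragments[fi]
    return DecomposedLigand(arm_atom_sets=arm_sets, scaffold_atom_set=scaffold, ligand=ligand)
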