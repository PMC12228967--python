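"""Toy world: deterministic fixtures and a geometric docking surrogate.

This module fabricates everything the alignment framework needs to run end
to end without external datasets, trained checkpoints, or a docking
installation:

* concave shell "pockets" of pseudo-atoms on a spherical cap,
* small valence-valid ligands assembled from a fragment grammar (rings,
  chain linkers, terminal substituents) with idealized geometry,
* a smooth, deterministic contact potential standing in for a docking
  scorer (lower = better; attractive well near 3.5 Angstrom, steep clash
  penalty inside 2.5 Angstrom),
* a stochastic perturbation sampler that produces K jittered/edited
  variants of a base ligand, with an optional planted fraction of corrupted
  (disconnected) samples to exercise validity filtering.

Every operation is fully deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .moltypes import Atom, Bond, Molecule3D, PocketAtom, ProteinPocket
from .pose_prep import DecomposedLigand, center_of_mass

__all__ = [
    "ToyWorldConfig",
    "ToyWorld",
    "make_toy_pocket",
    "make_toy_ligand",
    "cavity_center",
    "surrogate_dock_score",
    "SurrogateDockingScorer",
    "perturbation_sampler",
]

# Surrogate-potential constants.  DOCK_SCALE is the calibration constant
# that maps raw contact sums onto a docking-score-like scale where a seated
# toy ligand lands roughly in [-11, -5]: the -8.18 success threshold is
# reachable for well-packed ligands but not trivially met.
CLASH_DISTANCE = 2.5
WELL_CENTER = 3.5
WELL_WIDTH = 0.7
CLASH_SLOPE = 2.0
DOCK_SCALE = 0.08


@dataclass(frozen=True)
class ToyWorldConfig:
    seed: int = 0
    n_targets: int = 8
    pocket_radius: float = 5.0
    pocket_atoms: int = 48
    ligand_size_range: tuple[int, int] = (6, 16)
    fragment_grammar: tuple[str, ...] = ("benzene", "cyclohexane", "cyclopentane")
    jitter: float = 0.05  # Angstrom, coordinate noise on idealized geometry

    def __post_init__(self):
        if self.ligand_size_range[0] < 2:
            raise ValueError("ligand size range must allow >= 2 atoms")
        if self.pocket_radius <= 0:
            raise ValueError("pocket radius must be positive")


def _rng(config: ToyWorldConfig, index: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, index, salt])
    )


# --------------------------------------------------------------------------
# pockets
# --------------------------------------------------------------------------


def make_toy_pocket(config: ToyWorldConfig, index: int) -> ProteinPocket:
    """Concave shell of pseudo-atoms with an opening toward +z.

    Atoms sit on a spherical cap of radius ~pocket_radius around the cavity
    center (the origin of the pocket frame); everything stays within
    pocket_radius + 1 Angstrom of the cavity center.
    """
    rng = _rng(config, index, 1)
    elements = rng.choice(["C", "N", "O"], size=config.pocket_atoms, p=[0.7, 0.15, 0.15])
    atoms = []
    n = 0
    while n < config.pocket_atoms:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        if u[2] > 0.574:  # leave the cavity mouth open
            continue
        r = config.pocket_radius + rng.uniform(-0.5, 0.3)
        pos = r * u
        atoms.append(
            PocketAtom(str(elements[n]), (pos[0], pos[1], pos[2]),
                       f"A:ALA:{n + 1}", f"{elements[n]}{n + 1}")
        )
        n += 1
    return ProteinPocket(atoms=atoms, name=f"toy-pocket-{index}")


def cavity_center(pocket: ProteinPocket) -> np.ndarray:
    """Estimate of the cavity center: the centroid of the shell atoms."""
    return pocket.coords().mean(axis=0)


# --------------------------------------------------------------------------
# ligands
# --------------------------------------------------------------------------

_RING_SPECS = {
    "benzene": (6, "aromatic", 1.40),
    "cyclohexane": (6, "single", 1.54),
    "cyclopentane": (5, "single", 1.54),
}


def _ring(kind: str, offset: int):
    n, order, blen = _RING_SPECS[kind]
    radius = blen / (2.0 * math.sin(math.pi / n))
    coords = [
        (radius * math.cos(2 * math.pi * k / n), radius * math.sin(2 * math.pi * k / n), 0.0)
        for k in range(n)
    ]
    atoms = [Atom("C", c) for c in coords]
    bonds = [Bond(offset + k, offset + (k + 1) % n, order) for k in range(n)]
    return atoms, bonds, radius


def make_toy_ligand(
    config: ToyWorldConfig,
    index: int,
    planted_partition: bool = False,
) -> tuple[Molecule3D, DecomposedLigand | None]:
    """Assemble a valence-valid toy ligand from the fragment grammar.

    With ``planted_partition=True`` the ligand is a "dumbbell" (two rings
    joined by a 3-atom chain) and the ground-truth 2-arm/1-scaffold
    partition is returned for decomposition tests.
    """
    rng = _rng(config, index, 2)
    grammar = list(config.fragment_grammar)
    template = "dumbbell" if planted_partition else rng.choice(["ring", "dumbbell", "ring_tail"])

    atoms: list[Atom] = []
    bonds: list[Bond] = []
    groups: dict[str, set[int]] = {"arm1": set(), "arm2": set(), "scaffold": set()}

    kind1 = str(rng.choice(grammar))
    ring1_atoms, ring1_bonds, r1 = _ring(kind1, 0)
    atoms.extend(ring1_atoms)
    bonds.extend(ring1_bonds)
    groups["arm1"] = set(range(len(ring1_atoms)))

    if template == "dumbbell":
        # 3-atom chain linker then a second ring, along +x
        attach1 = 0  # ring-1 atom at (r1, 0, 0)
        link_start = len(atoms)
        for k in range(3):
            x = r1 + 1.5 * (k + 1)
            atoms.append(Atom("C", (x, 0.5 * ((-1) ** k), 0.0)))
        bonds.append(Bond(attach1, link_start, "single"))
        bonds.append(Bond(link_start, link_start + 1, "single"))
        bonds.append(Bond(link_start + 1, link_start + 2, "single"))
        groups["scaffold"] = {link_start, link_start + 1, link_start + 2}

        kind2 = str(rng.choice(grammar))
        ring2_start = len(atoms)
        ring2_atoms, ring2_bonds, r2 = _ring(kind2, ring2_start)
        cx = r1 + 1.5 * 4 + r2
        ring2_atoms = [
            Atom(a.element, (-a.coords[0] + cx, a.coords[1], a.coords[2]))
            for a in ring2_atoms
        ]
        atoms.extend(ring2_atoms)
        bonds.extend(ring2_bonds)
        bonds.append(Bond(link_start + 2, ring2_start, "single"))
        groups["arm2"] = set(range(ring2_start, len(atoms)))
    elif template == "ring_tail":
        attach1 = 0
        prev = attach1
        for k in range(int(rng.integers(2, 4))):
            x = r1 + 1.5 * (k + 1)
            idx = len(atoms)
            atoms.append(Atom("C", (x, 0.5 * ((-1) ** k), 0.0)))
            bonds.append(Bond(prev, idx, "single"))
            prev = idx
            groups["arm1"].add(idx)

    # terminal substituents on ring-1 atoms (never on the +x attachment atom)
    n_subs = int(rng.integers(0, 3))
    ring1_size = len(ring1_atoms)
    free = [k for k in range(1, ring1_size)]
    rng.shuffle(free)
    for k in free[:n_subs]:
        host = atoms[k]
        direction = np.array(host.coords)
        norm = np.linalg.norm(direction[:2])
        if norm < 1e-9:
            continue
        pos = direction + 1.40 * direction / np.linalg.norm(direction)
        elem = str(rng.choice(["O", "N", "F", "C"]))
        idx = len(atoms)
        atoms.append(Atom(elem, (pos[0], pos[1], pos[2])))
        bonds.append(Bond(k, idx, "single"))
        groups["arm1"].add(idx)

    coords = np.array([a.coords for a in atoms])
    coords = coords - coords.mean(axis=0)
    coords = coords + rng.normal(0.0, config.jitter, size=coords.shape)
    mol = Molecule3D(
        atoms=[Atom(a.element, tuple(map(float, c)), a.formal_charge)
               for a, c in zip(atoms, coords)],
        bonds=bonds,
        name=f"toy-ligand-{index}",
    ).validate()

    partition = None
    if planted_partition:
        partition = DecomposedLigand(
            arm_atom_sets=[set(groups["arm1"]), set(groups["arm2"])],
            scaffold_atom_set=set(groups["scaffold"]),
            ligand=mol,
        )
    return mol, partition


# --------------------------------------------------------------------------
# surrogate docking
# --------------------------------------------------------------------------


def surrogate_dock_score(ligand: Molecule3D, pocket: ProteinPocket) -> float:
    """Deterministic smooth contact score (lower = better).

    Sum over ligand-pocket heavy-atom pairs of a Gaussian attractive well
    centered at 3.5 Angstrom plus a linear clash penalty below 2.5
    Angstrom, scaled by the calibration constant DOCK_SCALE.  Invariant
    under joint rigid motion of ligand and pocket; sensitive to moving the
    ligand alone.
    """
    lig = ligand.coords()[ligand.heavy_indices()]
    poc = pocket.coords()
    d = np.linalg.norm(lig[:, None, :] - poc[None, :, :], axis=-1)
    well = -np.exp(-((d - WELL_CENTER) ** 2) / (2.0 * WELL_WIDTH**2))
    clash = CLASH_SLOPE * np.clip(CLASH_DISTANCE - d, 0.0, None)
    return float(DOCK_SCALE * (well + clash).sum())


class SurrogateDockingScorer:
    """Docking-scorer contract built on the geometric surrogate.

    "Docking" a ligand places its center of mass at the pocket's cavity
    center (a deterministic pose); the returned score is the surrogate
    contact score of that pose.
    """

    def __call__(self, ligand: Molecule3D, pocket: ProteinPocket):
        shift = cavity_center(pocket) - center_of_mass(ligand)
        pose = ligand.with_coords(ligand.coords() + shift)
        pose.name = f"{ligand.name}|docked"
        return surrogate_dock_score(pose, pocket), pose


# --------------------------------------------------------------------------
# perturbation sampler
# --------------------------------------------------------------------------


def perturbation_sampler(
    base: Molecule3D,
    pocket: ProteinPocket,
    count: int,
    seed: int,
    temperature: float = 1.0,
    corruption_fraction: float = 0.0,
) -> list[Molecule3D]:
    """Generate ``count`` variants of ``base`` by seeded coordinate jitter
    (scale proportional to temperature) and occasional terminal-substituent
    element swaps.  ``corruption_fraction`` of the samples (rounded) are
    deliberately disconnected so validity filtering has something to catch.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 97]))
    n_corrupt = int(round(corruption_fraction * count))
    corrupt_idx = set(rng.choice(count, size=n_corrupt, replace=False).tolist()) if n_corrupt else set()

    degree = [0] * base.n_atoms
    for b in base.bonds:
        degree[b.i] += 1
        degree[b.j] += 1
    terminals = [k for k in range(base.n_atoms)
                 if degree[k] == 1 and base.atoms[k].element in ("C", "N", "O", "F")]

    out = []
    for k in range(count):
        coords = base.coords()
        if temperature > 0:
            coords = coords + rng.normal(0.0, 0.15 * temperature, size=coords.shape)
        atoms = [Atom(a.element, tuple(map(float, c)), a.formal_charge)
                 for a, c in zip(base.atoms, coords)]
        if terminals and temperature > 0 and rng.random() < 0.5 * min(1.0, temperature):
            t_idx = int(rng.choice(terminals))
            atoms[t_idx] = Atom(str(rng.choice(["C", "N", "O", "F"])),
                                atoms[t_idx].coords, atoms[t_idx].formal_charge)
        bonds = list(base.bonds)
        if k in corrupt_idx:
            # a far-away stray atom disconnects the heavy-atom graph
            atoms.append(Atom("C", (40.0, 40.0, 40.0)))
        out.append(Molecule3D(atoms=atoms, bonds=bonds, name=f"{base.name}-v{k}").validate())
    return out


# --------------------------------------------------------------------------
# world container
# --------------------------------------------------------------------------


@dataclass
class ToyWorld:
    """A bundle of targets: pockets, seated base ligands, and generators."""

    config: ToyWorldConfig = field(default_factory=ToyWorldConfig)

    def target_ids(self) -> list[str]:
        return [f"target-{i}" for i in range(self.config.n_targets)]

    def pocket(self, i: int) -> ProteinPocket:
        return make_toy_pocket(self.config, i)

    def base_ligand(self, i: int, seated: bool = True) -> Molecule3D:
        mol, _ = make_toy_ligand(self.config, i)
        if seated:
            pocket = self.pocket(i)
            shift = cavity_center(pocket) - center_of_mass(mol)
            mol = mol.with_coords(mol.coords() + shift)
        return mol

    def targets(self) -> list[tuple[str, ProteinPocket]]:
        return [(tid, self.pocket(i)) for i, tid in enumerate(self.target_ids())]

    def make_generator(self, corruption_fraction: float = 0.0):
        """A candidate-generator closure over the world's base ligands.

        Conforms to the generator contract: (pocket, count, seed,
        temperature) -> list of Molecule3D.
        """
        bases = {f"toy-pocket-{i}": self.base_ligand(i) for i in range(self.config.n_targets)}

        def generate(pocket: ProteinPocket, count: int, seed: int, temperature: float = 1.0):
            base = bases.get(pocket.name)
            if base is None:
                raise KeyError(f"unknown toy pocket {pocket.name!r}")
            return perturbation_sampler(
                base, pocket, count, seed, temperature, corruption_fraction
            )

        return generate
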