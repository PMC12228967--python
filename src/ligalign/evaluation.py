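"""Evaluation metrics for generated molecule sets.

Covers: per-metric means/medians and the success rate (QED > 0.25,
SA > 0.59, Vina < -8.18, all strict), the "accumulated" three-metric
summary in which the docking mean is mapped into [0, 1] by dividing by
-10, and the Jensen–Shannon divergence between binned bond-length
distributions of a generated set and a reference set (base-2 logs, so the
value lives in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon

from .moltypes import Molecule3D
from .reward import success_flag

__all__ = [
    "MetricSummary",
    "JSDBins",
    "accumulated_score",
    "summarize",
    "bond_lengths",
    "bond_distance_jsd",
    "jsd_table",
    "UndefinedMetricError",
    "DEFAULT_BOND_QUERIES",
]


class UndefinedMetricError(ValueError):
    """A divergence was requested for a bond type absent from one side."""


@dataclass(frozen=True)
class JSDBins:
    """Fixed histogram binning for bond lengths (Angstrom).

    Out-of-range lengths are clipped into the edge bins.
    """

    lo: float = 0.8
    hi: float = 3.0
    width: float = 0.02

    def edges(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.width))
        return self.lo + self.width * np.arange(n + 1)


#: bond-type queries covering the common organic bonds; ':' is aromatic.
DEFAULT_BOND_QUERIES = (
    ("C", "C", "single"),
    ("C", "C", "double"),
    ("C", "N", "single"),
    ("C", "N", "double"),
    ("C", "O", "single"),
    ("C", "O", "double"),
    ("C", "C", "aromatic"),
    ("C", "N", "aromatic"),
)


def accumulated_score(qed_mean: float, sa_mean: float, vina_mean: float) -> float:
    """QED + SA + Vina/(-10): equal-weight summary with the docking mean
    normalized into [0, 1] by dividing by -10.  Returned unrounded; round
    to 3 decimals at presentation."""
    return float(qed_mean) + float(sa_mean) + float(vina_mean) / (-10.0)


@dataclass
class MetricSummary:
    means: dict[str, float]
    medians: dict[str, float]
    success_rate: float
    n_molecules: int

    def accumulated(self, which: str = "mean") -> float:
        src = self.means if which == "mean" else self.medians
        return accumulated_score(src["qed"], src["sa_norm"], src["vina"])


def summarize(records: list[tuple[float, float, float]]) -> MetricSummary:
    """Means, medians and success rate over (qed, sa_norm, vina) records.

    The success-rate denominator is every record passed in, i.e. every
    molecule that survived validity filtering.
    """
    if not records:
        raise ValueError("cannot summarize an empty record list")
    arr = np.asarray(records, dtype=float)
    names = ("qed", "sa_norm", "vina")
    means = {n: float(arr[:, k].mean()) for k, n in enumerate(names)}
    medians = {n: float(np.median(arr[:, k])) for k, n in enumerate(names)}
    flags = [success_flag(q, s, v) for q, s, v in arr]
    return MetricSummary(
        means=means,
        medians=medians,
        success_rate=float(np.mean(flags)),
        n_molecules=len(records),
    )


def bond_lengths(
    mols: list[Molecule3D], bond_query: tuple[str, str, str]
) -> np.ndarray:
    """Euclidean lengths of every bond matching (element, element, order).

    The element pair is unordered: (C, N, single) matches N-C bonds too.
    """
    e1, e2, order = bond_query
    want = frozenset((e1, e2)) if e1 != e2 else frozenset((e1,))
    out = []
    for mol in mols:
        coords = mol.coords()
        for b in mol.bonds:
            if b.order != order:
                continue
            pair = frozenset((mol.atoms[b.i].element, mol.atoms[b.j].element))
            if pair == want:
                out.append(float(np.linalg.norm(coords[b.i] - coords[b.j])))
    return np.asarray(out, dtype=float)


def _hist(lengths: np.ndarray, bins: JSDBins) -> np.ndarray:
    edges = bins.edges()
    clipped = np.clip(lengths, bins.lo, bins.hi)
    counts, _ = np.histogram(clipped, bins=edges)
    return counts / counts.sum()


def bond_distance_jsd(
    generated: list[Molecule3D],
    reference: list[Molecule3D],
    bond_query: tuple[str, str, str],
    bins: JSDBins = JSDBins(),
) -> float:
    """Jensen–Shannon divergence (base 2, in [0, 1]) between the binned
    bond-length distributions of the two sets for one bond type."""
    if not generated or not reference:
        raise ValueError("both molecule lists must be non-empty")
    lg = bond_lengths(generated, bond_query)
    lr = bond_lengths(reference, bond_query)
    if lg.size == 0:
        raise UndefinedMetricError(f"no {bond_query} bonds in the generated set")
    if lr.size == 0:
        raise UndefinedMetricError(f"no {bond_query} bonds in the reference set")
    p = _hist(lg, bins)
    q = _hist(lr, bins)
    # jensenshannon returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(p, q, base=2) ** 2)


def jsd_table(
    generated: list[Molecule3D],
    reference: list[Molecule3D],
    queries=DEFAULT_BOND_QUERIES,
    bins: JSDBins = JSDBins(),
) -> dict[str, float]:
    """Per-bond-type JSD for every query present in both sets.

    Keys use the compact field notation: '-' single, '=' double,
    '#' triple, ':' aromatic (e.g. 'C-C', 'C:N').
    """
    symbol = {"single": "-", "double": "=", "triple": "#", "aromatic": ":"}
    out = {}
    for e1, e2, order in queries:
        try:
            out[f"{e1}{symbol[order]}{e2}"] = bond_distance_jsd(
                generated, reference, (e1, e2, order), bins
            )
        except UndefinedMetricError:
            continue
    return out
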