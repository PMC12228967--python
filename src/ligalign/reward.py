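"""Multi-objective reward for ranking generated ligands.

Three objectives enter the reward: drug-likeness (QED, natively in [0,1]),
synthetic accessibility (raw 1–10 scale mapped to [0,1], higher = easier to
make), and a docking score (lower = better binding) min–max normalized and
inverted across the K candidates generated for the same target so that the
best binder of a cohort gets 1.0.  The reward is the weighted sum

    r = w_qed * QED + w_sa * SA_norm + w_dock * dock_norm

with non-negative, user-tunable weights.
"""

from __future__ import annotations

import math
import os
import sys
from dataclasses import dataclass

from .moltypes import Molecule3D

__all__ = [
    "RewardWeights",
    "RewardVector",
    "compute_qed",
    "compute_sa_norm",
    "normalize_dock_scores",
    "score_candidate",
    "success_flag",
    "SUCCESS_QED",
    "SUCCESS_SA",
    "SUCCESS_VINA",
]

# Success-rate thresholds (strict inequalities): QED > 0.25, SA_norm > 0.59,
# docking score < -8.18 kcal/mol.
SUCCESS_QED = 0.25
SUCCESS_SA = 0.59
SUCCESS_VINA = -8.18


@dataclass(frozen=True)
class RewardWeights:
    w_qed: float = 1.0
    w_sa: float = 0.0
    w_dock: float = 0.0

    def __post_init__(self):
        if min(self.w_qed, self.w_sa, self.w_dock) < 0:
            raise ValueError("reward weights must be non-negative")
        if self.w_qed == self.w_sa == self.w_dock == 0:
            raise ValueError("at least one reward weight must be positive")


@dataclass(frozen=True)
class RewardVector:
    qed: float
    sa_norm: float
    dock_raw: float
    dock_norm: float
    reward: float


def _sascorer():
    # RDKit ships the synthetic-accessibility scorer in its contrib tree.
    from rdkit.Chem import RDConfig

    contrib = os.path.join(RDConfig.RDContribDir, "SA_Score")
    if contrib not in sys.path:
        sys.path.append(contrib)
    import sascorer

    return sascorer


def compute_qed(mol: Molecule3D) -> float:
    """Quantitative estimate of drug-likeness, already in [0,1]."""
    from rdkit.Chem import QED

    from ._chem import to_rdkit

    return float(QED.qed(to_rdkit(mol)))


def compute_sa_norm(mol: Molecule3D) -> float:
    """Synthetic accessibility mapped to [0,1], higher = more synthesizable.

    The raw score s lives on a 1 (easy) .. 10 (hard) scale; the normalized
    value is (10 - s) / 9.
    """
    from ._chem import to_rdkit

    raw = float(_sascorer().calculateScore(to_rdkit(mol)))
    return sa_raw_to_norm(raw)


def sa_raw_to_norm(raw: float) -> float:
    return (10.0 - raw) / 9.0


def normalize_dock_scores(scores: list[float]) -> list[float]:
    """Min–max normalize and invert a cohort of docking scores.

    Scores are lower-is-better; each s maps to (max - s) / (max - min) so
    the most negative score of the cohort gets 1.0 and the worst gets 0.0.
    A degenerate cohort (all equal) maps every entry to 0.5 so the cohort
    stays rankable by the other objectives.
    """
    if not scores:
        raise ValueError("empty docking-score cohort")
    if any(not math.isfinite(s) for s in scores):
        raise ValueError("non-finite docking score in cohort")
    lo, hi = min(scores), max(scores)
    if hi == lo:
        return [0.5] * len(scores)
    return [(hi - s) / (hi - lo) for s in scores]


def score_candidate(
    mol: Molecule3D, dock_raw: float, dock_norm: float, weights: RewardWeights
) -> RewardVector:
    """Assemble the full reward vector for one candidate.

    ``dock_norm`` must come from :func:`normalize_dock_scores` over the
    candidate's own target cohort.  Propagates the invalid-molecule error
    when QED/SA cannot be computed; the caller excludes such candidates.
    """
    qed = compute_qed(mol)
    sa = compute_sa_norm(mol)
    reward = weights.w_qed * qed + weights.w_sa * sa + weights.w_dock * dock_norm
    return RewardVector(qed=qed, sa_norm=sa, dock_raw=dock_raw,
                        dock_norm=dock_norm, reward=reward)


def success_flag(qed: float, sa_norm: float, vina: float) -> bool:
    """Drug-design readiness: QED > 0.25 and SA > 0.59 and Vina < -8.18.

    All three inequalities are strict; values exactly on a threshold fail.
    """
    for v in (qed, sa_norm, vina):
        if not math.isfinite(v):
            raise ValueError("success_flag requires finite inputs")
    return qed > SUCCESS_QED and sa_norm > SUCCESS_SA and vina < SUCCESS_VINA


class ExternalDockingScorer:
    """Adapter that shells out to a user-supplied docking executable.

    The command is a template with ``{ligand}``, ``{pocket}`` and ``{out}``
    placeholders; the executable must print the affinity (kcal/mol, lower =
    better) as the last whitespace-separated token of its final stdout line.
    Intended for real docking backends; the test suite uses the geometric
    surrogate from :mod:`ligalign.synthetic` instead.
    """

    def __init__(self, command_template: str):
        self.command_template = command_template

    def __call__(self, ligand: Molecule3D, pocket):
        import subprocess
        import tempfile

        from .io import write_pocket_pdb, write_sdf

        with tempfile.TemporaryDirectory() as tmp:
            lig_path = os.path.join(tmp, "ligand.sdf")
            poc_path = os.path.join(tmp, "pocket.pdb")
            out_path = os.path.join(tmp, "out.sdf")
            write_sdf([ligand], lig_path)
            write_pocket_pdb(pocket, poc_path)
            cmd = self.command_template.format(
                ligand=lig_path, pocket=poc_path, out=out_path
            )
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(f"docking command failed: {proc.stderr[-500:]}")
            last = proc.stdout.strip().splitlines()[-1]
            score = float(last.split()[-1])
            pose = None
            if os.path.exists(out_path):
                from .io import read_sdf

                poses = read_sdf(out_path, skip_bad=True)
                pose = poses[0] if poses else None
        return score, pose
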