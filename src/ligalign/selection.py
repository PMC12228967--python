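"""Best-of-K curation and Best-of-N selection.

Best-of-K (one alignment iteration): for each target pocket, draw K
candidates from the generator, drop samples that fail reconstruction
validity, rank the survivors with the multi-objective reward (docking
scores min–max normalized within the cohort), keep the argmax, relocate it
onto its docking pose, decompose it into arms/scaffold and attach the
fragment priors.  The curated records feed the fine-tuning loop.

Best-of-N: same generate-and-rank step, but the winner is simply returned;
no model state is touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._chem import is_valid
from .diffusion import DecompPriors, estimate_priors
from .moltypes import Molecule3D, ProteinPocket
from .pose_prep import DecomposedLigand, ExtractionParams, adaptive_decompose, relocate_to_pose
from .reward import RewardVector, RewardWeights, normalize_dock_scores, score_candidate

log = logging.getLogger(__name__)

__all__ = [
    "Candidate",
    "CandidateSet",
    "SamplerConfig",
    "CurationRecord",
    "CurationBatch",
    "NoValidSampleError",
    "filter_valid",
    "best_of_k",
    "best_of_n",
    "build_curation_batch",
]


class NoValidSampleError(RuntimeError):
    """All candidates of a target were invalid (or there were none)."""


@dataclass
class Candidate:
    mol: Molecule3D
    pose: Molecule3D | None
    reward: RewardVector


@dataclass
class CandidateSet:
    """The scored K-sample cohort of one target."""

    target_id: str
    pocket: ProteinPocket
    candidates: list[Candidate]
    K_requested: int

    def __post_init__(self):
        if len(self.candidates) > self.K_requested:
            raise ValueError("more candidates than requested K")


@dataclass(frozen=True)
class SamplerConfig:
    K: int = 10
    N: int = 10
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.K < 1 or self.N < 1:
            raise ValueError("K and N must be >= 1")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class CurationRecord:
    target_id: str
    ligand: Molecule3D  # best-of-K winner after CoM relocation
    pocket: ProteinPocket
    decomposed: DecomposedLigand
    priors: DecompPriors
    reward: RewardVector


@dataclass
class CurationBatch:
    """Subset B of curated (target, winner) records for fine-tuning."""

    records: list[CurationRecord]
    batch_size_B: int
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (target_id, reason)

    @property
    def subset_size_b(self) -> int:
        return len(self.records)

    def __post_init__(self):
        if len(self.records) > self.batch_size_B:
            raise ValueError("curated subset larger than batch size B")


def filter_valid(samples: list[Molecule3D]) -> list[Molecule3D]:
    """Drop samples that fail molecular reconstruction (disconnected
    heavy-atom graph, unresolvable valences, < 2 heavy atoms); order kept."""
    return [m for m in samples if is_valid(m)]


def _score_cohort(
    target_id: str,
    pocket: ProteinPocket,
    samples: list[Molecule3D],
    scorer,
    weights: RewardWeights,
    k_requested: int,
) -> CandidateSet:
    docked = [scorer(m, pocket) for m in samples]
    dock_norm = normalize_dock_scores([d[0] for d in docked])
    candidates = [
        Candidate(mol=m, pose=pose, reward=score_candidate(m, raw, dn, weights))
        for m, (raw, pose), dn in zip(samples, docked, dock_norm)
    ]
    return CandidateSet(target_id=target_id, pocket=pocket,
                        candidates=candidates, K_requested=k_requested)


def best_of_k(cset: CandidateSet) -> tuple[int, Molecule3D]:
    """Reward-argmax over the cohort; ties broken by lowest index."""
    if not cset.candidates:
        raise NoValidSampleError(f"target {cset.target_id}: no valid candidates")
    best = 0
    for k, cand in enumerate(cset.candidates):
        if cand.reward.reward > cset.candidates[best].reward.reward:
            best = k
    return best, cset.candidates[best].mol


def best_of_n(
    generator,
    pocket: ProteinPocket,
    scorer,
    weights: RewardWeights,
    config: SamplerConfig,
    target_id: str = "",
) -> tuple[Molecule3D, RewardVector]:
    """Draw N samples, score the valid ones, return the reward-argmax.

    Docking normalization is min–max over the valid draws of this target.
    No generator or model state is modified.
    """
    samples = generator(pocket, config.N, config.seed, config.temperature)
    valid = filter_valid(samples)
    if not valid:
        raise NoValidSampleError(f"target {target_id or pocket.name}: 0/{config.N} valid samples")
    cset = _score_cohort(target_id or pocket.name, pocket, valid, scorer, weights, config.N)
    idx, mol = best_of_k(cset)
    return mol, cset.candidates[idx].reward


def build_curation_batch(
    targets: list[tuple[str, ProteinPocket]],
    generator,
    scorer,
    weights: RewardWeights,
    config: SamplerConfig,
    extraction: ExtractionParams | None = None,
    batch_size_B: int | None = None,
) -> CurationBatch:
    """One data-collection + ranking + preparation pass over the targets.

    Per target: generate K, drop invalid samples, score and rank, relocate
    the winner onto its docking pose, decompose against the pocket and
    attach fragment priors.  Targets with zero valid candidates are skipped
    (and logged), never aborting the batch.
    """
    extraction = extraction or ExtractionParams()
    records: list[CurationRecord] = []
    skipped: list[tuple[str, str]] = []
    for i, (target_id, pocket) in enumerate(targets):
        seed_i = (config.seed * 1009 + i * 9176) % (2**31 - 1)
        try:
            samples = generator(pocket, config.K, seed_i, config.temperature)
            valid = filter_valid(samples)
            if not valid:
                raise NoValidSampleError(f"0/{len(samples)} samples valid")
            cset = _score_cohort(target_id, pocket, valid, scorer, weights, config.K)
            idx, winner = best_of_k(cset)
            pose = cset.candidates[idx].pose
            relocated = relocate_to_pose(winner, pose) if pose is not None else winner
            decomposed = adaptive_decompose(relocated, pocket, extraction)
            priors = estimate_priors(decomposed)
            records.append(
                CurationRecord(
                    target_id=target_id,
                    ligand=relocated,
                    pocket=pocket,
                    decomposed=decomposed,
                    priors=priors,
                    reward=cset.candidates[idx].reward,
                )
            )
        except Exception as exc:  # per-target isolation: skip, never abort
            log.warning("skipping target %s: %s", target_id, exc)
            skipped.append((target_id, str(exc)))
    return CurationBatch(
        records=records,
        batch_size_B=batch_size_B if batch_size_B is not None else len(targets),
        skipped=skipped,
    )
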