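"""End-to-end orchestration: pre-training, Best-of-K iterations, and the
desk-scale alignment and Best-of-N experiments.

These functions glue the modules together the way a full run does:
generate -> filter -> rank -> relocate -> decompose -> fine-tune ->
re-sample, entirely on the synthetic toy world, with a single run-level
seed fanned out deterministically to every stochastic stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._chem import is_valid
from .diffusion import (
    LossWeights,
    NoiseSchedule,
    NumpyDenoiser,
    estimate_priors,
    finetune,
    isotropic_priors,
    sample_ligand,
)
from .moltypes import ProteinPocket
from .pose_prep import ExtractionParams, adaptive_decompose
from .reward import RewardWeights, compute_qed
from .selection import (
    CurationBatch,
    CurationRecord,
    RewardVector,
    SamplerConfig,
    best_of_n,
    build_curation_batch,
)
from .synthetic import SurrogateDockingScorer, ToyWorld, ToyWorldConfig

__all__ = [
    "make_diffusion_generator",
    "pretraining_batch",
    "alignment_experiment",
    "bon_sweep",
    "AlignmentResult",
]

GEN_SIGMA = 0.8  # Angstrom: isotropic prior std for pocket-only generation


def generation_schedule() -> NoiseSchedule:
    """Schedule used for toy generation: lambda linear 1e-3..0.12, T=100.

    Generation needs the terminal marginal to essentially reach the prior
    (alpha_bar_T ~ 2e-3 here); a weaker schedule leaves the ancestral chain
    anchored to its random initialization instead of the model.
    """
    return NoiseSchedule.linear(100, 1e-3, 0.12)


def make_diffusion_generator(model: NumpyDenoiser, sigma_iso: float = GEN_SIGMA):
    """Wrap a denoiser as a candidate generator.

    Priors for pocket-only generation are a single isotropic fragment at
    the pocket's cavity center (the shell centroid); the atom count of
    each sample is drawn from the model's learned size prior.  Conforms to
    the generator contract (pocket, count, seed, temperature) ->
    molecules; temperature is not consumed by this generator.
    """

    def generate(pocket: ProteinPocket, count: int, seed: int, temperature: float = 1.0):
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 31]))
        center = pocket.coords().mean(axis=0)
        out = []
        for k in range(count):
            n_atoms = model.sample_n_atoms(rng)
            priors = isotropic_priors(center, n_atoms, sigma_iso)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            out.append(sample_ligand(model, pocket, priors, n_atoms, seed=sub_seed))
        return out

    return generate


def pretraining_batch(world: ToyWorld, extraction: ExtractionParams | None = None) -> CurationBatch:
    """Training records built from the toy world's seated base ligands.

    Mirrors initializing from an already-trained generator: the denoiser is
    first fitted to realistic ligands so its samples are non-trivially
    valid before any alignment step."""
    extraction = extraction or ExtractionParams()
    records = []
    for i, (tid, pocket) in enumerate(world.targets()):
        ligand = world.base_ligand(i)
        decomposed = adaptive_decompose(ligand, pocket, extraction)
        records.append(
            CurationRecord(
                target_id=tid,
                ligand=ligand,
                pocket=pocket,
                decomposed=decomposed,
                priors=estimate_priors(decomposed),
                reward=RewardVector(0.0, 0.0, 0.0, 0.0, 0.0),
            )
        )
    return CurationBatch(records=records, batch_size_B=len(records))


def _mean_qed_of_samples(model, targets, n_samples, seed):
    """Mean/SE of QED over valid samples drawn round-robin from targets."""
    generator = make_diffusion_generator(model)
    qeds = []
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 41]))
    i = 0
    drawn = 0
    while drawn < n_samples:
        _, pocket = targets[i % len(targets)]
        mols = generator(pocket, 1, int(rng.integers(0, 2**31 - 1)))
        drawn += 1
        i += 1
        for m in mols:
            if is_valid(m):
                qeds.append(compute_qed(m))
    qeds = np.array(qeds)
    if qeds.size == 0:
        return float("nan"), float("nan"), 0
    se = float(qeds.std(ddof=1) / np.sqrt(qeds.size)) if qeds.size > 1 else float("inf")
    return float(qeds.mean()), se, int(qeds.size)


@dataclass
class AlignmentResult:
    pre_mean_qed: float
    pre_se: float
    pre_n_valid: int
    post_mean_qed: float
    post_se: float
    post_n_valid: int
    curated_targets: int
    skipped_targets: int


def alignment_experiment(
    seed: int = 0,
    n_targets: int = 8,
    K: int = 10,
    weights: RewardWeights = RewardWeights(1.0, 0.0, 0.0),
    pretrain_iters: int = 4000,
    pretrain_lr: float = 1e-3,
    finetune_lr: float = 1e-3,
    finetune_iters: int = 2000,
    eval_samples: int = 50,
) -> AlignmentResult:
    """One full Best-of-K alignment iteration on the toy world.

    Pre-trains the toy denoiser on the world's base ligands, measures the
    mean QED of samples, runs curation (generate K per target, rank by the
    reward, relocate, decompose) and fine-tuning, then re-measures.  The
    desk-scale sizes (8 targets, 50 evaluation samples) keep the full loop
    in the couple-of-minutes range on one CPU.
    """
    world = ToyWorld(ToyWorldConfig(seed=seed, n_targets=n_targets))
    targets = world.targets()
    model = NumpyDenoiser(schedule=generation_schedule())
    model = finetune(model, pretraining_batch(world), lr=pretrain_lr,
                     iters=pretrain_iters, seed=seed)

    pre_mean, pre_se, pre_n = _mean_qed_of_samples(model, targets, eval_samples, seed + 1)

    generator = make_diffusion_generator(model)
    scorer = SurrogateDockingScorer()
    config = SamplerConfig(K=K, seed=seed + 2)
    batch = build_curation_batch(targets, generator, scorer, weights, config)
    if not batch.records:
        raise RuntimeError("curation produced zero records; cannot fine-tune")
    tuned = finetune(model, batch, lr=finetune_lr, iters=finetune_iters, seed=seed + 3)

    post_mean, post_se, post_n = _mean_qed_of_samples(tuned, targets, eval_samples, seed + 4)
    return AlignmentResult(
        pre_mean_qed=pre_mean, pre_se=pre_se, pre_n_valid=pre_n,
        post_mean_qed=post_mean, post_se=post_se, post_n_valid=post_n,
        curated_targets=len(batch.records), skipped_targets=len(batch.skipped),
    )


def bon_sweep(
    seed: int = 0,
    Ns: tuple[int, ...] = (1, 5, 10, 20),
    repetitions: int = 200,
    weights: RewardWeights = RewardWeights(1.0, 1.0, 1.0),
    n_targets: int = 4,
    temperature: float = 1.0,
) -> dict[int, tuple[float, float]]:
    """Mean (and standard error) of the Best-of-N winner reward across N.

    Each repetition picks a toy target and runs an independent Best-of-N
    selection with the perturbation generator and the surrogate scorer.
    Larger N should not lower the expected winner reward.
    """
    world = ToyWorld(ToyWorldConfig(seed=seed, n_targets=n_targets))
    targets = world.targets()
    generator = world.make_generator()
    scorer = SurrogateDockingScorer()
    out: dict[int, tuple[float, float]] = {}
    for N in Ns:
        rewards = []
        for rep in range(repetitions):
            _, pocket = targets[rep % len(targets)]
            config = SamplerConfig(
                K=N, N=N, temperature=temperature,
                seed=(seed * 7919 + rep * 104729 + N * 1299721) % (2**31 - 1),
            )
            _, rv = best_of_n(generator, pocket, scorer, weights, config)
            rewards.append(rv.reward)
        rewards = np.array(rewards)
        out[N] = (float(rewards.mean()), float(rewards.std(ddof=1) / np.sqrt(len(rewards))))
    return out
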