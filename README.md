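# ligalign

Reward-ranked alignment of pocket-conditioned ligand generators, at desk
scale.  The package implements the full align-and-fine-tune cycle used to
steer diffusion-based structure-based drug design (SBDD) models toward
drug-like output, runnable end to end with no external dataset, trained
checkpoint, or docking installation:

* a **multi-objective reward** r = w_qed·QED + w_sa·SA + w_dock·dock_norm,
  where QED and synthetic accessibility (SA, mapped from the raw 1–10
  scale to [0, 1], higher = easier) come from RDKit and docking scores are
  min–max-normalized and inverted within each target's candidate cohort;
* **Best-of-K curation**: generate K candidates per target pocket, drop
  samples that fail reconstruction validity, keep the reward argmax,
  rigidly translate it so its center of mass matches the heavy-atom CoM
  of its docking pose, decompose it into arms and scaffold against the
  pocket, and fine-tune the generator on the curated records;
* **Best-of-N selection**: same ranking, no fine-tuning — just return the
  winner;
* a **decomposed diffusion model** over atom positions, element types and
  the five bond categories, with per-fragment Gaussian priors
  O_P = {mu_{1:K}, Sigma_{1:K}, H}, forward kernels
  q(x~_t|x~_{t-1}) = N(sqrt(alpha_t) x~_{t-1}, lambda_t Sigma) and
  p_t = (1-lambda_t) p_{t-1} + lambda_t/K, KL reconstruction losses, and
  an SGD fine-tuning loop;
* **evaluation**: per-metric means/medians, the success rate
  (QED > 0.25, SA > 0.59, Vina < -8.18, all strict), the "accumulated"
  summary QED + SA + Vina/(-10), and the Jensen–Shannon divergence
  (base 2) between binned bond-length distributions of two molecule sets;
* a **synthetic toy world** (pockets, grammar-built ligands, a
  deterministic geometric docking surrogate, perturbation and diffusion
  samplers) that exercises every stage.

It is aimed at method developers who want a small, fully testable
reference implementation of the alignment machinery around an SBDD
generator — not at production ligand design.

## Worked example

Create a toy world and run a Best-of-N sweep:

```bash
ligalign make-fixtures --out demo/world --seed 7 --n-targets 4
ligalign bon --out demo/bon --seed 7 --n-targets 4 --n 1 --n 10
```

`demo/bon/bon-report.json` then contains, per N, the metric summary over
the four per-target winners (this exact output, seed 7):

```json
"1":  {"means": {"qed": 0.587, "sa_norm": 0.886, "vina": -8.205}, "success_rate": 0.75}
"10": {"means": {"qed": 0.570, "sa_norm": 0.892, "vina": -8.571}, "success_rate": 0.75}
```

Reading it: with N = 10 the selected winners bind the surrogate pocket
better on average (vina -8.57 vs -8.20, lower is better) while QED/SA
stay in the drug-like range; 3 of 4 winners clear all three success
thresholds.  The full alignment loop (pre-train the toy denoiser, curate
a Best-of-K batch, fine-tune, report) runs as

```bash
ligalign align --out demo/align --seed 7 --n-targets 4
```

and writes per-iteration curation summaries, the fine-tuned model
artifact and the training-loss trace.  Library users can do the same in
a few lines:

```python
from ligalign.pipeline import alignment_experiment
res = alignment_experiment(seed=1)   # 8 targets, K=10, QED-only weights
print(res.pre_mean_qed, res.post_mean_qed)   # e.g. 0.477 -> 0.535
```

Other subcommands: `rank` (score candidate SDFs per target against
pocket PDBs and emit a reward table + winner SDFs), `prepare` (CoM
relocation of a ligand SDF onto a pose SDF), `evaluate` (metric summary
and per-bond-type JSD table for two molecule sets).

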