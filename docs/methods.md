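# Methods

## Problem setting

Structure-based drug design (SBDD) conditions a generative model on a
protein binding site P = {(x_i^P, v_i^P)} and asks for ligands
M = {(x_i^M, v_i^M, b_ij^M)} — 3D atom positions, element types over a
vocabulary of K_a elements, and bond types over five categories
(non-bonded, single, double, triple, aromatic) — that bind the site and
are drug-like.  Raw pocket-conditioned generators optimize likelihood, not
practitioner preferences, so this package implements a post-hoc alignment
cycle: generate a cohort of candidates per target, rank them with a
multi-objective reward, curate the winners, and fine-tune the generator on
them (Best-of-K), or simply return the cohort winner with no fine-tuning
(Best-of-N).

## Reward

For each candidate the reward is the weighted sum

    r = w_qed * QED + w_sa * SA_norm + w_dock * dock_norm

* QED is the RDKit quantitative estimate of drug-likeness, natively in
  [0, 1].
* SA_norm maps the RDKit synthetic-accessibility score s in [1, 10]
  (1 = easy) to (10 - s)/9, so higher means easier to synthesize.
* dock_norm min–max-normalizes the docking scores of the K candidates of
  *one* target and inverts them: the most negative (best) score of the
  cohort gets 1.0, the worst 0.0.  A degenerate cohort (all scores equal)
  maps to 0.5 everywhere, keeping the cohort rankable by the other two
  objectives.  Normalizing per cohort makes the docking term a relative
  signal; its absolute scale never leaks into the reward.

Weights are non-negative with at least one positive; the package default
is (1, 0, 0), i.e. QED-only ranking, which in practice also helps the
other metrics because the three objectives are positively coupled on
small drug-like molecules.

The success-rate metric counts molecules with QED > 0.25, SA_norm > 0.59
and docking score < -8.18 kcal/mol; all three inequalities are strict, so
boundary values fail.

## Pose relocation and decomposition

Generated ligands frequently float far from the pocket, which breaks any
step that needs ligand–pocket proximity.  `relocate_to_pose` rigidly
translates the generated ligand so that its center of mass coincides with
the center of mass of its docking pose, after stripping the pose's
hydrogens (docking tools add/remove them freely; only heavy atoms define a
stable anchor).  The CoM is mass-weighted by default; an unweighted
centroid mode exists for pipelines that define "CoM" geometrically.  The
operation changes no internal coordinates, so it is exactly idempotent and
preserves every interatomic distance.

`adaptive_decompose` partitions the ligand into peripheral **arms**
(|A| >= 1) and at most one central **scaffold** (|S| <= 1).  The graph is
cut at acyclic single bonds that join two ring systems, or join a ring
system to a chain of at least two atoms (so terminal methyls and single
substituents stay with their ring).  A fragment that links two or more
other fragments is scaffold material; each remaining peripheral fragment
becomes an arm when one of its atoms lies within `cutoff` (default 4 A) of
a pocket atom and within `radius` (default 6 A) of the fragment centroid.
If no arm qualifies, both thresholds are relaxed by 0.5 A up to 8 times;
if contact is never found, the whole ligand becomes a single arm with an
empty scaffold, so downstream priors always exist.  This decomposition is
a deliberately simple, fully documented graph-plus-proximity rule: it is
not a reimplementation of any sub-pocket detection tool, and the
relaxation order (joint in both thresholds) is a package choice.

## Decomposed diffusion

Each fragment k gets a Gaussian prior (mu_k, Sigma_k) estimated by maximum
likelihood from its member atoms (ddof=0 covariance, regularized by
+1e-3 I so single-atom fragments stay non-singular), plus the assignment H
of atoms to fragments.  Positions are expressed prior-centered:
x~_i = x_i - mu_{frag(i)}.

Forward process with schedule {lambda_t}, alpha_t = 1 - lambda_t,
alpha_bar_t = prod alpha_s:

* positions, "ddpm" mode (default):
  q(x~_t | x~_{t-1}) = N(sqrt(alpha_t) x~_{t-1}, lambda_t Sigma_frag), so
  the marginal is N(sqrt(alpha_bar_t) x~_0, (1 - alpha_bar_t) Sigma_frag)
  and the terminal state matches the fragment prior.  A second, "plain"
  mode drops the mean shrinkage, giving marginal
  N(x~_0, (sum_{s<=t} lambda_s) Sigma_frag); both are implemented and
  tested because the two conventions coexist in the literature and only
  the shrinkage form consumes the alpha_bar bookkeeping.
* categories (atom types, K_a; bond types, K_b = 5):
  p_t = (1 - lambda_t) p_{t-1} + lambda_t / K, with closed-form marginal
  p_t = alpha_bar_t p_0 + (1 - alpha_bar_t)/K.

The reverse-time posterior over the category at t-1 is the standard
uniform-noise discrete-diffusion posterior

    c(p_t, p_0) ∝ (alpha_t p_t + (1-alpha_t)/K)
                  ⊙ (alpha_bar_{t-1} p_0 + (1-alpha_bar_{t-1})/K),

verified against exhaustive Bayes in the tests.  Losses:
L_x = ||x_0 - x^_0||^2 summed over atoms, and L_v, L_b the KL divergences
KL(c(p_t, truth) || c(p_t, prediction)) summed over atoms / pairs;
L = L_x + gamma_v L_v + gamma_b L_b with gamma_v = gamma_b = 100 by
default.  Summation (not averaging) over atoms is a package convention.

### Schedules

`NoiseSchedule.linear()` defaults to lambda linear from 1e-4 to 0.02 over
T = 100 steps.  That schedule leaves alpha_bar_T ~= 0.37 — far from the
prior — which is adequate for training-time noising but ill-posed for
ancestral generation: the categorical chain then stays anchored to its
random initialization instead of following the model.  Generation in the
toy pipeline therefore uses `pipeline.generation_schedule()`, lambda
linear 1e-3..0.12 over T = 100 (alpha_bar_T ~= 2e-3).  Both endpoints and
T are configurable.

### Denoiser

The bundled denoiser is intentionally tiny — the alignment cycle, not the
network, is the point, and any object implementing
`predict(state, pocket, priors) -> (x^0, v^0, b^0)` can replace it:

* positions: x^0 = c_x * sqrt(alpha_bar_t) * x~_t with learnable scalar
  c_x (the optimal linear shrinkage when the data variance matches the
  prior variance);
* atom types: softmax of global logits plus a linear map of per-atom
  features (sqrt(alpha_bar_t), distance to the nearest pocket atom,
  local neighbor density);
* bond types: softmax of global logits plus a linear map of pair features
  (pair distance, sqrt(alpha_bar_t));
* a learnable atom-count prior (softmax over 4..16 heavy atoms) — the
  desk-scale analogue of the ligand-size prior that pocket-conditioned
  generators fit on training complexes.  It is updated by cross-entropy
  on the sizes of training records and sampled at generation time, which
  lets Best-of-K curation transfer size preferences (the dominant QED
  lever at this scale) into the fine-tuned model.

All gradients are analytic (chain rule through the softmax and through
the categorical posterior); optimization is plain SGD.  No equivariance is
claimed: the position head is a scalar shrinkage, which is exactly why
sampling yields Gaussian "blob" geometries rather than realistic
conformers (see Limitations).

### Sampling and reconstruction

Ancestral sampling starts from the fragment priors (positions
~ N(0, Sigma_frag) in the shifted frame; categories uniform one-hot) and
iterates t = T..1 with the model's predictions and the posterior kernels;
at t = 1 categories are discretized by argmax.  Molecule reconstruction is
distance-first, as in geometry-based reconstruction tools: pairs at clear
covalent distance (0.8–1.75 A) are always bonded with the predicted
category setting the order, pairs in the 1.75–2.0 A shell are bonded only
when the model predicts a bond, aromatic predictions outside rings are
downgraded to single (an isolated aromatic bond cannot be kekulized), and
atoms over their element's maximum valence lose their longest bonds.
Samples may still be invalid (typically disconnected); validity filtering
is a separate downstream step, exactly as failed reconstructions are
excluded in the full-scale pipeline.

## Fine-tuning (Best-of-K) and Best-of-N

One alignment iteration: per target, draw K = 10 candidates, drop invalid
samples, score and rank, relocate the winner onto its docking pose,
decompose, attach priors; fine-tune the denoiser on the curated records
(t drawn uniformly per SGD step).  Full-scale settings are lr = 1e-6 and
1000 iterations from a trained checkpoint; the desk-scale toy experiment
uses lr = 1e-3 and 2000 iterations because the tiny denoiser needs larger
steps to move at all.  Targets whose cohort has no valid sample are
skipped and logged, never retried within an iteration.  Best-of-N shares
the generate-and-rank step but returns the winner directly and touches no
model state; its docking normalization is over the N valid draws of that
target, and BoN summaries are computed over winners only.

## Synthetic toy world

The fixture generator stands in for the training distribution:

* **Pockets**: ~48 pseudo-atoms (C/N/O) on a spherical cap of radius
  ~5 A with an opening toward +z; deterministic per (seed, index).
* **Ligands**: assembled from a fragment grammar (benzene, cyclohexane,
  cyclopentane rings; 2–3-atom chain linkers; terminal O/N/F/C
  substituents) with idealized geometry plus 0.05 A jitter.  The
  "dumbbell" template (ring–linker–ring) carries a planted 2-arm /
  1-scaffold partition for decomposition tests.
* **Surrogate docking**: a smooth contact potential — Gaussian attractive
  well centered at 3.5 A (width 0.7 A) plus a linear clash penalty below
  2.5 A — summed over ligand–pocket heavy-atom pairs and scaled by the
  calibration constant DOCK_SCALE = 0.08, chosen once so seated toy
  ligands score roughly in [-10, -5.4]: the -8.18 success threshold is
  reachable but not trivial.  The score is invariant under joint rigid
  motion and deterministic.  "Docking" a ligand translates its CoM to the
  cavity center and returns that pose.
* **Perturbation sampler**: K jittered copies of a base ligand
  (jitter sd = 0.15 * temperature) with occasional terminal-substituent
  element swaps; a configurable fraction of samples is deliberately
  disconnected to exercise validity filtering.

What the toy world does *not* emulate: real conformational ensembles,
docking physics, protein flexibility, or the chemical diversity of a real
training set.  Passing tests demonstrate the correctness of the ranking,
relocation, decomposition, diffusion and fine-tuning machinery — not that
the toy denoiser generates publishable ligands.

## Desk-scale experiments

* **Alignment experiment** (`pipeline.alignment_experiment`): 8 toy
  targets; the denoiser is first pre-trained for 4000 SGD steps (lr 1e-3)
  on the world's seated base ligands — the analogue of starting from a
  trained checkpoint — then one Best-of-K iteration (K = 10, weights
  (1, 0, 0), fine-tune lr 1e-3, 2000 steps) is run and the mean QED of 50
  fresh samples is compared before and after.  Typical runs improve mean
  QED by +0.03 to +0.07, mostly through the learned size prior shifting
  toward the curated winners.  Runtime ~15 s on one CPU.
* **Best-of-N sweep** (`pipeline.bon_sweep`): 200 independent Best-of-N
  selections per N over the toy targets with weights (1, 1, 1); the mean
  winner reward is non-decreasing in N within one Monte-Carlo standard
  error.  The big jump is from N = 1 (where the degenerate docking
  normalization pins dock_norm at 0.5) to N = 5; beyond that the curve
  plateaus.

## Numerical choices

* Fragment covariance regularization: +1e-3 A^2 on the diagonal.
* Histogram for bond-length JSD: fixed 0.02 A bins over [0.8, 3.0] A,
  out-of-range lengths clipped into the edge bins; base-2 logarithms so
  the divergence lives in [0, 1]; zero-count bins need no pseudo-counts
  because the mixture construction handles them (0 log 0 = 0).  Bin
  settings are a config object (`JSDBins`).
* Element pairs in bond queries match unordered (C–N means N–C too).
* Ties in Best-of-K break to the lowest candidate index.
* Every stochastic operation takes an explicit seed; run-level seeds fan
  out deterministically via `numpy.random.SeedSequence`.
* Model persistence is a single JSON artifact (parameters, schedule,
  vocabulary); the parameter count is small enough that a binary format
  would buy nothing.

## Known limitations

* The scalar position head cannot produce structured geometry; generated
  molecules are connectivity-plausible blobs.  Validity (~30–50% in the
  toy pipeline) comes from distance-gated reconstruction plus filtering.
* The decomposition is a simplified stand-in for sub-pocket-based tools;
  arm/scaffold labels agree with planted constructions on the toy grammar
  but are not validated against any external decomposer.
* QED/SA are computed on the molecular graph, so rigid relocation cannot
  change them; the ablation question of "score before or after
  relocation" is moot here by construction.
* The external docking adapter (`ExternalDockingScorer`) shells out to a
  user-supplied executable and is not exercised by the test suite.
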