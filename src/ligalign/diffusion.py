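"""Desk-scale decomposed diffusion over ligand positions, atom types and bonds.

The generative model diffuses three coupled variables conditioned on a
protein pocket: continuous atom positions, a categorical atom-type variable
over ``K_a`` elements, and a categorical bond-type variable over the five
bond categories (non-bonded, single, double, triple, aromatic).  Positions
are expressed in a *prior-centered* frame: each atom is shifted by the mean
of its fragment (arm or scaffold), and the position noise is drawn from the
fragment's covariance, so fragments with tight geometry get tight noise.

Forward process, per step t with rate schedule {lambda_t}, alpha_t =
1 - lambda_t, alpha_bar_t = prod alpha_s:

* positions ("ddpm" mode, default):
    x_t | x_{t-1} ~ N(sqrt(alpha_t) x_{t-1}, lambda_t Sigma_frag)
  giving the marginal N(sqrt(alpha_bar_t) x_0, (1 - alpha_bar_t) Sigma_frag).
  An alternative "plain" mode omits the sqrt(alpha_t) mean shrinkage, in
  which case the marginal is N(x_0, (sum_{s<=t} lambda_s) Sigma_frag).
* categories:  p_t = (1 - lambda_t) p_{t-1} + lambda_t / K, whose closed
  form from step 0 is p_t = alpha_bar_t p_0 + (1 - alpha_bar_t) / K.

Training minimizes  L = L_x + gamma_v L_v + gamma_b L_b  where L_x is the
squared position-reconstruction error and L_v, L_b are KL divergences
between the true and predicted categorical posteriors.

The bundled denoiser is a deliberately small distance-featurized predictor
whose few parameters are trained by plain SGD with hand-derived gradients;
it honors the same predict() contract a full equivariant network would, and
any object with that contract can be plugged in instead.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .moltypes import BOND_ORDERS, Atom, Bond, Molecule3D, MoleculeError, ProteinPocket
from .pose_prep import DecomposedLigand

__all__ = [
    "NoiseSchedule",
    "DecompPriors",
    "DiffusionState",
    "LossWeights",
    "estimate_priors",
    "isotropic_priors",
    "prior_shift",
    "prior_unshift",
    "forward_position",
    "forward_categorical_step",
    "forward_categorical",
    "categorical_posterior",
    "loss_terms",
    "NumpyDenoiser",
    "sample_ligand",
    "finetune",
    "build_training_arrays",
    "DEFAULT_ATOM_VOCAB",
]

#: bond categories of the discrete diffusion; index 0 is the implicit
#: "non-bonded" category, the rest follow moltypes.BOND_ORDERS.
BOND_CATEGORIES = ("none",) + BOND_ORDERS
K_BOND = len(BOND_CATEGORIES)

DEFAULT_ATOM_VOCAB = ("C", "N", "O", "F", "S")

SIGMA_REG = 1e-3  # Angstrom^2, diagonal regularization of fragment covariances

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2}
_ORDER_VALENCE = {"single": 1, "double": 2, "triple": 3, "aromatic": 1}


# --------------------------------------------------------------------------
# schedule
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSchedule:
    """Corruption-rate schedule lambda_1..lambda_T with alpha bookkeeping."""

    lambdas: np.ndarray  # shape (T,), entries in (0, 1)

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim != 1 or lam.size == 0:
            raise ValueError("schedule must be a non-empty 1-D array")
        if np.any(lam <= 0) or np.any(lam >= 1):
            raise ValueError("lambda_t must lie strictly in (0, 1)")
        object.__setattr__(self, "lambdas", lam)

    @classmethod
    def linear(cls, T: int = 100, start: float = 1e-4, end: float = 0.02) -> "NoiseSchedule":
        return cls(np.linspace(start, end, T))

    @property
    def T(self) -> int:
        return int(self.lambdas.size)

    def lam(self, t: int) -> float:
        return float(self.lambdas[t - 1])

    def alpha(self, t: int) -> float:
        return 1.0 - self.lam(t)

    def alpha_bar(self, t: int) -> float:
        """prod_{s<=t} alpha_s; alpha_bar(0) = 1."""
        if t == 0:
            return 1.0
        return float(np.prod(1.0 - self.lambdas[:t]))

    def lambda_cumsum(self, t: int) -> float:
        return float(np.sum(self.lambdas[:t]))


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------


@dataclass
class DecompPriors:
    """Per-fragment Gaussian priors and the atom->fragment assignment."""

    mu: np.ndarray  # (K, 3)
    sigma: np.ndarray  # (K, 3, 3) symmetric PD (after regularization)
    assignment: np.ndarray  # (N,) fragment index per atom

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).reshape(-1, 3)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(-1, 3, 3)
        self.assignment = np.asarray(self.assignment, dtype=int)
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("fragment means must be finite")
        K = self.mu.shape[0]
        if self.sigma.shape[0] != K:
            raise ValueError("mu/sigma fragment counts differ")
        if self.assignment.min(initial=0) < 0 or (
            self.assignment.size and self.assignment.max() >= K
        ):
            raise ValueError("atom assignment references unknown fragment")
        # eigenvalue check: PSD up to small numerical slack
        for k in range(K):
            w = np.linalg.eigvalsh((self.sigma[k] + self.sigma[k].T) / 2)
            if w.min() < -1e-9:
                raise ValueError(f"fragment {k} covariance is not PSD")

    @property
    def n_fragments(self) -> int:
        return int(self.mu.shape[0])

    def chol(self) -> np.ndarray:
        """Cholesky factors of the (regularized) fragment covariances."""
        return np.linalg.cholesky(self.sigma)

    def per_atom_mu(self) -> np.ndarray:
        return self.mu[self.assignment]

    def per_atom_chol(self) -> np.ndarray:
        return self.chol()[self.assignment]

    def per_atom_sigma(self) -> np.ndarray:
        return self.sigma[self.assignment]


def estimate_priors(decomposed: DecomposedLigand) -> DecompPriors:
    """Maximum-likelihood fragment priors from the decomposed ligand.

    Per fragment: mu is the mean of the member-atom coordinates and sigma
    the ML (ddof=0) sample covariance plus SIGMA_REG * I, so single-atom
    fragments get an isotropic floor instead of a singular matrix.
    """
    coords = decomposed.ligand.coords()
    fragments = decomposed.fragments
    K = len(fragments)
    mu = np.zeros((K, 3))
    sigma = np.zeros((K, 3, 3))
    assignment = np.full(decomposed.ligand.n_atoms, -1, dtype=int)
    for k, frag in enumerate(fragments):
        idx = sorted(frag)
        xyz = coords[idx]
        mu[k] = xyz.mean(axis=0)
        centered = xyz - mu[k]
        sigma[k] = centered.T @ centered / len(idx) + SIGMA_REG * np.eye(3)
        assignment[idx] = k
    return DecompPriors(mu=mu, sigma=sigma, assignment=assignment)


def isotropic_priors(center, n_atoms: int, sigma_iso: float = 1.0) -> DecompPriors:
    """Single-fragment isotropic prior used when generating from a pocket
    alone (no reference ligand to decompose)."""
    center = np.asarray(center, dtype=float).reshape(3)
    return DecompPriors(
        mu=center[None, :],
        sigma=(sigma_iso**2 * np.eye(3))[None, :, :],
        assignment=np.zeros(n_atoms, dtype=int),
    )


def prior_shift(positions: np.ndarray, priors: DecompPriors) -> np.ndarray:
    """x_i -> x_i - mu_{frag(i)} (exactly inverted by prior_unshift)."""
    return np.asarray(positions, dtype=float) - priors.per_atom_mu()


def prior_unshift(positions: np.ndarray, priors: DecompPriors) -> np.ndarray:
    return np.asarray(positions, dtype=float) + priors.per_atom_mu()


# --------------------------------------------------------------------------
# forward process
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ForwardPositionResult:
    sample: np.ndarray  # (N, 3)
    marginal_mean: np.ndarray  # (N, 3)
    marginal_cov_scale: float  # marginal covariance = scale * Sigma_frag(i)


def forward_position(
    x0_shifted: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    priors: DecompPriors,
    mode: str = "ddpm",
    rng: np.random.Generator | None = None,
) -> ForwardPositionResult:
    """Sample the noised positions at time t and return the analytic marginal.

    mode "ddpm":  marginal N(sqrt(alpha_bar_t) x_0, (1-alpha_bar_t) Sigma).
    mode "plain": marginal N(x_0, (sum_{s<=t} lambda_s) Sigma) — the
    variance-growing variant without mean shrinkage.
    """
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t={t} outside schedule range 1..{schedule.T}")
    x0 = np.asarray(x0_shifted, dtype=float).reshape(-1, 3)
    if mode == "ddpm":
        abar = schedule.alpha_bar(t)
        mean = np.sqrt(abar) * x0
        scale = 1.0 - abar
    elif mode == "plain":
        mean = x0.copy()
        scale = schedule.lambda_cumsum(t)
    else:
        raise ValueError(f"unknown forward-position mode {mode!r}")
    rng = rng or np.random.default_rng()
    z = rng.standard_normal(x0.shape)
    chol = priors.per_atom_chol()
    noise = np.einsum("nij,nj->ni", chol, z)
    return ForwardPositionResult(
        sample=mean + np.sqrt(scale) * noise,
        marginal_mean=mean,
        marginal_cov_scale=float(scale),
    )


def forward_categorical_step(
    p_prev: np.ndarray, t: int, schedule: NoiseSchedule, k_cat: int
) -> np.ndarray:
    """One uniform-noise step: p_t = (1-lambda_t) p_{t-1} + lambda_t / K."""
    if k_cat < 2:
        raise ValueError("categorical diffusion needs at least 2 categories")
    lam = schedule.lam(t)
    return (1.0 - lam) * np.asarray(p_prev, dtype=float) + lam / k_cat


def forward_categorical(
    p0: np.ndarray, t: int, schedule: NoiseSchedule, k_cat: int
) -> np.ndarray:
    """Closed-form marginal: p_t = alpha_bar_t p_0 + (1 - alpha_bar_t) / K."""
    if k_cat < 2:
        raise ValueError("categorical diffusion needs at least 2 categories")
    if not 0 <= t <= schedule.T:
        raise ValueError(f"t={t} outside schedule range")
    abar = schedule.alpha_bar(t)
    return abar * np.asarray(p0, dtype=float) + (1.0 - abar) / k_cat


def categorical_posterior(
    p_t: np.ndarray, p_0: np.ndarray, t: int, schedule: NoiseSchedule, k_cat: int
) -> np.ndarray:
    """Posterior over the category at t-1 given the state at t and at 0.

    c(p_t, p_0) = normalize[ (alpha_t p_t + (1-alpha_t)/K)
                             * (alpha_bar_{t-1} p_0 + (1-alpha_bar_{t-1})/K) ]

    Broadcasts over leading axes; the category axis is the last one.
    """
    if t < 1:
        raise ValueError("posterior requires t >= 1")
    a = schedule.alpha(t) * np.asarray(p_t, dtype=float) + (1.0 - schedule.alpha(t)) / k_cat
    abar_prev = schedule.alpha_bar(t - 1)
    m = abar_prev * np.asarray(p_0, dtype=float) + (1.0 - abar_prev) / k_cat
    n = a * m
    z = n.sum(axis=-1, keepdims=True)
    if np.any(z <= 0):
        raise FloatingPointError("categorical posterior normalizer vanished")
    return n / z


# --------------------------------------------------------------------------
# states and losses
# --------------------------------------------------------------------------


@dataclass
class DiffusionState:
    """(positions, atom-type simplex, bond-type simplex) at time t.

    Positions live in the prior-centered frame.  Bond probabilities are
    indexed by the upper-triangle pair list (i < j, lexicographic).
    """

    positions: np.ndarray  # (N, 3)
    atom_probs: np.ndarray  # (N, K_a)
    bond_probs: np.ndarray  # (N*(N-1)/2, K_BOND)
    t: int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.atom_probs = np.asarray(self.atom_probs, dtype=float)
        self.bond_probs = np.asarray(self.bond_probs, dtype=float)
        n = self.positions.shape[0]
        if self.atom_probs.shape[0] != n:
            raise ValueError("atom_probs row count must match atom count")
        if self.bond_probs.shape != (n * (n - 1) // 2, K_BOND):
            raise ValueError("bond_probs must cover all atom pairs with 5 categories")
        for probs, label in ((self.atom_probs, "atom"), (self.bond_probs, "bond")):
            if probs.size and not np.allclose(probs.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"{label} probabilities must sum to 1")


def pair_index(n: int) -> np.ndarray:
    """Upper-triangle (i, j) pairs, i < j, lexicographic; shape (P, 2)."""
    iu = np.triu_indices(n, k=1)
    return np.stack(iu, axis=1)


@dataclass(frozen=True)
class LossWeights:
    gamma_v: float = 100.0
    gamma_b: float = 100.0

    def __post_init__(self):
        if self.gamma_v < 0 or self.gamma_b < 0:
            raise ValueError("loss weights must be non-negative")


def _kl(q: np.ndarray, r: np.ndarray) -> float:
    """Sum of categorical KL(q||r) over all leading axes, with 0 log 0 = 0."""
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    mask = q > 0
    out = np.zeros_like(q)
    out[mask] = q[mask] * (np.log(q[mask]) - np.log(np.maximum(r[mask], 1e-300)))
    return float(out.sum())


def loss_terms(
    state_t: DiffusionState,
    truth: tuple[np.ndarray, np.ndarray, np.ndarray],
    pred: tuple[np.ndarray, np.ndarray, np.ndarray],
    t: int,
    schedule: NoiseSchedule,
    weights: LossWeights = LossWeights(),
) -> tuple[float, float, float, float]:
    """(L_x, L_v, L_b, L_total) for one noisy state.

    L_x is the squared Euclidean reconstruction error summed over atoms;
    L_v and L_b are KL divergences between the categorical posteriors built
    from the truth and from the prediction, summed over atoms / pairs.
    """
    x0, v0, b0 = truth
    xh, vh, bh = pred
    k_a = np.asarray(v0).shape[-1]
    L_x = float(np.sum((np.asarray(x0) - np.asarray(xh)) ** 2))
    q_v = categorical_posterior(state_t.atom_probs, v0, t, schedule, k_a)
    r_v = categorical_posterior(state_t.atom_probs, vh, t, schedule, k_a)
    L_v = _kl(q_v, r_v)
    q_b = categorical_posterior(state_t.bond_probs, b0, t, schedule, K_BOND)
    r_b = categorical_posterior(state_t.bond_probs, bh, t, schedule, K_BOND)
    L_b = _kl(q_b, r_b)
    return L_x, L_v, L_b, L_x + weights.gamma_v * L_v + weights.gamma_b * L_b


# --------------------------------------------------------------------------
# denoiser
# --------------------------------------------------------------------------


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class NumpyDenoiser:
    """Tiny distance-featurized denoiser fulfilling the predict() contract.

    * positions:  x_hat0 = c_x * sqrt(alpha_bar_t) * x_t  (the optimal
      linear shrinkage when the data variance matches the prior variance,
      with c_x learnable),
    * atom types: softmax(theta_v + W_v f_i) with per-atom features
      f_i = [sqrt(alpha_bar_t), nearest-pocket distance / 10,
      close-neighbor count / 10],
    * bond types: softmax(theta_b + W_b g_ij) with pair features
      g_ij = [min(d_ij, 6)/3, sqrt(alpha_bar_t)].

    The model also carries a learnable atom-count prior (softmax over
    SIZE_SUPPORT), the desk-scale analogue of the ligand-size prior that
    pocket-conditioned generators fit on their training complexes; it is
    updated during (pre-)training by cross-entropy on the record sizes and
    sampled from at generation time.

    All parameters are trained with plain SGD; gradients are analytic
    (chain rule through the softmax and the categorical posterior).
    """

    N_ATOM_FEATS = 3
    N_BOND_FEATS = 2
    SIZE_SUPPORT = tuple(range(4, 17))  # heavy atoms

    def __init__(
        self,
        schedule: NoiseSchedule | None = None,
        atom_vocab: tuple[str, ...] = DEFAULT_ATOM_VOCAB,
        forward_mode: str = "ddpm",
    ):
        self.schedule = schedule or NoiseSchedule.linear()
        self.atom_vocab = tuple(atom_vocab)
        self.forward_mode = forward_mode
        k_a = len(self.atom_vocab)
        self.params = {
            "c_x": np.array(1.0),
            "theta_v": np.zeros(k_a),
            "W_v": np.zeros((k_a, self.N_ATOM_FEATS)),
            "theta_b": np.zeros(K_BOND),
            "W_b": np.zeros((K_BOND, self.N_BOND_FEATS)),
            "size_logits": np.zeros(len(self.SIZE_SUPPORT)),
        }
        self.last_trace: list[float] = []

    # -- contract ------------------------------------------------------------

    @property
    def k_atom(self) -> int:
        return len(self.atom_vocab)

    def state_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for key in sorted(self.params):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.params[key]).tobytes())
        return h.hexdigest()

    def _features(self, state: DiffusionState, pocket: ProteinPocket, priors: DecompPriors):
        x_world = prior_unshift(state.positions, priors)
        n = x_world.shape[0]
        sqrt_abar = np.sqrt(self.schedule.alpha_bar(state.t))
        poc = pocket.coords()
        d_poc = np.linalg.norm(x_world[:, None, :] - poc[None, :, :], axis=-1).min(axis=1)
        d_all = np.linalg.norm(x_world[:, None, :] - x_world[None, :, :], axis=-1)
        close = ((d_all < 2.2).sum(axis=1) - 1) / 10.0
        f_atom = np.stack([np.full(n, sqrt_abar), d_poc / 10.0, close], axis=1)
        pairs = pair_index(n)
        d_pair = np.linalg.norm(x_world[pairs[:, 0]] - x_world[pairs[:, 1]], axis=-1)
        g_bond = np.stack([np.minimum(d_pair, 6.0) / 3.0,
                           np.full(len(pairs), sqrt_abar)], axis=1)
        return f_atom, g_bond

    def predict(self, state: DiffusionState, pocket: ProteinPocket, priors: DecompPriors):
        """(x_hat0, v_hat0, b_hat0) — positions in the shifted frame,
        categorical predictions as simplices."""
        f_atom, g_bond = self._features(state, pocket, priors)
        sqrt_abar = np.sqrt(self.schedule.alpha_bar(state.t))
        xh = float(self.params["c_x"]) * sqrt_abar * state.positions
        vh = _softmax(self.params["theta_v"][None, :] + f_atom @ self.params["W_v"].T)
        bh = _softmax(self.params["theta_b"][None, :] + g_bond @ self.params["W_b"].T)
        return xh, vh, bh

    def size_probs(self) -> np.ndarray:
        return _softmax(self.params["size_logits"])

    def sample_n_atoms(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.SIZE_SUPPORT, p=self.size_probs()))

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "atom_vocab": list(self.atom_vocab),
            "forward_mode": self.forward_mode,
            "schedule_lambdas": self.schedule.lambdas.tolist(),
            "params": {k: np.asarray(v).tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "NumpyDenoiser":
        payload = json.loads(Path(path).read_text())
        model = cls(
            schedule=NoiseSchedule(np.array(payload["schedule_lambdas"])),
            atom_vocab=tuple(payload["atom_vocab"]),
            forward_mode=payload["forward_mode"],
        )
        model.params = {k: np.array(v) for k, v in payload["params"].items()}
        return model


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


def build_training_arrays(
    ligand: Molecule3D, priors: DecompPriors, atom_vocab: tuple[str, ...]
):
    """(x0_shifted, v0 one-hot, b0 one-hot) for one training ligand."""
    elements = ligand.elements()
    vocab_index = {e: k for k, e in enumerate(atom_vocab)}
    try:
        v_idx = np.array([vocab_index[e] for e in elements])
    except KeyError as exc:
        raise MoleculeError(f"element {exc} outside the atom vocabulary {atom_vocab}")
    n = ligand.n_atoms
    v0 = np.eye(len(atom_vocab))[v_idx]
    pairs = pair_index(n)
    pair_pos = {(int(i), int(j)): k for k, (i, j) in enumerate(pairs)}
    b_idx = np.zeros(len(pairs), dtype=int)
    order_index = {o: k + 1 for k, o in enumerate(BOND_ORDERS)}
    for b in ligand.bonds:
        key = (min(b.i, b.j), max(b.i, b.j))
        b_idx[pair_pos[key]] = order_index[b.order]
    b0 = np.eye(K_BOND)[b_idx]
    x0 = prior_shift(ligand.coords(), priors)
    return x0, v0, b0


def _posterior_kl_grad(p_t, p0, p_hat, t, schedule, k_cat):
    """Gradient of KL(c(p_t,p0) || c(p_t,p_hat)) w.r.t. p_hat (batched)."""
    alpha = schedule.alpha(t)
    abar_prev = schedule.alpha_bar(t - 1)
    a = alpha * p_t + (1.0 - alpha) / k_cat
    m_true = abar_prev * p0 + (1.0 - abar_prev) / k_cat
    q = a * m_true
    q = q / q.sum(axis=-1, keepdims=True)
    m_hat = abar_prev * p_hat + (1.0 - abar_prev) / k_cat
    nh = a * m_hat
    z = nh.sum(axis=-1, keepdims=True)
    # d/dp_hat [-sum q log n + log Z]  with dn/dp_hat = a * abar_prev
    grad = a * abar_prev * (1.0 / z - q / nh)
    kl = _kl(q, nh / z)
    return kl, grad


def _softmax_backward(p: np.ndarray, grad_p: np.ndarray) -> np.ndarray:
    dot = (p * grad_p).sum(axis=-1, keepdims=True)
    return p * (grad_p - dot)


def finetune(
    model: NumpyDenoiser,
    batch,
    lr: float = 1e-6,
    iters: int = 1000,
    seed: int = 0,
    loss_weights: LossWeights = LossWeights(),
    trace_path=None,
) -> NumpyDenoiser:
    """SGD fine-tuning of the denoiser on a curated batch.

    Per iteration: draw a record and a time step t uniformly, noise the
    record's ground truth through the forward process, and take one
    gradient step on L_x + gamma_v L_v + gamma_b L_b.  Returns a new model;
    the input model is left untouched.  ``batch`` is anything with a
    non-empty ``records`` list whose entries expose ``ligand``, ``pocket``
    and ``priors``.
    """
    records = list(batch.records)
    if not records:
        raise ValueError("cannot fine-tune on an empty batch")
    model = copy.deepcopy(model)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
    schedule = model.schedule
    k_a = model.k_atom

    prepared = [
        (rec, build_training_arrays(rec.ligand, rec.priors, model.atom_vocab))
        for rec in records
    ]
    trace = []
    for _ in range(iters):
        rec, (x0, v0, b0) = prepared[int(rng.integers(len(prepared)))]
        t = int(rng.integers(1, schedule.T + 1))
        fwd = forward_position(x0, t, schedule, rec.priors, model.forward_mode, rng)
        v_t = _sample_onehot(forward_categorical(v0, t, schedule, k_a), rng)
        b_t = _sample_onehot(forward_categorical(b0, t, schedule, K_BOND), rng)
        state = DiffusionState(positions=fwd.sample, atom_probs=v_t, bond_probs=b_t, t=t)

        f_atom, g_bond = model._features(state, rec.pocket, rec.priors)
        sqrt_abar = np.sqrt(schedule.alpha_bar(t))
        c_x = float(model.params["c_x"])
        xh = c_x * sqrt_abar * state.positions
        z_v = model.params["theta_v"][None, :] + f_atom @ model.params["W_v"].T
        vh = _softmax(z_v)
        z_b = model.params["theta_b"][None, :] + g_bond @ model.params["W_b"].T
        bh = _softmax(z_b)

        # losses + gradients
        resid = x0 - xh
        L_x = float(np.sum(resid**2))
        g_cx = float(np.sum(-2.0 * sqrt_abar * state.positions * resid))

        L_v, g_vh = _posterior_kl_grad(v_t, v0, vh, t, schedule, k_a)
        g_zv = _softmax_backward(vh, g_vh)
        L_b, g_bh = _posterior_kl_grad(b_t, b0, bh, t, schedule, K_BOND)
        g_zb = _softmax_backward(bh, g_bh)

        gv, gb = loss_weights.gamma_v, loss_weights.gamma_b
        model.params["c_x"] = model.params["c_x"] - lr * g_cx
        model.params["theta_v"] -= lr * gv * g_zv.sum(axis=0)
        model.params["W_v"] -= lr * gv * (g_zv.T @ f_atom)
        model.params["theta_b"] -= lr * gb * g_zb.sum(axis=0)
        model.params["W_b"] -= lr * gb * (g_zb.T @ g_bond)

        # atom-count prior: cross-entropy step toward this record's size
        support = model.SIZE_SUPPORT
        s_idx = int(np.clip(rec.ligand.n_atoms, support[0], support[-1])) - support[0]
        p_size = _softmax(model.params["size_logits"])
        onehot = np.zeros(len(support))
        onehot[s_idx] = 1.0
        model.params["size_logits"] -= lr * (p_size - onehot)

        trace.append(L_x + gv * L_v + gb * L_b)

    model.last_trace = trace
    if trace_path is not None:
        lines = ["iteration,loss"] + [f"{i},{v}" for i, v in enumerate(trace)]
        Path(trace_path).write_text("\n".join(lines) + "\n")
    return model


def _sample_onehot(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one category per row of a simplex batch, as one-hot rows."""
    probs = np.asarray(probs, dtype=float)
    cdf = probs.cumsum(axis=-1)
    u = rng.random(probs.shape[:-1] + (1,))
    idx = (u > cdf).sum(axis=-1)
    idx = np.minimum(idx, probs.shape[-1] - 1)
    return np.eye(probs.shape[-1])[idx]


# --------------------------------------------------------------------------
# sampling (reverse process + reconstruction)
# --------------------------------------------------------------------------


def _position_posterior(x_t, x_hat0, t, schedule, mode):
    """Mean and covariance scale of q(x_{t-1} | x_t, x_hat0)."""
    lam = schedule.lam(t)
    if mode == "ddpm":
        abar_t = schedule.alpha_bar(t)
        abar_prev = schedule.alpha_bar(t - 1)
        alpha = schedule.alpha(t)
        denom = 1.0 - abar_t
        mean = (np.sqrt(abar_prev) * lam * x_hat0 + np.sqrt(alpha) * (1.0 - abar_prev) * x_t) / denom
        scale = lam * (1.0 - abar_prev) / denom
    else:  # plain: kernels N(x_{t-1}, lam Sigma), marginal N(x0, csum Sigma)
        c_t = schedule.lambda_cumsum(t)
        c_prev = schedule.lambda_cumsum(t - 1)
        if c_prev == 0.0:
            return x_hat0, 0.0
        mean = (c_prev * x_t + lam * x_hat0) / c_t
        scale = lam * c_prev / c_t
    return mean, scale


def sample_ligand(
    model: NumpyDenoiser,
    pocket: ProteinPocket,
    priors: DecompPriors,
    n_atoms: int,
    schedule: NoiseSchedule | None = None,
    seed: int = 0,
) -> Molecule3D:
    """Ancestral sampling through the reverse process, then reconstruction.

    Starts from prior noise (positions ~ N(0, Sigma_frag) in the shifted
    frame, categories uniform), iterates t = T..1 with the model's
    predictions and the posterior kernels, un-shifts by the fragment means,
    and discretizes categories by argmax.

    Bond reconstruction is distance-first, as in geometry-based molecular
    reconstruction tools: atom pairs at clear covalent distance (0.8–1.75
    Angstrom) are always bonded, with the predicted category setting the
    order (single unless the model says double/triple); pairs in the outer
    shell (1.75–2.0 Angstrom) are bonded only when the model predicts a
    bond.  Aromatic predictions are downgraded to single bonds because an
    isolated aromatic assignment outside a proper ring cannot be
    kekulized.  Atoms exceeding their element's maximum valence lose their
    longest bonds.  The result may still fail validity; callers filter.
    """
    schedule = schedule or model.schedule
    if priors.assignment.size != n_atoms:
        raise ValueError("priors must assign exactly n_atoms atoms")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 23]))
    k_a = model.k_atom
    n_pairs = n_atoms * (n_atoms - 1) // 2

    chol = priors.per_atom_chol()
    x = np.einsum("nij,nj->ni", chol, rng.standard_normal((n_atoms, 3)))
    v = _sample_onehot(np.full((n_atoms, k_a), 1.0 / k_a), rng)
    b = _sample_onehot(np.full((n_pairs, K_BOND), 1.0 / K_BOND), rng)

    for t in range(schedule.T, 0, -1):
        state = DiffusionState(positions=x, atom_probs=v, bond_probs=b, t=t)
        xh, vh, bh = model.predict(state, pocket, priors)
        mean, scale = _position_posterior(x, xh, t, schedule, model.forward_mode)
        if t > 1:
            noise = np.einsum("nij,nj->ni", chol, rng.standard_normal((n_atoms, 3)))
            x = mean + np.sqrt(max(scale, 0.0)) * noise
            v = _sample_onehot(categorical_posterior(v, vh, t, schedule, k_a), rng)
            b = _sample_onehot(categorical_posterior(b, bh, t, schedule, K_BOND), rng)
        else:
            x = mean
            v = categorical_posterior(v, vh, t, schedule, k_a)
            b = categorical_posterior(b, bh, t, schedule, K_BOND)

    coords = prior_unshift(x, priors)
    elements = [model.atom_vocab[k] for k in v.argmax(axis=-1)]
    atoms = [Atom(e, tuple(map(float, c))) for e, c in zip(elements, coords)]

    pairs = pair_index(n_atoms)
    b_cat = b.argmax(axis=-1)
    d_pair = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=-1)
    bonds: list[Bond] = []
    for k, (i, j) in enumerate(pairs):
        d = d_pair[k]
        if d < 0.8 or d > 2.0:
            continue
        order = BOND_CATEGORIES[b_cat[k]]
        if d <= 1.75:
            # clear covalent contact: always a bond; model sets the order
            if order in ("none", "aromatic"):
                order = "single"
        else:
            if order == "none":
                continue
            if order == "aromatic":
                order = "single"
        bonds.append(Bond(int(i), int(j), order))

    # valence capping: drop the longest bonds of over-bonded atoms
    def load(bond_list):
        tot = np.zeros(n_atoms)
        for bd in bond_list:
            val = _ORDER_VALENCE[bd.order]
            tot[bd.i] += val
            tot[bd.j] += val
        return tot

    def blen(bd: Bond) -> float:
        return float(np.linalg.norm(coords[bd.i] - coords[bd.j]))

    caps = np.array([_MAX_VALENCE.get(e, 4) for e in elements], dtype=float)
    totals = load(bonds)
    while True:
        over = np.where(totals > caps)[0]
        if over.size == 0:
            break
        worst = int(over[0])
        incident = [bd for bd in bonds if worst in (bd.i, bd.j)]
        drop = max(incident, key=blen)
        bonds.remove(drop)
        val = _ORDER_VALENCE[drop.order]
        totals[drop.i] -= val
        totals[drop.j] -= val

    return Molecule3D(atoms=atoms, bonds=bonds, name=f"sample-{seed}").validate()
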