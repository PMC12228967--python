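"""Priors, forward process, posteriors, losses, sampling and fine-tuning."""

import numpy as np
import pytest

from ligalign.diffusion import (
    BOND_CATEGORIES,
    K_BOND,
    DiffusionState,
    LossWeights,
    NoiseSchedule,
    NumpyDenoiser,
    build_training_arrays,
    categorical_posterior,
    estimate_priors,
    finetune,
    forward_categorical,
    forward_categorical_step,
    forward_position,
    isotropic_priors,
    loss_terms,
    pair_index,
    prior_shift,
    prior_unshift,
    sample_ligand,
)
from ligalign.pose_prep import DecomposedLigand, adaptive_decompose
from ligalign.selection import CurationBatch
from ligalign.synthetic import cavity_center, make_toy_ligand, make_toy_pocket

STRONG = NoiseSchedule.linear(100, 1e-3, 0.12)


@pytest.fixture(scope="module")
def decomposed(world):
    from ligalign.pose_prep import center_of_mass

    pocket = make_toy_pocket(world.config, 0)
    mol, _ = make_toy_ligand(world.config, 5, planted_partition=True)
    shift = cavity_center(pocket) - center_of_mass(mol)
    seated = mol.with_coords(mol.coords() + shift)
    return pocket, adaptive_decompose(seated, pocket)


class TestSchedule:
    def test_linear_default_monotone(self):
        sch = NoiseSchedule.linear()
        abars = [sch.alpha_bar(t) for t in range(sch.T + 1)]
        assert all(b > a for a, b in zip(abars[1:], abars))  # strictly decreasing
        assert abars[0] == 1.0

    def test_invalid_lambdas_rejected(self):
        with pytest.raises(ValueError):
            NoiseSchedule(np.array([0.0, 0.1]))
        with pytest.raises(ValueError):
            NoiseSchedule(np.array([1.0]))


class TestPriors:
    def test_single_atom_fragment_gets_regularized_sigma(self):
        from ligalign.moltypes import Atom, Molecule3D

        mol = Molecule3D(atoms=[Atom("C", (1, 2, 3)), Atom("C", (4, 5, 6))])
        dec = DecomposedLigand(arm_atom_sets=[{0}, {1}], scaffold_atom_set=set(), ligand=mol)
        priors = estimate_priors(dec)
        np.testing.assert_allclose(priors.mu[0], [1, 2, 3])
        np.testing.assert_allclose(priors.sigma[0], 1e-3 * np.eye(3))

    def test_tetrahedron_mean_is_centroid(self):
        from ligalign.moltypes import Atom, Molecule3D

        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        mol = Molecule3D(atoms=[Atom("C", tuple(v)) for v in verts])
        dec = DecomposedLigand(arm_atom_sets=[{0, 1, 2, 3}], scaffold_atom_set=set(), ligand=mol)
        np.testing.assert_allclose(estimate_priors(dec).mu[0], [0, 0, 0], atol=1e-12)

    def test_matches_numpy_mean_and_covariance(self, decomposed):
        _, dec = decomposed
        priors = estimate_priors(dec)
        coords = dec.ligand.coords()
        for k, frag in enumerate(dec.fragments):
            xyz = coords[sorted(frag)]
            np.testing.assert_allclose(priors.mu[k], xyz.mean(axis=0), atol=1e-9)
            np.testing.assert_allclose(
                priors.sigma[k], np.cov(xyz.T, ddof=0) + 1e-3 * np.eye(3), atol=1e-9
            )

    def test_shift_exactly_invertible(self, decomposed):
        _, dec = decomposed
        priors = estimate_priors(dec)
        x = dec.ligand.coords()
        np.testing.assert_allclose(prior_unshift(prior_shift(x, priors), priors), x, atol=1e-12)

    def test_atom_at_fragment_mean_shifts_to_origin(self, decomposed):
        _, dec = decomposed
        priors = estimate_priors(dec)
        x = priors.per_atom_mu()
        np.testing.assert_allclose(prior_shift(x, priors), 0.0, atol=1e-12)

    def test_fragmentwise_mean_of_shifted_positions_is_zero(self, decomposed):
        _, dec = decomposed
        priors = estimate_priors(dec)
        shifted = prior_shift(dec.ligand.coords(), priors)
        for k in range(priors.n_fragments):
            np.testing.assert_allclose(
                shifted[priors.assignment == k].mean(axis=0), 0.0, atol=1e-9
            )


class TestForwardPosition:
    @pytest.mark.parametrize("mode", ["ddpm", "plain"])
    def test_marginal_moments_match_monte_carlo(self, decomposed, mode):
        _, dec = decomposed
        priors = estimate_priors(dec)
        x0 = prior_shift(dec.ligand.coords(), priors)
        rng = np.random.default_rng(123)
        t = 40
        n_draws = 20000
        samples = np.stack(
            [forward_position(x0, t, STRONG, priors, mode, rng).sample for _ in range(n_draws)]
        )
        res = forward_position(x0, t, STRONG, priors, mode, rng)
        var_max = res.marginal_cov_scale * priors.per_atom_sigma()[:, 0, 0].max()
        se = np.sqrt(var_max / n_draws)
        assert np.abs(samples.mean(axis=0) - res.marginal_mean).max() < 4 * se

    def test_ddpm_terminal_limit_forgets_data(self, decomposed):
        _, dec = decomposed
        priors = estimate_priors(dec)
        x0 = prior_shift(dec.ligand.coords(), priors)
        res = forward_position(x0, STRONG.T, STRONG, priors, "ddpm", np.random.default_rng(0))
        assert np.abs(res.marginal_mean).max() < 0.2  # sqrt(alpha_bar_T) ~ 0.04
        assert res.marginal_cov_scale == pytest.approx(1.0, abs=5e-3)

    def test_unknown_mode_rejected(self, decomposed):
        _, dec = decomposed
        priors = estimate_priors(dec)
        with pytest.raises(ValueError, match="mode"):
            forward_position(np.zeros((2, 3)), 1, STRONG, priors, mode="bogus")


class TestForwardCategorical:
    def test_uniform_is_fixed_point(self):
        p = np.full(4, 0.25)
        for t in (1, 10, 50):
            np.testing.assert_allclose(forward_categorical(p, t, STRONG, 4), p, atol=1e-12)

    def test_step_composition_equals_closed_form(self):
        rng = np.random.default_rng(0)
        p0 = rng.dirichlet(np.ones(5))
        p = p0.copy()
        for t in range(1, 61):
            p = forward_categorical_step(p, t, STRONG, 5)
        np.testing.assert_allclose(p, forward_categorical(p0, 60, STRONG, 5), atol=1e-12)

    def test_terminal_limit_is_uniform(self):
        sch = NoiseSchedule.linear(1000, 1e-4, 0.05)
        p0 = np.array([1.0, 0.0, 0.0, 0.0])
        p = forward_categorical(p0, 1000, sch, 4)
        assert np.abs(p - 0.25).max() < 1e-6

    def test_too_few_categories_rejected(self):
        with pytest.raises(ValueError):
            forward_categorical(np.array([1.0]), 1, STRONG, 1)


class TestCategoricalPosterior:
    @pytest.mark.parametrize("k_cat", [2, 3, 4, 5])
    def test_equals_brute_force_bayes(self, k_cat):
        rng = np.random.default_rng(k_cat)
        for t in (1, 5, 40, 99):
            p0 = rng.dirichlet(np.ones(k_cat))
            observed = int(rng.integers(k_cat))
            p_t = np.eye(k_cat)[observed]
            post = categorical_posterior(p_t, p0, t, STRONG, k_cat)
            prior = STRONG.alpha_bar(t - 1) * p0 + (1 - STRONG.alpha_bar(t - 1)) / k_cat
            lik = np.array(
                [STRONG.alpha(t) * (k == observed) + (1 - STRONG.alpha(t)) / k_cat
                 for k in range(k_cat)]
            )
            brute = prior * lik
            brute /= brute.sum()
            np.testing.assert_allclose(post, brute, atol=1e-12)

    def test_t1_agreeing_onehots_concentrate(self):
        one = np.eye(3)[1]
        post = categorical_posterior(one, one, 1, STRONG, 3)
        assert post[1] > 0.99

    def test_uniform_inputs_give_uniform_posterior(self):
        u = np.full(5, 0.2)
        np.testing.assert_allclose(categorical_posterior(u, u, 10, STRONG, 5), u, atol=1e-12)


class TestLossTerms:
    def _state(self, rng, n=4):
        n_pairs = n * (n - 1) // 2
        v = rng.dirichlet(np.ones(3), size=n)
        b = rng.dirichlet(np.ones(K_BOND), size=n_pairs)
        return DiffusionState(positions=rng.normal(size=(n, 3)), atom_probs=v,
                              bond_probs=b, t=10)

    def test_perfect_prediction_has_zero_loss(self):
        rng = np.random.default_rng(1)
        state = self._state(rng)
        truth = (rng.normal(size=(4, 3)), rng.dirichlet(np.ones(3), size=4),
                 rng.dirichlet(np.ones(K_BOND), size=6))
        L_x, L_v, L_b, L_tot = loss_terms(state, truth, truth, 10, STRONG)
        assert L_x == L_v == L_b == L_tot == 0.0

    def test_unit_offset_positions(self):
        rng = np.random.default_rng(2)
        state = self._state(rng)
        x0 = rng.normal(size=(4, 3))
        v0 = rng.dirichlet(np.ones(3), size=4)
        b0 = rng.dirichlet(np.ones(K_BOND), size=6)
        offset = x0 + np.array([1.0, 0.0, 0.0])
        L_x, _, _, _ = loss_terms(state, (x0, v0, b0), (offset, v0, b0), 10, STRONG)
        assert L_x == pytest.approx(4.0)

    def test_kl_terms_nonnegative_and_zero_iff_equal(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            state = self._state(rng)
            v0 = rng.dirichlet(np.ones(3), size=4)
            b0 = rng.dirichlet(np.ones(K_BOND), size=6)
            vh = rng.dirichlet(np.ones(3), size=4)
            bh = rng.dirichlet(np.ones(K_BOND), size=6)
            x = rng.normal(size=(4, 3))
            _, L_v, L_b, _ = loss_terms(state, (x, v0, b0), (x, vh, bh), 10, STRONG)
            assert L_v >= 0.0 and L_b >= 0.0
            assert L_v > 0.0  # distinct random simplices differ a.s.

    def test_total_combines_weights(self):
        rng = np.random.default_rng(4)
        state = self._state(rng)
        truth = (rng.normal(size=(4, 3)), rng.dirichlet(np.ones(3), size=4),
                 rng.dirichlet(np.ones(K_BOND), size=6))
        pred = (truth[0] + 0.5, rng.dirichlet(np.ones(3), size=4),
                rng.dirichlet(np.ones(K_BOND), size=6))
        L_x, L_v, L_b, L_tot = loss_terms(state, truth, pred, 10, STRONG,
                                          LossWeights(gamma_v=2.0, gamma_b=3.0))
        assert L_tot == pytest.approx(L_x + 2.0 * L_v + 3.0 * L_b)


class TestTrainingArrays:
    def test_onehots_cover_bonds_and_atoms(self, decomposed):
        _, dec = decomposed
        priors = estimate_priors(dec)
        x0, v0, b0 = build_training_arrays(dec.ligand, priors, ("C", "N", "O", "F", "S"))
        n = dec.ligand.n_atoms
        assert x0.shape == (n, 3)
        assert v0.shape == (n, 5) and np.allclose(v0.sum(axis=1), 1.0)
        assert b0.shape == (n * (n - 1) // 2, K_BOND)
        assert int(b0[:, 1:].sum()) == len(dec.ligand.bonds)


def _tiny_batch(world):
    from ligalign.pipeline import pretraining_batch

    return pretraining_batch(world)


class TestFinetune:
    def test_zero_iterations_leaves_parameters_unchanged(self, world):
        model = NumpyDenoiser(schedule=STRONG)
        before = model.state_hash()
        out = finetune(model, _tiny_batch(world), lr=1e-3, iters=0, seed=0)
        assert out.state_hash() == before
        assert model.state_hash() == before

    def test_input_model_not_mutated(self, world):
        model = NumpyDenoiser(schedule=STRONG)
        before = model.state_hash()
        finetune(model, _tiny_batch(world), lr=1e-3, iters=50, seed=0)
        assert model.state_hash() == before

    def test_single_record_overfit_converges(self, world):
        batch = _tiny_batch(world)
        one = CurationBatch(records=batch.records[:1], batch_size_B=1)
        model = NumpyDenoiser(schedule=STRONG)
        # lr=0 run samples the same loss distribution without learning
        baseline = finetune(model, one, lr=0.0, iters=500, seed=1)
        trained = finetune(model, one, lr=1e-3, iters=2000, seed=0)
        untrained_loss = np.mean(baseline.last_trace)
        trained_tail = np.mean(trained.last_trace[-500:])
        assert trained_tail < 0.65 * untrained_loss

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            finetune(NumpyDenoiser(schedule=STRONG), CurationBatch(records=[], batch_size_B=1))

    def test_trace_written(self, world, tmp_path):
        path = tmp_path / "trace.csv"
        finetune(NumpyDenoiser(schedule=STRONG), _tiny_batch(world), lr=1e-3,
                 iters=20, seed=0, trace_path=path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration,loss" and len(lines) == 21


class TestSampleLigand:
    def test_deterministic_for_fixed_seed(self, world):
        pocket = make_toy_pocket(world.config, 0)
        model = NumpyDenoiser(schedule=STRONG)
        priors = isotropic_priors(cavity_center(pocket), 8, 0.8)
        m1 = sample_ligand(model, pocket, priors, 8, seed=7)
        m2 = sample_ligand(model, pocket, priors, 8, seed=7)
        assert m1.elements() == m2.elements()
        np.testing.assert_array_equal(m1.coords(), m2.coords())
        assert [(b.i, b.j, b.order) for b in m1.bonds] == [(b.i, b.j, b.order) for b in m2.bonds]

    @pytest.mark.parametrize("n_atoms", [4, 9, 14])
    def test_atom_count_respected(self, world, n_atoms):
        pocket = make_toy_pocket(world.config, 1)
        model = NumpyDenoiser(schedule=STRONG)
        priors = isotropic_priors(cavity_center(pocket), n_atoms, 0.8)
        assert sample_ligand(model, pocket, priors, n_atoms, seed=1).n_atoms == n_atoms

    def test_untrained_samples_near_prior_mean(self, world):
        pocket = make_toy_pocket(world.config, 2)
        model = NumpyDenoiser(schedule=STRONG)
        center = cavity_center(pocket)
        sigma = 0.8
        priors = isotropic_priors(center, 6, sigma)
        means = []
        for s in range(200):
            m = sample_ligand(model, pocket, priors, 6, seed=s)
            means.append(m.coords().mean(axis=0))
        grand = np.mean(means, axis=0)
        assert np.linalg.norm(grand - center) < 3 * sigma

    def test_save_load_round_trip(self, world, tmp_path):
        model = NumpyDenoiser(schedule=STRONG)
        model.params["theta_v"] += 0.3
        path = tmp_path / "model.json"
        model.save(path)
        back = NumpyDenoiser.load(path)
        assert back.state_hash() == model.state_hash()
        assert back.atom_vocab == model.atom_vocab
        np.testing.assert_allclose(back.schedule.lambdas, model.schedule.lambdas)
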