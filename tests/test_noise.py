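"""Forward corruption, CoM-free Gaussians and reverse-step posteriors."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import ctrldiff as cd
from ctrldiff.noise import one_step_sample, rng_for
from ctrldiff.schedule import transition_matrix
from conftest import random_rotation


class _NoiselessParams(cd.NoiseParams):
    """Schedule stub that keeps every channel perfectly clean."""

    def alpha_bar(self, t, channel):
        return np.ones_like(np.asarray(t, dtype=float))[()] if np.ndim(t) == 0 else np.ones(len(t))


class TestComGaussian:
    def test_column_sums_vanish(self):
        eps = cd.sample_com_gaussian(7, sigma=2.0, seed=0)
        assert np.abs(eps.sum(axis=0)).max() < 1e-6

    def test_single_atom_subspace_is_trivial(self):
        assert np.allclose(cd.sample_com_gaussian(1, sigma=5.0, seed=1), 0.0)

    def test_projected_variance_closed_form(self):
        # var per coordinate of the projected Gaussian is sigma^2 (1 - 1/n)
        n, sigma, draws = 5, 1.0, 100_000
        eps = cd.sample_com_gaussian(n, sigma, seed=2, size=draws)
        emp = eps.var()
        expected = sigma**2 * (1 - 1 / n)
        mc_se = expected * np.sqrt(2 / (draws * n * 3 - 1))
        assert abs(emp - expected) < 3 * mc_se


class TestForwardSample:
    def test_noiseless_schedule_returns_input_exactly(self, minimal_set):
        mol = minimal_set[3].copy()
        mol.coords = cd.center_com(mol.coords)
        state = cd.forward_sample(mol, 5, _NoiselessParams(T=10), seed=0)
        assert np.array_equal(state.graph.atom_types, mol.atom_types)
        assert np.array_equal(state.graph.charges, mol.charges)
        assert np.array_equal(state.graph.bonds, mol.bonds)
        assert np.abs(state.graph.coords - mol.coords).max() < 1e-12

    def test_output_structure_invariants(self, minimal_set, short_schedule):
        mol = minimal_set[3].copy()
        mol.coords = cd.center_com(mol.coords)
        state = cd.forward_sample(mol, 20, short_schedule, seed=3)
        g = state.graph
        assert np.array_equal(g.bonds, g.bonds.T)
        assert np.all(np.diag(g.bonds) == 0)
        assert np.abs(g.coords.mean(axis=0)).max() < 1e-6

    def test_terminal_types_follow_marginal(self, short_schedule):
        # aggregate ~10^4 atoms from repeated t=T corruptions of a 20-atom
        # all-carbon molecule: frequencies must match m_x
        n = 20
        mol = cd.Molecule3DGraph(
            cd.center_com(np.random.default_rng(0).normal(size=(n, 3))),
            np.full(n, 1),  # all carbon
            np.full(n, 1),
            np.zeros((n, n), dtype=int),
        )
        counts = np.zeros(5)
        reps = 500
        for s in range(reps):
            st = cd.forward_sample(mol, short_schedule.T, short_schedule, seed=s)
            counts += np.bincount(st.graph.atom_types, minlength=5)
        total = reps * n
        freqs = counts / total
        m = short_schedule.m_x
        se = np.sqrt(m * (1 - m) / total)
        assert np.all(np.abs(freqs - m) < 3 * se + 1e-12)

    def test_single_shot_matches_sequential_composition(self, short_schedule):
        # distributional identity: corrupting to t in one shot vs t one-step
        # corruptions; compare invariant statistics over 1000 draws
        mol = cd.generate_fixtures("minimal")[1]  # water, 3 atoms
        mol.coords = cd.center_com(mol.coords)
        t = 6
        single_d, seq_d, single_x, seq_x = [], [], [], []
        for s in range(1000):
            one = cd.forward_sample(mol, t, short_schedule, seed=s)
            state = cd.DiffusionState(mol.copy(), 0)
            for step in range(t):
                state = one_step_sample(state, short_schedule, seed=10_000 + s)
            single_d.append(np.linalg.norm(one.graph.coords[0] - one.graph.coords[1]))
            seq_d.append(np.linalg.norm(state.graph.coords[0] - state.graph.coords[1]))
            single_x.extend(one.graph.atom_types)
            seq_x.extend(state.graph.atom_types)
        assert ks_2samp(single_d, seq_d).pvalue > 0.01
        f1 = np.bincount(single_x, minlength=5) / len(single_x)
        f2 = np.bincount(seq_x, minlength=5) / len(seq_x)
        assert np.abs(f1 - f2).max() < 0.05

    def test_rotation_equivariance_of_corruption_distribution(self, short_schedule, rng):
        # rotating the clean molecule rotates the corrupted distribution:
        # rotation-invariant statistics (pairwise distances) must match
        mol = cd.generate_fixtures("minimal")[0]
        mol.coords = cd.center_com(mol.coords)
        Q = random_rotation(rng)
        rot = cd.Molecule3DGraph(mol.coords @ Q.T, mol.atom_types, mol.charges, mol.bonds)
        d_plain, d_rot = [], []
        for s in range(800):
            a = cd.forward_sample(mol, 15, short_schedule, seed=s).graph.coords
            b = cd.forward_sample(rot, 15, short_schedule, seed=5000 + s).graph.coords
            d_plain.append(np.linalg.norm(a[0] - a[1]))
            d_rot.append(np.linalg.norm(b[0] - b[1]))
        assert ks_2samp(d_plain, d_rot).pvalue > 0.01

    def test_rejects_uncentered_input(self, minimal_set, short_schedule):
        mol = minimal_set[0].copy()
        mol.coords = mol.coords + 5.0
        with pytest.raises(ValueError, match="CoM-free"):
            cd.forward_sample(mol, 3, short_schedule, seed=0)


def _posterior_oracle(x_t, pred, t, params, channel):
    """Brute-force Bayes enumeration over all clean categories."""
    m = params.marginal(channel)
    k = len(m)
    ab_t = params.alpha_bar(t, channel)
    ab_prev = params.alpha_bar(t - 1, channel)
    Q_step = transition_matrix(min(ab_t / ab_prev, 1.0), m)
    Q_prev = transition_matrix(float(ab_prev), m)
    out = np.zeros(k)
    for x0 in range(k):
        joint = np.array([Q_prev[x0, j] * Q_step[j, x_t] for j in range(k)])
        out += pred[x0] * joint / joint.sum()
    return out / out.sum()


class TestPosteriorCategorical:
    def test_matches_exhaustive_enumeration(self, short_schedule, rng):
        for t in (1, 5, 15, 29):
            for _ in range(10):
                pred = rng.dirichlet(np.ones(5))
                x_t = int(rng.integers(5))
                got = cd.posterior_categorical(
                    np.array([x_t]), pred[None, :], t, short_schedule, "x"
                )[0]
                want = _posterior_oracle(x_t, pred, t, short_schedule, "x")
                assert np.abs(got - want).max() < 1e-9

    def test_point_mass_with_noiseless_schedule(self):
        params = _NoiselessParams(T=10)
        pred = np.zeros((1, 5))
        pred[0, 2] = 1.0
        post = cd.posterior_categorical(np.array([2]), pred, 5, params, "x")
        assert np.allclose(post[0], pred[0])

    def test_output_normalized(self, short_schedule, rng):
        pred = rng.dirichlet(np.ones(5), size=20)
        x_t = rng.integers(5, size=20)
        post = cd.posterior_categorical(x_t, pred, 10, short_schedule, "x")
        assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-9

    def test_rejects_unnormalized_prediction(self, short_schedule):
        with pytest.raises(ValueError, match="normalized"):
            cd.posterior_categorical(np.array([0]), np.array([[0.5, 0.2, 0.1, 0.1, 0.0]]), 5, short_schedule)


def _ddpm_posterior_oracle(r_t, r0, t, params):
    """Independently coded textbook posterior using beta parameterization."""
    ab = lambda u: float(params.alpha_bar(u, "r"))
    abar_t, abar_prev = ab(t), ab(t - 1)
    alpha_t = abar_t / abar_prev
    beta_t = 1 - alpha_t
    coef0 = np.sqrt(abar_prev) * beta_t / (1 - abar_t)
    coeft = np.sqrt(alpha_t) * (1 - abar_prev) / (1 - abar_t)
    mean = coef0 * r0 + coeft * r_t
    var = (1 - abar_prev) / (1 - abar_t) * beta_t
    return mean - mean.mean(axis=0, keepdims=True), np.sqrt(var)


class TestPosteriorCoords:
    def test_matches_independent_implementation(self, short_schedule, rng):
        for t in (1, 7, 19, 30):
            r_t = cd.center_com(rng.normal(size=(4, 3)))
            r0 = cd.center_com(rng.normal(size=(4, 3)))
            mean, scale = cd.posterior_coords(r_t, r0, t, short_schedule)
            mean_o, scale_o = _ddpm_posterior_oracle(r_t, r0, t, short_schedule)
            assert np.abs(mean - mean_o).max() < 1e-10
            assert abs(scale - scale_o) < 1e-10

    def test_final_step_mean_approaches_prediction(self, rng):
        # noise-free limit: abar_0 is within 1e-5 of 1, so with a short
        # schedule (abar_1 well below 1) the r_t coefficient (1-abar_0)/(1-abar_1)
        # is ~1e-4 and the posterior mean collapses onto the prediction
        params = cd.NoiseParams(T=5)
        r0 = cd.center_com(rng.normal(size=(5, 3)))
        r_t = cd.center_com(rng.normal(size=(5, 3)))
        mean, _ = cd.posterior_coords(r_t, r0, 1, params)
        assert np.abs(mean - r0).max() < 1e-2

    def test_mean_is_com_free(self, short_schedule, rng):
        mean, _ = cd.posterior_coords(
            cd.center_com(rng.normal(size=(6, 3))),
            cd.center_com(rng.normal(size=(6, 3))),
            12,
            short_schedule,
        )
        assert np.abs(mean.sum(axis=0)).max() < 1e-6


class TestPrior:
    def test_coords_com_free_and_reproducible(self, short_schedule):
        a = cd.prior_sample(6, short_schedule, seed=9)
        b = cd.prior_sample(6, short_schedule, seed=9)
        assert np.abs(a.graph.coords.sum(axis=0)).max() < 1e-6
        assert np.array_equal(a.graph.bonds, b.graph.bonds)
        assert np.allclose(a.graph.coords, b.graph.coords)

    def test_bond_frequencies_match_marginal(self, short_schedule):
        counts = np.zeros(5)
        total = 0
        for s in range(300):
            g = cd.prior_sample(10, short_schedule, seed=s).graph
            iu, ju = np.triu_indices(10, 1)
            counts += np.bincount(g.bonds[iu, ju], minlength=5)
            total += len(iu)
        freqs = counts / total
        m = short_schedule.m_y
        se = np.sqrt(m * (1 - m) / total)
        assert np.all(np.abs(freqs - m) < 3 * se + 1e-12)

    def test_rotation_invariance_of_prior_density(self, short_schedule, rng):
        # the prior factorizes into an isotropic CoM-free Gaussian and
        # i.i.d. categorical draws; rotating a draw preserves its density
        state = cd.prior_sample(5, short_schedule, seed=4)
        Q = random_rotation(rng)
        R, RQ = state.graph.coords, state.graph.coords @ Q.T
        # isotropic Gaussian density depends only on the Frobenius norm
        assert abs((R**2).sum() - (RQ**2).sum()) < 1e-9
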