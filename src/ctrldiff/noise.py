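"""Forward corruption and reverse-step posteriors.

Coordinates receive isotropic Gaussian noise confined to the zero
centre-of-mass subspace (dimension 3(n-1)), which is what makes
translations unambiguous; the discrete channels are corrupted by the
marginal-mixing kernels from :mod:`ctrldiff.schedule`.  The reverse process
needs the Bayes posterior q(state_{t-1} | state_t, state_0) for each
channel, marginalized over the network's prediction of the clean state.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .molgraph import Molecule3DGraph
from .schedule import NoiseParams, transition_matrix

__all__ = [
    "DiffusionState",
    "rng_for",
    "sample_com_gaussian",
    "forward_sample",
    "posterior_categorical",
    "posterior_coords",
    "prior_sample",
]


@dataclasses.dataclass
class DiffusionState:
    """A molecule-shaped state of the diffusion chain at time index t."""

    graph: Molecule3DGraph
    t: int

    def __post_init__(self):
        com = np.abs(self.graph.coords.mean(axis=0)).max()
        if com > 1e-6:
            raise ValueError(f"state coordinates must be CoM-free (|CoM| = {com:.2e})")
        if self.t < 0:
            raise ValueError("t must be >= 0")


def rng_for(seed: int, *stream: int) -> np.random.Generator:
    """Counter-based fan-out: independent generator per (seed, stream...)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def sample_com_gaussian(n: int, sigma: float = 1.0, seed=0, size: int | None = None) -> np.ndarray:
    """Isotropic Gaussian on the CoM-free subspace of n-atom coordinates.

    An ambient N(0, sigma^2 I) draw projected so each column sums to zero;
    per-coordinate marginal variance is sigma^2 (1 - 1/n).  With `size`,
    returns a (size, n, 3) batch of independent draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = (n, 3) if size is None else (size, n, 3)
    eps = rng.normal(scale=1.0, size=shape) * sigma
    return eps - eps.mean(axis=-2, keepdims=True)


def _sample_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Sample one category per row of a (rows, k) probability array."""
    cdf = np.cumsum(probs, axis=-1)
    u = rng.random(size=probs.shape[:-1] + (1,))
    return (u > cdf[..., :-1]).sum(axis=-1).astype(np.int64)


def _corrupt_categorical(
    values: np.ndarray, alpha_bar_t: float, m: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    Q = transition_matrix(float(np.clip(alpha_bar_t, 0.0, 1.0)), m)
    return _sample_rows(rng, Q[values])


def forward_sample(g0: Molecule3DGraph, t: int, params: NoiseParams, seed: int) -> DiffusionState:
    """Draw G_t ~ q(G_t | G_0) in one shot using the closed-form marginals.

    Coordinates: N_CoM(sqrt(abar_r) R0, (1 - abar_r) I).  Each categorical
    channel uses its own schedule; bonds are sampled on the upper triangle
    and mirrored so the bond matrix stays symmetric with a "none" diagonal.
    """
    if not 1 <= t <= params.T:
        raise ValueError(f"t must lie in [1, {params.T}]")
    if np.abs(g0.coords.mean(axis=0)).max() > 1e-6:
        raise ValueError("input coordinates must be CoM-free")
    ab_r = params.alpha_bar(t, "r")
    coords = np.sqrt(ab_r) * g0.coords + sample_com_gaussian(
        g0.n_atoms, np.sqrt(1.0 - ab_r), rng_for(seed, t, 0)
    )
    types = _corrupt_categorical(
        g0.atom_types, params.alpha_bar(t, "x"), params.m_x, rng_for(seed, t, 1)
    )
    charges = _corrupt_categorical(
        g0.charges, params.alpha_bar(t, "c"), params.m_c, rng_for(seed, t, 2)
    )
    n = g0.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    upper = _corrupt_categorical(
        g0.bonds[iu, ju], params.alpha_bar(t, "y"), params.m_y, rng_for(seed, t, 3)
    )
    bonds = np.zeros((n, n), dtype=np.int64)
    bonds[iu, ju] = upper
    bonds[ju, iu] = upper
    graph = Molecule3DGraph(
        coords, types, charges, bonds, id=g0.id, vocab=g0.vocab
    )
    return DiffusionState(graph=graph, t=t)


def one_step_sample(state: DiffusionState, params: NoiseParams, seed: int) -> DiffusionState:
    """Single corruption step G_t -> G_{t+1} (used for composition checks)."""
    t_next = state.t + 1
    if t_next > params.T:
        raise ValueError("already at t = T")
    g = state.graph

    def step_alpha(channel):
        ab_now = params.alpha_bar(state.t, channel) if state.t > 0 else params.alpha_bar(0, channel)
        ab_next = params.alpha_bar(t_next, channel)
        return ab_next / max(ab_now, 1e-30)

    a_r = np.sqrt(min(step_alpha("r"), 1.0))
    coords = a_r * g.coords + sample_com_gaussian(
        g.n_atoms, np.sqrt(max(1.0 - a_r**2, 0.0)), rng_for(seed, t_next, 10)
    )
    types = _corrupt_categorical(g.atom_types, step_alpha("x"), params.m_x, rng_for(seed, t_next, 11))
    charges = _corrupt_categorical(g.charges, step_alpha("c"), params.m_c, rng_for(seed, t_next, 12))
    n = g.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    upper = _corrupt_categorical(g.bonds[iu, ju], step_alpha("y"), params.m_y, rng_for(seed, t_next, 13))
    bonds = np.zeros((n, n), dtype=np.int64)
    bonds[iu, ju] = upper
    bonds[ju, iu] = upper
    return DiffusionState(
        Molecule3DGraph(coords, types, charges, bonds, id=g.id, vocab=g.vocab), t_next
    )


def posterior_categorical(
    x_t: np.ndarray, pred_dist: np.ndarray, t: int, params: NoiseParams, channel: str = "x"
) -> np.ndarray:
    """p(x_{t-1} | x_t) marginalized over the predicted clean distribution.

    For each item with observed category x_t and predicted clean
    distribution p(x_0), computes

        sum_x0  q(x_{t-1} | x_t, x_0) p(x_0 = x)

    where q is the Bayes posterior of the marginal-mixing kernel family:
    q(x_{t-1} | x_t, x_0) ∝ Q_t[x_{t-1}, x_t] * Qbar_{t-1}[x_0, x_{t-1}].
    """
    if not 1 <= t <= params.T:
        raise ValueError(f"t must lie in [1, {params.T}]")
    x_t = np.asarray(x_t, dtype=np.int64)
    pred = np.asarray(pred_dist, dtype=np.float64)
    if np.abs(pred.sum(axis=-1) - 1.0).max() > 1e-6:
        raise ValueError("pred_dist rows must be normalized")
    m = params.marginal(channel)
    ab_t = params.alpha_bar(t, channel)
    ab_prev = params.alpha_bar(t - 1, channel)
    alpha_step = float(ab_t / max(ab_prev, 1e-30))
    Q_step = transition_matrix(min(alpha_step, 1.0), m)  # (k_prev? k x k) rows: from
    Q_bar_prev = transition_matrix(float(ab_prev), m)
    # lik[j] = Q_step[j, x_t]: probability x_t given x_{t-1}=j
    lik = Q_step[:, x_t].T  # (items, k)
    # prior_{x0}[j] = Q_bar_prev[x0, j]; unnormalized joint per x0 then marginalize
    # posterior[i, j] = sum_x0 pred[i, x0] * lik[i, j] * Qbar[x0, j] / norm(i, x0)
    # norm(i, x0) = sum_j lik[i, j] * Qbar[x0, j]
    k = len(m)
    joint = lik[:, None, :] * Q_bar_prev[None, :, :]  # (items, x0, j)
    norm = joint.sum(axis=-1, keepdims=True)
    cond = joint / np.maximum(norm, 1e-300)
    post = np.einsum("ik,ikj->ij", pred, cond)
    return post / post.sum(axis=-1, keepdims=True)


def posterior_coords(
    r_t: np.ndarray, r0_pred: np.ndarray, t: int, params: NoiseParams
) -> tuple[np.ndarray, float]:
    """Mean and scale of the reverse Gaussian step on the CoM-free subspace.

    Standard variance-preserving posterior:
        mu    = [sqrt(abar_{t-1}) beta_t r0 + sqrt(a_t^2)(1-abar_{t-1}) r_t] / (1-abar_t)
        sigma = sqrt( beta_t (1-abar_{t-1}) / (1-abar_t) )
    with a_t^2 = abar_t/abar_{t-1}, beta_t = 1 - a_t^2.  The mean is
    re-projected to the CoM-free subspace.
    """
    if not 1 <= t <= params.T:
        raise ValueError(f"t must lie in [1, {params.T}]")
    r_t = np.asarray(r_t, dtype=np.float64)
    r0 = np.asarray(r0_pred, dtype=np.float64)
    ab_t = float(params.alpha_bar(t, "r"))
    ab_prev = float(params.alpha_bar(t - 1, "r"))
    a_sq = ab_t / ab_prev
    beta = 1.0 - a_sq
    denom = 1.0 - ab_t
    mean = (np.sqrt(ab_prev) * beta * r0 + np.sqrt(a_sq) * (1.0 - ab_prev) * r_t) / denom
    mean = mean - mean.mean(axis=0, keepdims=True)
    scale = float(np.sqrt(max(beta * (1.0 - ab_prev) / denom, 0.0)))
    return mean, scale


def prior_sample(n: int, params: NoiseParams, seed: int) -> DiffusionState:
    """Draw the t = T prior: CoM-free Gaussian coordinates, marginal categories."""
    if n < 1:
        raise ValueError("n must be >= 1")
    coords = sample_com_gaussian(n, 1.0, rng_for(seed, 0, 100))
    rng = rng_for(seed, 0, 101)
    types = rng.choice(len(params.m_x), size=n, p=params.m_x)
    charges = rng_for(seed, 0, 102).choice(len(params.m_c), size=n, p=params.m_c)
    iu, ju = np.triu_indices(n, k=1)
    upper = rng_for(seed, 0, 103).choice(len(params.m_y), size=len(iu), p=params.m_y)
    bonds = np.zeros((n, n), dtype=np.int64)
    bonds[iu, ju] = upper
    bonds[ju, iu] = upper
    graph = Molecule3DGraph(coords, types.astype(np.int64), charges.astype(np.int64), bonds)
    return DiffusionState(graph=graph, t=params.T)
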