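"""Reverse diffusion sampling and batch generation.

Starting from the rotation-invariant prior at t = T (CoM-free Gaussian
coordinates, marginal categories), each step asks the denoiser for the
clean state, forms the per-channel Bayes posteriors and samples the next
state.  The final step (t = 1 -> 0) takes the posterior argmax for the
discrete channels and the posterior mean for coordinates, so the last
decision is reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .molgraph import Molecule3DGraph, write_sdf
from .network import DenoiserOutput, LayerConfig, denoiser_forward
from .noise import (
    DiffusionState,
    posterior_categorical,
    posterior_coords,
    prior_sample,
    rng_for,
    sample_com_gaussian,
)
from .schedule import NoiseParams

__all__ = ["SampleRun", "reverse_sample", "generate", "predictor_from_params"]


@dataclasses.dataclass
class SampleRun:
    """Configuration for a generation run."""

    n_molecules: int
    seed: int = 0
    atom_counts: np.ndarray | None = None  # histogram source; None -> fixed n
    fixed_n: int = 5
    condition: object = None

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


def predictor_from_params(params, config: LayerConfig, T: int):
    """Wrap raw parameters as a predict(state, t) -> DenoiserOutput callable."""

    def predict(state: DiffusionState, t: int) -> DenoiserOutput:
        return denoiser_forward(state, t, params, config, T)

    return predict


def _sample_categorical(rng, probs: np.ndarray) -> np.ndarray:
    cdf = np.cumsum(probs, axis=-1)
    u = rng.random(size=probs.shape[:-1] + (1,))
    return (u > cdf[..., :-1]).sum(axis=-1).astype(np.int64)


def reverse_sample(
    predict,
    n_atoms: int,
    params: NoiseParams,
    seed: int = 0,
    trace: list | None = None,
) -> Molecule3DGraph:
    """Run the reverse chain from the prior down to a clean molecule.

    `predict(state, t) -> DenoiserOutput` is any denoiser: raw parameters
    via :func:`predictor_from_params`, a control-block closure, or a
    plug-in oracle in tests.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    state = prior_sample(n_atoms, params, seed)
    iu, ju = np.triu_indices(n_atoms, k=1)
    for t in range(params.T, 0, -1):
        out = predict(state, t)
        g = state.graph
        post_x = posterior_categorical(g.atom_types, out.x_dist, t, params, "x")
        post_c = posterior_categorical(g.charges, out.c_dist, t, params, "c")
        if len(iu):
            post_y = posterior_categorical(g.bonds[iu, ju], out.y_dist, t, params, "y")
        else:
            post_y = np.zeros((0, len(params.m_y)))
        mean, scale = posterior_coords(g.coords, out.r0_pred, t, params)
        if t > 1:
            coords = mean + sample_com_gaussian(n_atoms, scale, rng_for(seed, t, 20))
            types = _sample_categorical(rng_for(seed, t, 21), post_x)
            charges = _sample_categorical(rng_for(seed, t, 22), post_c)
            upper = _sample_categorical(rng_for(seed, t, 23), post_y) if len(iu) else np.zeros(0, dtype=np.int64)
        else:
            coords = mean
            types = post_x.argmax(axis=-1)
            charges = post_c.argmax(axis=-1)
            upper = post_y.argmax(axis=-1) if len(iu) else np.zeros(0, dtype=np.int64)
        bonds = np.zeros((n_atoms, n_atoms), dtype=np.int64)
        if len(iu):
            bonds[iu, ju] = upper
            bonds[ju, iu] = upper
        graph = Molecule3DGraph(coords, types, charges, bonds, id=g.id, vocab=g.vocab)
        state = DiffusionState(graph=graph, t=t - 1)
        if trace is not None:
            trace.append(state)
    return state.graph


def sample_atom_counts(run: SampleRun, rng) -> np.ndarray:
    if run.atom_counts is None:
        return np.full(run.n_molecules, run.fixed_n, dtype=np.int64)
    counts = np.asarray(run.atom_counts, dtype=np.int64)
    return rng.choice(counts, size=run.n_molecules, replace=True)


def generate(
    run: SampleRun,
    predict,
    params: NoiseParams,
    out_path=None,
    metadata: dict | None = None,
) -> list[Molecule3DGraph]:
    """Generate a batch of molecules, optionally writing them as SDF.

    Atom counts follow the empirical histogram in `run.atom_counts`
    (typically the training-set sizes); metadata (seed, schedule, model
    hash) is written into the SDF property block.
    """
    rng = rng_for(run.seed, 999)
    sizes = sample_atom_counts(run, rng)
    mols = []
    for k, n in enumerate(sizes):
        mol = reverse_sample(predict, int(n), params, seed=int(rng_for(run.seed, k).integers(2**31)))
        mol.id = f"gen{k}"
        mols.append(mol)
    if out_path is not None:
        props = {"seed": run.seed, "schedule": str(params.to_dict())}
        props.update(metadata or {})
        write_sdf(mols, out_path, properties=props)
    return mols
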