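"""Conditioning via a frozen base network, a trainable copy and zero layers.

The conditioned prediction is

    y_c = F(x; theta) + Z( F(x + Z(c; theta_z1); theta_c); theta_z2 )

where F is the denoiser, theta the frozen unconditional parameters,
theta_c a trainable copy, and Z zero-initialized linear layers.  Because
both zero layers start at exactly zero, the conditioned model is
bit-identical to the unconditional one at construction, and conditioning
strength grows only as training moves the zero layers off zero.

The condition c is a reference 3D molecular graph (a lead compound): its
types/charges and centred coordinates are embedded with the frozen input
embedding, zero-padded with a mask to the sample's atom count.  Additive
combination on the distribution heads happens in logit space (then
softmax), and on the coordinate head through a zero-initialized scalar
gate, which keeps the equivariance contract intact.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autograd import Tensor
from .molgraph import DEFAULT_VOCAB, Molecule3DGraph
from .network import (
    LayerConfig,
    T_EMBED_DIM,
    DenoiserOutput,
    _normalize_logits,
    clone_params,
    forward_tensors,
    graph_to_arrays,
)

__all__ = ["ControlState", "ConditionTensor", "zero_layer", "build_control_model",
           "conditioned_forward", "encode_condition"]


@dataclasses.dataclass
class ConditionTensor:
    """Reference structure embedded for conditioning.

    node_feats (n, width) frozen-embedding features, zero rows where padded;
    coords (n, 3) CoM-free, zero rows where padded; mask (n,) 1 for real
    condition atoms.
    """

    node_feats: np.ndarray
    coords: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        real = self.mask.astype(bool)
        if real.any():
            com = np.abs(self.coords[real].mean(axis=0)).max()
            if com > 1e-6:
                raise ValueError("condition coordinates must be CoM-free")


@dataclasses.dataclass
class ControlState:
    """Frozen base, trainable copy, and the two zero layers.

    theta_frozen is never touched by training; at construction
    theta_trainable equals theta_frozen element-wise and every zero-layer
    parameter is exactly zero.
    """

    theta_frozen: dict[str, Tensor]
    theta_trainable: dict[str, Tensor]
    theta_z1: dict[str, Tensor]
    theta_z2: dict[str, Tensor]
    config: LayerConfig

    def trainable_parameters(self) -> dict[str, Tensor]:
        out = {f"ctrl.{k}": v for k, v in self.theta_trainable.items()}
        out.update({f"z1.{k}": v for k, v in self.theta_z1.items()})
        out.update({f"z2.{k}": v for k, v in self.theta_z2.items()})
        return out


def zero_layer(x, theta_z: dict, group: str):
    """Per-channel-group 1x1 linear map, zero at initialization.

    Scalar channel groups get a square weight matrix + bias; the coordinate
    group gets a single scalar gate (g * R), the only linear map on vectors
    that commutes with rotations.
    """
    if group == "coords":
        return Tensor._lift(x) * theta_z["coords.g"]
    W = theta_z[group + ".W"]
    b = theta_z[group + ".b"]
    return Tensor._lift(x) @ W + b


def build_control_model(
    base_params: dict[str, Tensor], config: LayerConfig, vocab=DEFAULT_VOCAB
) -> ControlState:
    """Freeze the base network and attach a trainable copy with zero layers."""
    frozen = clone_params(base_params, requires_grad=False)
    trainable = clone_params(base_params, requires_grad=True)
    d = config.width
    kx, kc, ky = vocab.n_atom_types, vocab.n_charges, vocab.n_bonds
    z1 = {
        "node.W": Tensor(np.zeros((d, d)), requires_grad=True),
        "node.b": Tensor(np.zeros(d), requires_grad=True),
        "coords.g": Tensor(np.zeros(1), requires_grad=True),
    }
    z2 = {
        "x.W": Tensor(np.zeros((kx, kx)), requires_grad=True),
        "x.b": Tensor(np.zeros(kx), requires_grad=True),
        "c.W": Tensor(np.zeros((kc, kc)), requires_grad=True),
        "c.b": Tensor(np.zeros(kc), requires_grad=True),
        "y.W": Tensor(np.zeros((ky, ky)), requires_grad=True),
        "y.b": Tensor(np.zeros(ky), requires_grad=True),
        "coords.g": Tensor(np.zeros(1), requires_grad=True),
    }
    return ControlState(frozen, trainable, z1, z2, config)


def encode_condition(
    ref: Molecule3DGraph, target_n: int, base_params: dict[str, Tensor], config: LayerConfig
) -> ConditionTensor:
    """Embed a reference molecule with the frozen input embedding.

    Atom types and charges pass through the frozen node embedding (with the
    t = 0 time features); coordinates are centred.  If the reference has
    fewer atoms than the target, rows are zero-padded and masked; if more,
    the first target_n atoms are used.
    """
    if ref.n_atoms < 1:
        raise ValueError("empty reference molecule")
    arrays = graph_to_arrays(ref)
    n_ref = ref.n_atoms
    t_emb = np.zeros((n_ref, T_EMBED_DIM))
    t_emb[:] = _cond_time_features()
    node_in = np.concatenate([arrays["x"], arrays["c"], t_emb], axis=-1)
    feats = node_in @ base_params["embed.node.W"].data + base_params["embed.node.b"].data
    coords = arrays["R"] - arrays["R"].mean(axis=0, keepdims=True)
    if n_ref >= target_n:
        feats, coords = feats[:target_n], coords[:target_n]
        coords = coords - coords.mean(axis=0, keepdims=True)
        mask = np.ones(target_n)
    else:
        pad = target_n - n_ref
        feats = np.vstack([feats, np.zeros((pad, feats.shape[1]))])
        coords = np.vstack([coords, np.zeros((pad, 3))])
        mask = np.concatenate([np.ones(n_ref), np.zeros(pad)])
    return ConditionTensor(node_feats=feats, coords=coords, mask=mask)


def _cond_time_features() -> np.ndarray:
    from .network import _time_embedding

    return _time_embedding(0, 1)


def conditioned_forward_tensors(
    graph_arrays: dict, t: int, T: int, cond: ConditionTensor, cs: ControlState
) -> dict[str, Tensor]:
    """Logit-level conditioned forward pass (autodiff-capable)."""
    base = forward_tensors(graph_arrays, t, T, cs.theta_frozen, cs.config)
    mask = cond.mask[:, None]
    cond_feats = zero_layer(Tensor(cond.node_feats * mask), cs.theta_z1, "node")
    cond_coords = zero_layer(Tensor(cond.coords * mask), cs.theta_z1, "coords")
    ctrl = forward_tensors(
        graph_arrays,
        t,
        T,
        cs.theta_trainable,
        cs.config,
        extra_node=cond_feats,
        extra_coords=cond_coords,
    )
    return {
        # both addends are CoM-free (base/ctrl r0 are projected; the gate is a
        # scalar), so no re-projection: this keeps the construction-time
        # output bit-identical to the frozen model
        "r0": base["r0"] + zero_layer(ctrl["r0"], cs.theta_z2, "coords"),
        "x_logits": base["x_logits"] + zero_layer(ctrl["x_logits"], cs.theta_z2, "x"),
        "c_logits": base["c_logits"] + zero_layer(ctrl["c_logits"], cs.theta_z2, "c"),
        "y_logits": base["y_logits"] + zero_layer(ctrl["y_logits"], cs.theta_z2, "y"),
    }


def conditioned_forward(
    state, t: int, cond: ConditionTensor, cs: ControlState, T: int
) -> DenoiserOutput:
    """Conditioned prediction of the clean molecule.

    At construction (both zero layers at zero) the output equals the frozen
    model's output exactly for any condition.
    """
    graph = state.graph if hasattr(state, "graph") else state
    arrays = graph_to_arrays(graph)
    if cond.node_feats.shape[0] != graph.n_atoms:
        raise ValueError(
            f"condition has {cond.node_feats.shape[0]} rows, sample has {graph.n_atoms} atoms"
        )
    out = conditioned_forward_tensors(arrays, t, T, cond, cs)
    return _normalize_logits(out)
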