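"""SE(3)-equivariant graph-transformer denoiser.

Scalar (node/edge) features flow through standard attention + feed-forward
blocks; coordinates are only ever moved by three equivariant primitives:

* ``regnn_update``  — each atom moves along weighted difference vectors to
  the other atoms, with scalar weights computed from rotation-invariant
  features (squared distances, squared norms, cosines);
* ``pos_mlp``       — a per-atom radial rescaling whose learnable map sees
  only coordinate norms;
* ``e3_norm``       — a learnable global rescaling by the mean coordinate
  norm.

All three commute with rotations, and every coordinate tensor lives in the
zero centre-of-mass frame (re-projected after each update), which is what
makes the squared-norm and cosine features well defined and the whole map
translation-equivariant.  Because attention weights and all learnable maps
on the scalar path consume only invariants, the predicted categorical
distributions are exactly rotation/translation invariant while the
predicted clean coordinates are equivariant.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from ._autograd import Tensor, concat, log_softmax
from .molgraph import DEFAULT_VOCAB, Vocabulary

__all__ = [
    "LayerConfig",
    "DenoiserOutput",
    "init_params",
    "parameter_count",
    "com_projection",
    "e3_norm",
    "pos_mlp",
    "regnn_update",
    "transformer_layer",
    "denoiser_forward",
    "save_checkpoint",
    "load_checkpoint",
]

T_EMBED_DIM = 8
_NORM_GUARD = 1e-8  # cosine feature guard for near-zero coordinate norms


@dataclasses.dataclass(frozen=True)
class LayerConfig:
    """Architecture hyperparameters.

    width       node feature width
    n_layers    transformer blocks
    n_heads     attention heads (must divide width)
    eps         the ∂ guard added to norms before division
    edge_width  edge feature width (default width // 2)
    msg_width   hidden width of the message/radial MLPs (default width // 2)
    """

    width: int = 64
    n_layers: int = 2
    n_heads: int = 4
    eps: float = 1.0
    edge_width: int | None = None
    msg_width: int | None = None

    def __post_init__(self):
        if min(self.width, self.n_layers, self.n_heads) < 1:
            raise ValueError("width, n_layers and n_heads must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.width % self.n_heads:
            raise ValueError("n_heads must divide width")

    @property
    def de(self) -> int:
        return self.edge_width or self.width // 2

    @property
    def dm(self) -> int:
        return self.msg_width or self.width // 2

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "n_layers": self.n_layers,
            "n_heads": self.n_heads,
            "eps": self.eps,
            "edge_width": self.de,
            "msg_width": self.dm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayerConfig":
        return cls(
            width=int(d["width"]),
            n_layers=int(d["n_layers"]),
            n_heads=int(d["n_heads"]),
            eps=float(d["eps"]),
            edge_width=int(d["edge_width"]),
            msg_width=int(d["msg_width"]),
        )


@dataclasses.dataclass
class DenoiserOutput:
    """Network prediction of the clean molecule.

    r0_pred (n, 3) CoM-free coordinates; x_dist (n, k_x), c_dist (n, k_c)
    per-atom distributions; y_dist (n_pairs, k_y) per-edge distributions on
    the upper triangle i < j (mirrored implicitly by symmetry).
    """

    r0_pred: np.ndarray
    x_dist: np.ndarray
    c_dist: np.ndarray
    y_dist: np.ndarray

    def __post_init__(self):
        for name in ("x_dist", "c_dist", "y_dist"):
            d = getattr(self, name)
            if d.size and np.abs(d.sum(axis=-1) - 1.0).max() > 1e-6:
                raise ValueError(f"{name} rows must be normalized")
        if np.abs(self.r0_pred.mean(axis=0)).max() > 1e-5:
            raise ValueError("r0_pred must be CoM-free")


# ---------------------------------------------------------------------------
# parameter construction
# ---------------------------------------------------------------------------

def _param_shapes(config: LayerConfig, vocab: Vocabulary) -> dict[str, tuple]:
    d, de, dm = config.width, config.de, config.dm
    kx, kc, ky = vocab.n_atom_types, vocab.n_charges, vocab.n_bonds
    f_node = kx + kc + T_EMBED_DIM
    f_edge = ky + 1  # bond one-hot + squared distance
    shapes: dict[str, tuple] = {
        "embed.node.W": (f_node, d),
        "embed.node.b": (d,),
        "embed.edge.W": (f_edge, de),
        "embed.edge.b": (de,),
    }
    for i in range(config.n_layers):
        p = f"layer{i}."
        shapes.update(
            {
                p + "attn.Wq": (d, d),
                p + "attn.Wk": (d, d),
                p + "attn.Wv": (d, d),
                p + "attn.Wo": (d, d),
                p + "attn.bo": (d,),
                p + "attn.Wbias": (de, config.n_heads),
                p + "ln1.g": (d,),
                p + "ln1.b": (d,),
                p + "ffn.W1": (d, 2 * d),
                p + "ffn.b1": (2 * d,),
                p + "ffn.W2": (2 * d, d),
                p + "ffn.b2": (d,),
                p + "ln2.g": (d,),
                p + "ln2.b": (d,),
                p + "effn.W1": (de + 2 * d, 2 * de),
                p + "effn.b1": (2 * de,),
                p + "effn.W2": (2 * de, de),
                p + "effn.b2": (de,),
                p + "eln.g": (de,),
                p + "eln.b": (de,),
                p + "regnn.W1": (2 * d + 4 + de, dm),
                p + "regnn.b1": (dm,),
                p + "regnn.W2": (dm, 1),
                p + "regnn.b2": (1,),
                p + "posmlp.W1": (1, dm),
                p + "posmlp.b1": (dm,),
                p + "posmlp.W2": (dm, 1),
                p + "posmlp.b2": (1,),
                p + "e3norm.gamma": (1,),
            }
        )
    shapes.update(
        {
            "head.x.W": (d, kx),
            "head.x.b": (kx,),
            "head.c.W": (d, kc),
            "head.c.b": (kc,),
            "head.y.W": (de, ky),
            "head.y.b": (ky,),
        }
    )
    return shapes


def parameter_count(config: LayerConfig, vocab: Vocabulary = DEFAULT_VOCAB) -> int:
    """Total parameter count as a pure function of config + vocabulary."""
    return sum(int(np.prod(s)) for s in _param_shapes(config, vocab).values())


def init_params(
    config: LayerConfig, vocab: Vocabulary = DEFAULT_VOCAB, seed: int = 0
) -> dict[str, Tensor]:
    """Glorot-initialized parameter dictionary; norm gains start at 1."""
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}
    for name, shape in _param_shapes(config, vocab).items():
        if name.endswith((".b", ".b1", ".b2", ".bo", "ln1.b", "ln2.b", "eln.b")):
            data = np.zeros(shape)
        elif name.endswith((".g", "gamma")):
            data = np.ones(shape)
        else:
            fan_in = shape[0] if len(shape) > 1 else shape[0]
            fan_out = shape[-1]
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            data = rng.normal(scale=scale, size=shape)
        params[name] = Tensor(data, requires_grad=True)
    return params


def clone_params(params: dict[str, Tensor], requires_grad: bool = True) -> dict[str, Tensor]:
    return {k: Tensor(v.data.copy(), requires_grad=requires_grad) for k, v in params.items()}


# ---------------------------------------------------------------------------
# equivariant coordinate primitives (Tensor core + numpy wrappers)
# ---------------------------------------------------------------------------

def _project_com(R: Tensor) -> Tensor:
    return R - R.mean(axis=0, keepdims=True)


def _norms(R: Tensor) -> Tensor:
    return ((R**2).sum(axis=-1, keepdims=True) + 1e-12).sqrt()


def com_projection(R: np.ndarray) -> np.ndarray:
    """Project coordinates onto the zero centre-of-mass subspace."""
    R = np.asarray(R, dtype=np.float64)
    return R - R.mean(axis=0, keepdims=True)


def e3_norm(R, gamma: float = 1.0, eps: float = 1.0):
    """Equivariant normalization: gamma * R / (mean_norm + eps)."""
    if isinstance(R, Tensor) or isinstance(gamma, Tensor):
        Rt = R if isinstance(R, Tensor) else Tensor(R)
        nbar = _norms(Rt).mean()
        return Rt * (gamma * (1.0 / (nbar + eps)))
    R = np.asarray(R, dtype=np.float64)
    nbar = np.sqrt((R**2).sum(axis=-1) + 1e-12).mean()
    return gamma * R / (nbar + eps)


def pos_mlp(R: np.ndarray, mlp, eps: float = 1.0) -> np.ndarray:
    """Radial feed-forward: Pi_CoM( mlp(|r_i|) * r_i / (|r_i| + eps) ).

    `mlp` maps an (n, 1) array of norms to an (n, 1) array of scalars; it
    sees only norms, so the whole map is rotation-equivariant.
    """
    R = np.asarray(R, dtype=np.float64)
    norms = np.sqrt((R**2).sum(axis=-1, keepdims=True) + 1e-12)
    scale = np.asarray(mlp(norms), dtype=np.float64).reshape(-1, 1)
    return com_projection(scale * R / (norms + eps))


def regnn_update(R: np.ndarray, X: np.ndarray, Y: np.ndarray, phi) -> np.ndarray:
    """Relaxed-EGNN coordinate update with a user message function.

    phi(X_i, X_j, delta_ij, Y_ij) -> scalar weight, where delta_ij is the
    invariant feature vector (|r_i - r_j|^2, |r_i|^2, |r_j|^2, cos(r_i, r_j)).
    Each atom moves by sum_j phi(..) (r_j - r_i); output is re-projected to
    the CoM-free subspace.
    """
    R = np.asarray(R, dtype=np.float64)
    n = len(R)
    out = R.copy()
    norms = np.sqrt((R**2).sum(axis=-1))
    for i in range(n):
        delta = np.zeros(3)
        for j in range(n):
            if i == j:
                continue
            diff = R[j] - R[i]
            if norms[i] < _NORM_GUARD or norms[j] < _NORM_GUARD:
                cos_ij = 0.0
            else:
                cos_ij = float(R[i] @ R[j] / (norms[i] * norms[j]))
            feats = np.array([diff @ diff, norms[i] ** 2, norms[j] ** 2, cos_ij])
            delta += float(phi(X[i], X[j], feats, Y[i, j])) * diff
        out[i] = R[i] + delta
    return com_projection(out)


# ---------------------------------------------------------------------------
# network forward (autodiff path)
# ---------------------------------------------------------------------------

def _layer_norm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / (var + 1e-8).sqrt() * g + b


def _linear(x: Tensor, params: dict, name: str) -> Tensor:
    return x @ params[name + ".W"] + params[name + ".b"]


def _mlp2(x: Tensor, params: dict, name: str, act: str = "silu") -> Tensor:
    h = x @ params[name + ".W1"] + params[name + ".b1"]
    h = h.silu() if act == "silu" else h.tanh()
    return h @ params[name + ".W2"] + params[name + ".b2"]


def _pair_invariants(R: Tensor) -> Tensor:
    """(n, n, 4) rotation-invariant pair features of CoM-free coordinates."""
    n = R.shape[0]
    sq = (R**2).sum(axis=-1)  # (n,)
    diff2 = (
        sq.reshape(n, 1) + sq.reshape(1, n) - 2.0 * (R @ R.transpose(1, 0))
    )  # |r_i - r_j|^2
    norms = (sq + 1e-12).sqrt()
    denom = (norms.reshape(n, 1) + _NORM_GUARD) * (norms.reshape(1, n) + _NORM_GUARD)
    cos = (R @ R.transpose(1, 0)) / denom
    return concat(
        [
            diff2.reshape(n, n, 1),
            (sq.reshape(n, 1) * Tensor(np.ones((1, n)))).reshape(n, n, 1),
            (Tensor(np.ones((n, 1))) * sq.reshape(1, n)).reshape(n, n, 1),
            cos.reshape(n, n, 1),
        ],
        axis=-1,
    )


def _time_embedding(t: int, T: int) -> np.ndarray:
    frac = t / T
    freqs = 2.0 ** np.arange(T_EMBED_DIM // 2)
    return np.concatenate(
        [np.sin(2 * np.pi * freqs * frac), np.cos(2 * np.pi * freqs * frac)]
    )


def _attention(h: Tensor, e: Tensor, params: dict, prefix: str, config: LayerConfig) -> Tensor:
    n, d = h.shape
    H = config.n_heads
    dh = d // H
    q = (h @ params[prefix + "attn.Wq"]).reshape(n, H, dh).transpose(1, 0, 2)
    k = (h @ params[prefix + "attn.Wk"]).reshape(n, H, dh).transpose(1, 0, 2)
    v = (h @ params[prefix + "attn.Wv"]).reshape(n, H, dh).transpose(1, 0, 2)
    scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))  # (H, n, n)
    bias = (e @ params[prefix + "attn.Wbias"]).transpose(2, 0, 1)
    attn = log_softmax(scores + bias, axis=-1).exp()
    out = (attn @ v).transpose(1, 0, 2).reshape(n, d)
    return out @ params[prefix + "attn.Wo"] + params[prefix + "attn.bo"]


def _coordinate_update(
    R: Tensor, h: Tensor, e: Tensor, params: dict, prefix: str, config: LayerConfig
) -> Tensor:
    """rEGNN move + radial MLP inside one residual, then CoM projection.

    With the message and radial output weights at zero the update is zero,
    so the coordinate path can pass through unchanged.
    """
    n, d = h.shape
    inv = _pair_invariants(R)  # (n, n, 4)
    hi = (h.reshape(n, 1, d) * Tensor(np.ones((1, n, 1)))).reshape(n, n, d)
    hj = (h.reshape(1, n, d) * Tensor(np.ones((n, 1, 1)))).reshape(n, n, d)
    msg_in = concat([hi, hj, inv, e], axis=-1)
    phi = _mlp2(msg_in, params, prefix + "regnn", act="silu").tanh()  # (n, n, 1)
    mask = Tensor(1.0 - np.eye(n)[..., None])
    diff = R.reshape(1, n, 3) - R.reshape(n, 1, 3)  # diff[i, j] = r_j - r_i
    # normalized aggregation (mean over neighbours) keeps the per-layer
    # coordinate change bounded so stacked layers cannot blow up the scale
    regnn_delta = (phi * mask * diff).sum(axis=1) * (1.0 / max(n - 1, 1))

    Rn = e3_norm(R, gamma=params[prefix + "e3norm.gamma"], eps=config.eps)
    norms = _norms(Rn)
    radial = _mlp2(norms, params, prefix + "posmlp", act="silu")  # (n, 1)
    pos_delta = radial * Rn / (norms + config.eps)

    return _project_com(R + regnn_delta + pos_delta)


def transformer_layer(
    h: Tensor, e: Tensor, R: Tensor, params: dict, prefix: str, config: LayerConfig
) -> tuple[Tensor, Tensor, Tensor]:
    """One block: attention, node FF, edge FF, equivariant coordinate update."""
    n, d = h.shape
    h = _layer_norm(h + _attention(h, e, params, prefix, config), params[prefix + "ln1.g"], params[prefix + "ln1.b"])
    h = _layer_norm(h + _mlp2(h, params, prefix + "ffn"), params[prefix + "ln2.g"], params[prefix + "ln2.b"])
    hi = (h.reshape(n, 1, d) * Tensor(np.ones((1, n, 1)))).reshape(n, n, d)
    hj = (h.reshape(1, n, d) * Tensor(np.ones((n, 1, 1)))).reshape(n, n, d)
    e = _layer_norm(
        e + _mlp2(concat([e, hi, hj], axis=-1), params, prefix + "effn"),
        params[prefix + "eln.g"],
        params[prefix + "eln.b"],
    )
    R = _coordinate_update(R, h, e, params, prefix, config)
    return h, e, R


def _embed_inputs(
    x_onehot: np.ndarray,
    c_onehot: np.ndarray,
    y_onehot: np.ndarray,
    R: np.ndarray,
    t: int,
    T: int,
    params: dict,
) -> tuple[Tensor, Tensor, Tensor]:
    n = len(x_onehot)
    t_emb = np.broadcast_to(_time_embedding(t, T), (n, T_EMBED_DIM))
    node_in = Tensor(np.concatenate([x_onehot, c_onehot, t_emb], axis=-1))
    Rt = Tensor(np.asarray(R, dtype=np.float64))
    d2 = ((R[:, None, :] - R[None, :, :]) ** 2).sum(axis=-1, keepdims=True)
    edge_in = Tensor(np.concatenate([y_onehot, d2], axis=-1))
    h = _linear(node_in, params, "embed.node")
    e = _linear(edge_in, params, "embed.edge")
    return h, e, Rt


def forward_tensors(
    graph_arrays: dict,
    t: int,
    T: int,
    params: dict[str, Tensor],
    config: LayerConfig,
    extra_node: Tensor | None = None,
    extra_coords: Tensor | None = None,
) -> dict[str, Tensor]:
    """Autodiff forward pass returning logits and predicted coordinates.

    graph_arrays holds one-hot numpy arrays ``x`` (n,k_x), ``c`` (n,k_c),
    ``y`` (n,n,k_y) and CoM-free coordinates ``R`` (n,3).  `extra_node` /
    `extra_coords` are additive conditioning inputs (the control branch's
    first zero layer output).
    """
    h, e, R = _embed_inputs(
        graph_arrays["x"], graph_arrays["c"], graph_arrays["y"], graph_arrays["R"], t, T, params
    )
    if extra_node is not None:
        h = h + extra_node
    if extra_coords is not None:
        R = _project_com(R + extra_coords)
    for i in range(config.n_layers):
        h, e, R = transformer_layer(h, e, R, params, f"layer{i}.", config)
    n = h.shape[0]
    e_sym = e + e.transpose(1, 0, 2)
    iu, ju = np.triu_indices(n, k=1)
    return {
        "r0": _project_com(R),
        "x_logits": _linear(h, params, "head.x"),
        "c_logits": _linear(h, params, "head.c"),
        "y_logits": _linear(e_sym[iu, ju], params, "head.y"),
    }


def graph_to_arrays(graph, vocab: Vocabulary | None = None) -> dict:
    """One-hot encode a Molecule3DGraph for the network."""
    vocab = vocab or graph.vocab
    n = graph.n_atoms
    x = np.eye(vocab.n_atom_types)[graph.atom_types]
    c = np.eye(vocab.n_charges)[graph.charges]
    y = np.eye(vocab.n_bonds)[graph.bonds]
    return {"x": x, "c": c, "y": y, "R": np.asarray(graph.coords, dtype=np.float64)}


def _normalize_logits(out: dict[str, Tensor]) -> DenoiserOutput:
    def dist(t: Tensor) -> np.ndarray:
        z = t.data - t.data.max(axis=-1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=-1, keepdims=True)

    return DenoiserOutput(
        r0_pred=out["r0"].data - out["r0"].data.mean(axis=0, keepdims=True),
        x_dist=dist(out["x_logits"]),
        c_dist=dist(out["c_logits"]),
        y_dist=dist(out["y_logits"]),
    )


def denoiser_forward(
    state, t: int, params: dict[str, Tensor], config: LayerConfig, T: int
) -> DenoiserOutput:
    """Predict the clean molecule from a noisy state (inference API).

    `state` is a DiffusionState or Molecule3DGraph with CoM-free
    coordinates.  Deterministic: no dropout or sampling inside the network.
    """
    graph = state.graph if hasattr(state, "graph") else state
    if np.abs(graph.coords.mean(axis=0)).max() > 1e-6:
        raise ValueError("input coordinates must be CoM-free")
    arrays = graph_to_arrays(graph)
    out = forward_tensors(arrays, t, T, params, config)
    return _normalize_logits(out)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(path, params: dict[str, Tensor], config: LayerConfig, meta: dict | None = None):
    arrays = {f"param::{k}": v.data for k, v in params.items()}
    header = {
        "schema": CHECKPOINT_SCHEMA,
        "config": config.to_dict(),
        "meta": meta or {},
    }
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[dict[str, Tensor], LayerConfig, dict]:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {header.get('schema')}")
        params = {
            k[len("param::") :]: Tensor(data[k].copy(), requires_grad=True)
            for k in data.files
            if k.startswith("param::")
        }
    return params, LayerConfig.from_dict(header["config"]), header.get("meta", {})
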