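"""Training objective and optimization loop.

The loss is the weighted sum of a coordinate MSE against the clean
positions and categorical cross-entropies on atom types, charges and
bonds (bonds on the upper triangle only):

    L = lam_r * MSE(r0_pred, R0) + lam_x * CE(x) + lam_c * CE(c) + lam_y * CE(y)

Each step draws a molecule and a uniform timestep, corrupts the molecule
with the forward process, predicts the clean state and takes an Adam step.
Runs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import time

import numpy as np

from ._autograd import Tensor, log_softmax
from .molgraph import Molecule3DGraph
from .network import LayerConfig, forward_tensors, graph_to_arrays, init_params
from .noise import forward_sample, rng_for
from .schedule import NoiseParams

__all__ = ["TrainConfig", "LossBreakdown", "diffusion_loss", "Adam", "train"]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    steps: int = 2000
    batch_size: int = 1
    learning_rate: float = 1e-3
    seed: int = 0
    lambda_r: float = 1.0
    lambda_x: float = 1.0
    lambda_c: float = 1.0
    lambda_y: float = 2.0
    grad_clip: float = 1.0
    schedule: NoiseParams = dataclasses.field(default_factory=NoiseParams)
    model: LayerConfig = dataclasses.field(default_factory=LayerConfig)

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        for name in ("lambda_r", "lambda_x", "lambda_c", "lambda_y"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclasses.dataclass
class LossBreakdown:
    total: float
    coords: float
    types: float
    charges: float
    bonds: float


def _cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer targets under the logits."""
    if logits.data.size == 0:
        return Tensor(0.0)
    logp = log_softmax(logits, axis=-1)
    rows = np.arange(len(targets))
    return -logp[rows, targets].mean()


def diffusion_loss(
    pred: dict[str, Tensor],
    clean: Molecule3DGraph,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 2.0),
) -> tuple[Tensor, LossBreakdown]:
    """Weighted MSE + cross-entropy loss against the clean molecule.

    `pred` is the logit-level network output (r0, x_logits, c_logits,
    y_logits).  Zero iff coordinates are exact and every predicted
    distribution is a point mass on the truth.
    """
    lam_r, lam_x, lam_c, lam_y = weights
    n = clean.n_atoms
    r0 = np.asarray(clean.coords, dtype=np.float64)
    if pred["r0"].shape != r0.shape:
        raise ValueError("coordinate shape mismatch between prediction and target")
    mse = ((pred["r0"] - r0) ** 2).mean()
    iu, ju = np.triu_indices(n, k=1)
    ce_x = _cross_entropy(pred["x_logits"], clean.atom_types)
    ce_c = _cross_entropy(pred["c_logits"], clean.charges)
    ce_y = _cross_entropy(pred["y_logits"], clean.bonds[iu, ju])
    total = lam_r * mse + lam_x * ce_x + lam_c * ce_c + lam_y * ce_y
    breakdown = LossBreakdown(
        total=float(total.data),
        coords=float(mse.data),
        types=float(ce_x.data),
        charges=float(ce_c.data),
        bonds=float(ce_y.data),
    )
    return total, breakdown


class Adam:
    """Adam with global-norm gradient clipping over a parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, grad_clip: float = 1.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        grads = {k: p.grad for k, p in self.params.items() if p.grad is not None}
        if self.grad_clip:
            gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if gnorm > self.grad_clip:
                scale = self.grad_clip / gnorm
                grads = {k: g * scale for k, g in grads.items()}
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k].data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    dataset: list[Molecule3DGraph],
    config: TrainConfig,
    params: dict[str, Tensor] | None = None,
    forward_fn=None,
    log_path=None,
) -> tuple[dict[str, Tensor], list[LossBreakdown]]:
    """Optimize denoiser parameters on a dataset of clean molecules.

    `forward_fn(arrays, t)` may override the plain denoiser forward (the
    control block passes its conditioned forward here); by default the
    unconditional network with `params` is used.  Returns the trained
    parameters and the per-step loss trace.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    sched = config.schedule
    if params is None:
        params = init_params(config.model, dataset[0].vocab, seed=config.seed)
    if forward_fn is None:
        def forward_fn(arrays, t):
            return forward_tensors(arrays, t, sched.T, params, config.model)

    centered = []
    for mol in dataset:
        m = mol.copy()
        m.coords = m.coords - m.coords.mean(axis=0, keepdims=True)
        centered.append(m)

    opt = Adam(params, lr=config.learning_rate, grad_clip=config.grad_clip)
    weights = (config.lambda_r, config.lambda_x, config.lambda_c, config.lambda_y)
    trace: list[LossBreakdown] = []
    log_f = open(log_path, "w") if log_path else None
    try:
        for step in range(config.steps):
            rng = rng_for(config.seed, step)
            opt.zero_grad()
            breakdowns = []
            any_grad = False
            for b in range(config.batch_size):
                mol = centered[int(rng.integers(len(centered)))]
                t = int(rng.integers(1, sched.T + 1))
                state = forward_sample(mol, t, sched, seed=int(rng.integers(2**31)))
                pred = forward_fn(graph_to_arrays(state.graph), t)
                loss, bd = diffusion_loss(pred, mol, weights)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at step {step} (t={t}, mol={mol.id!r}): {bd}"
                    )
                if loss.requires_grad:
                    loss.backward(np.full_like(loss.data, 1.0 / config.batch_size))
                    any_grad = True
                breakdowns.append(bd)
            if any_grad:
                opt.step()
            bd = LossBreakdown(
                total=float(np.mean([b.total for b in breakdowns])),
                coords=float(np.mean([b.coords for b in breakdowns])),
                types=float(np.mean([b.types for b in breakdowns])),
                charges=float(np.mean([b.charges for b in breakdowns])),
                bonds=float(np.mean([b.bonds for b in breakdowns])),
            )
            trace.append(bd)
            if log_f:
                log_f.write(json.dumps({"step": step, "loss": bd.total,
                                        "coords": bd.coords, "types": bd.types,
                                        "charges": bd.charges, "bonds": bd.bonds,
                                        "time": time.time()}) + "\n")
    finally:
        if log_f:
            log_f.close()
    return params, trace


def smoothed(trace: list[LossBreakdown], window: int = 200) -> np.ndarray:
    """Moving average of the total loss."""
    totals = np.array([b.total for b in trace])
    if len(totals) < window:
        window = max(len(totals), 1)
    kernel = np.ones(window) / window
    return np.convolve(totals, kernel, mode="valid")
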