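"""High-level modelling interface.

`MoleculeDiffusion` is built from a list of training molecules plus the
schedule/architecture configuration; `fit()` runs the diffusion training
loop and returns a `DiffusionResults` carrying the trained parameters,
the loss trace and diagnostics, with `sample()`, `add_control()`,
`evaluate()` and `summary()` hanging off the results object.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .control import ControlState, build_control_model, conditioned_forward, encode_condition
from .metrics import MetricsReport, evaluate_molecules
from .molgraph import Molecule3DGraph, read_sdf
from .network import LayerConfig, denoiser_forward, init_params, load_checkpoint, parameter_count, save_checkpoint
from .sampling import SampleRun, generate, predictor_from_params
from .schedule import NoiseParams
from .training import TrainConfig, smoothed, train

__all__ = ["MoleculeDiffusion", "DiffusionResults"]


class MoleculeDiffusion:
    """Joint 3D-coordinate / atom-type / charge / bond diffusion model.

    Parameters
    ----------
    molecules : training set of fully labelled 3D molecular graphs
    schedule : noise schedule and categorical marginals (NoiseParams)
    arch : network architecture (LayerConfig)
    marginals_from_data : if True (default), replace the schedule's
        categorical marginals with the empirical marginals of the training
        set, which is what makes the t = T prior match the data statistics.
    """

    def __init__(
        self,
        molecules: list[Molecule3DGraph],
        schedule: NoiseParams | None = None,
        arch: LayerConfig | None = None,
        marginals_from_data: bool = True,
    ):
        if not molecules:
            raise ValueError("training set must be non-empty")
        self.molecules = list(molecules)
        self.arch = arch or LayerConfig()
        schedule = schedule or NoiseParams()
        if marginals_from_data:
            schedule = dataclasses.replace(
                schedule,
                m_x=self._empirical_marginal("x"),
                m_c=self._empirical_marginal("c"),
                m_y=self._empirical_marginal("y"),
            )
        self.schedule = schedule

    @classmethod
    def from_sdf(cls, path, **kwargs) -> "MoleculeDiffusion":
        return cls(read_sdf(path), **kwargs)

    def _empirical_marginal(self, channel: str) -> np.ndarray:
        vocab = self.molecules[0].vocab
        if channel == "x":
            k, values = vocab.n_atom_types, np.concatenate([m.atom_types for m in self.molecules])
        elif channel == "c":
            k, values = vocab.n_charges, np.concatenate([m.charges for m in self.molecules])
        else:
            k = vocab.n_bonds
            uppers = []
            for m in self.molecules:
                iu, ju = np.triu_indices(m.n_atoms, k=1)
                uppers.append(m.bonds[iu, ju])
            values = np.concatenate(uppers) if uppers else np.zeros(0, dtype=np.int64)
            if values.size == 0:
                return np.eye(k)[0]
        counts = np.bincount(values, minlength=k).astype(np.float64)
        # floor so no category has exactly zero prior mass
        counts = counts + 0.5
        return counts / counts.sum()

    def atom_count_histogram(self) -> np.ndarray:
        return np.array([m.n_atoms for m in self.molecules])

    def fit(
        self,
        steps: int = 2000,
        learning_rate: float = 1e-3,
        batch_size: int = 1,
        seed: int = 0,
        log_path=None,
        **loss_weights,
    ) -> "DiffusionResults":
        """Train the unconditional denoiser and return the results object."""
        config = TrainConfig(
            steps=steps,
            batch_size=batch_size,
            learning_rate=learning_rate,
            seed=seed,
            schedule=self.schedule,
            model=self.arch,
            **loss_weights,
        )
        params, trace = train(self.molecules, config, log_path=log_path)
        return DiffusionResults(self, params, trace, config)

    def results_from_params(self, params, trace=None) -> "DiffusionResults":
        config = TrainConfig(steps=1, schedule=self.schedule, model=self.arch)
        return DiffusionResults(self, params, trace or [], config)

    @classmethod
    def load(cls, checkpoint_path, molecules: list[Molecule3DGraph]) -> "DiffusionResults":
        params, arch, meta = load_checkpoint(checkpoint_path)
        schedule = NoiseParams.from_dict(meta["schedule"]) if "schedule" in meta else None
        model = cls(molecules, schedule=schedule, arch=arch, marginals_from_data=schedule is None)
        return model.results_from_params(params)


class DiffusionResults:
    """Fitted diffusion model: parameters, loss trace and sampling API."""

    def __init__(self, model: MoleculeDiffusion, params, trace, config: TrainConfig):
        self.model = model
        self.params = params
        self.loss_trace = trace
        self.config = config
        self.control: ControlState | None = None

    # -- diagnostics ----------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return parameter_count(self.model.arch, self.model.molecules[0].vocab)

    def final_loss(self, window: int = 200) -> float:
        return float(smoothed(self.loss_trace, window)[-1]) if self.loss_trace else float("nan")

    def initial_loss(self, window: int = 200) -> float:
        return float(smoothed(self.loss_trace, window)[0]) if self.loss_trace else float("nan")

    def summary(self) -> str:
        sched = self.model.schedule
        lines = [
            "Controlled equivariant molecule diffusion",
            "=" * 45,
            f"training molecules      {len(self.model.molecules)}",
            f"parameters              {self.n_parameters}",
            f"layers / width / heads  {self.model.arch.n_layers} / {self.model.arch.width} / {self.model.arch.n_heads}",
            f"diffusion steps T       {sched.T}",
            f"schedule exponents      nu_r={sched.nu_r} nu_x={sched.nu_x} nu_c={sched.nu_c} nu_y={sched.nu_y}",
            f"optimizer steps         {len(self.loss_trace)}",
        ]
        if self.loss_trace:
            lines += [
                f"loss (smoothed) start   {self.initial_loss():.4f}",
                f"loss (smoothed) final   {self.final_loss():.4f}",
            ]
        lines.append(f"control branch          {'attached' if self.control else 'none'}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        save_checkpoint(
            path, self.params, self.model.arch, meta={"schedule": self.model.schedule.to_dict()}
        )

    # -- conditioning ---------------------------------------------------------
    def add_control(self) -> ControlState:
        """Attach a ControlNet-style branch (frozen base + trainable copy)."""
        self.control = build_control_model(self.params, self.model.arch, self.model.molecules[0].vocab)
        return self.control

    def _predictor(self, condition: Molecule3DGraph | None):
        T = self.model.schedule.T
        if condition is None or self.control is None:
            return predictor_from_params(self.params, self.model.arch, T)
        cs = self.control

        def predict(state, t):
            cond = encode_condition(condition, state.graph.n_atoms, cs.theta_frozen, cs.config)
            return conditioned_forward(state, t, cond, cs, T)

        return predict

    # -- generation -----------------------------------------------------------
    def sample(
        self,
        n_molecules: int,
        seed: int = 0,
        condition: Molecule3DGraph | None = None,
        out_path=None,
        fixed_n: int | None = None,
    ) -> list[Molecule3DGraph]:
        """Generate molecules; atom counts follow the training histogram."""
        run = SampleRun(
            n_molecules=n_molecules,
            seed=seed,
            atom_counts=None if fixed_n else self.model.atom_count_histogram(),
            fixed_n=fixed_n or 5,
        )
        return generate(
            run,
            self._predictor(condition),
            self.model.schedule,
            out_path=out_path,
            metadata={"n_parameters": self.n_parameters},
        )

    def evaluate(self, generated: list[Molecule3DGraph]) -> MetricsReport:
        """Score generated molecules against the training set."""
        return evaluate_molecules(generated, self.model.molecules)
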