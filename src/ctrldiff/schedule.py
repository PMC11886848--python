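"""Noise schedules and categorical transition matrices.

The corruption process is variance-preserving Gaussian diffusion for
coordinates and marginal-mixing categorical diffusion for atom types,
charges and bonds.  Each modality gets its own power-cosine schedule

    alpha_bar(t) = cos( (pi/2) * ((t/T + s)/(1 + s))**nu )**2

so discrete channels can be corrupted faster or slower than coordinates
(nu = 1 is the plain cosine schedule).  Categorical corruption mixes the
current one-hot state with the dataset marginal m:

    Q(alpha) = alpha * I + (1 - alpha) * 1 m^T

a family closed under composition, Q(a) Q(b) = Q(ab), so the t-step kernel
is simply Q(alpha_bar_t).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "NoiseParams",
    "ScheduleValues",
    "TransitionSet",
    "alpha_bar",
    "transition_matrix",
]

CHANNELS = ("r", "x", "c", "y")

# floor/ceiling for alpha_bar away from the exact endpoints, to keep
# posteriors non-degenerate
_ALPHA_CLAMP = 1e-5


def alpha_bar(t, T: int, s: float = 0.008, nu: float = 1.0):
    """Power-cosine cumulative signal level, clamped to [0, 1].

    Exactly 0 at t = T for every nu (the argument reaches pi/2) and close
    to 1 at t = 0.  Vectorized over t.
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0) or np.any(t > T):
        raise ValueError(f"t must lie in [0, {T}]")
    frac = ((t / T + s) / (1.0 + s)) ** nu
    val = np.cos(0.5 * np.pi * frac) ** 2
    # the raw value at t=T is cos(pi/2)^2 which may carry float dust
    val = np.where(t == T, 0.0, val)
    return np.clip(val, 0.0, 1.0)[()] if val.ndim == 0 else np.clip(val, 0.0, 1.0)


@dataclasses.dataclass(frozen=True)
class NoiseParams:
    """Schedule and marginal configuration of the corruption process.

    T        total diffusion steps
    s        cosine-schedule offset
    nu_*     per-modality schedule exponents (r=coords, x=types, c=charges,
             y=bonds); nu > 1 corrupts discrete channels more slowly early on
    m_*      dataset marginal distributions used as the categorical prior
    """

    T: int = 500
    s: float = 0.008
    nu_r: float = 1.0
    nu_x: float = 1.5
    nu_c: float = 1.5
    nu_y: float = 1.5
    m_x: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.51, 0.35, 0.06, 0.07, 0.01])
    )
    m_c: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.01, 0.98, 0.01])
    )
    m_y: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.88, 0.10, 0.008, 0.002, 0.01])
    )

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.s <= 0:
            raise ValueError("s must be > 0")
        for name in ("nu_r", "nu_x", "nu_c", "nu_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("m_x", "m_c", "m_y"):
            m = np.asarray(getattr(self, name), dtype=np.float64)
            if np.any(m < 0) or abs(m.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector")
            object.__setattr__(self, name, m)

    def nu(self, channel: str) -> float:
        return {"r": self.nu_r, "x": self.nu_x, "c": self.nu_c, "y": self.nu_y}[channel]

    def marginal(self, channel: str) -> np.ndarray:
        return {"x": self.m_x, "c": self.m_c, "y": self.m_y}[channel]

    def alpha_bar(self, t, channel: str):
        """Clamped ᾱ for one modality.

        Categorical channels hit exactly 0 at t = T (prior = marginal);
        elsewhere, and for coordinates at T, values are clamped into
        [1e-5, 1 - 1e-5] to avoid degenerate posteriors.
        """
        raw = alpha_bar(t, self.T, self.s, self.nu(channel))
        clamped = np.clip(raw, _ALPHA_CLAMP, 1.0 - _ALPHA_CLAMP)
        if channel != "r":
            clamped = np.where(np.asarray(t) == self.T, 0.0, clamped)
        return clamped[()] if np.ndim(clamped) == 0 else clamped

    def schedule(self, channel: str) -> "ScheduleValues":
        t = np.arange(self.T + 1)
        ab = np.asarray(self.alpha_bar(t, channel), dtype=np.float64)
        alpha_t = np.sqrt(ab[1:] / ab[:-1]) if channel == "r" else ab[1:] / np.maximum(ab[:-1], 1e-30)
        if channel == "r":
            sigma_t = np.sqrt(1.0 - alpha_t**2)
        else:
            sigma_t = np.sqrt(np.clip(1.0 - alpha_t**2, 0.0, 1.0))
        return ScheduleValues(alpha_bar=ab, alpha_t=alpha_t, sigma_t=sigma_t)

    def to_dict(self) -> dict:
        return {
            "family": "cosine-power",
            "T": self.T,
            "s": self.s,
            "nu": {c: self.nu(c) for c in CHANNELS},
            "marginals": {c: self.marginal(c).tolist() for c in ("x", "c", "y")},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseParams":
        nu = d.get("nu", {})
        marg = d.get("marginals", {})
        kwargs = {"T": int(d["T"]), "s": float(d["s"])}
        for c in CHANNELS:
            if c in nu:
                kwargs[f"nu_{c}"] = float(nu[c])
        for c in ("x", "c", "y"):
            if c in marg:
                kwargs[f"m_{c}"] = np.asarray(marg[c], dtype=np.float64)
        return cls(**kwargs)


@dataclasses.dataclass(frozen=True)
class ScheduleValues:
    """Derived per-step schedule: ᾱ_0..ᾱ_T, α_t and σ_t for t = 1..T."""

    alpha_bar: np.ndarray
    alpha_t: np.ndarray
    sigma_t: np.ndarray


def transition_matrix(alpha: float, m: np.ndarray) -> np.ndarray:
    """Marginal-mixing categorical kernel Q = alpha·I + (1-alpha)·1 mᵀ."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    m = np.asarray(m, dtype=np.float64)
    if np.any(m < 0) or abs(m.sum() - 1.0) > 1e-9:
        raise ValueError("m must be a probability vector")
    k = len(m)
    return alpha * np.eye(k) + (1.0 - alpha) * np.ones((k, 1)) * m[None, :]


@dataclasses.dataclass(frozen=True)
class TransitionSet:
    """Per-step transition matrices for the three categorical channels."""

    Q_x: np.ndarray  # (T, k_x, k_x), step kernels Q_t
    Q_c: np.ndarray
    Q_y: np.ndarray

    @classmethod
    def from_params(cls, params: NoiseParams) -> "TransitionSet":
        mats = {}
        for channel in ("x", "c", "y"):
            sched = params.schedule(channel)
            m = params.marginal(channel)
            mats[channel] = np.stack(
                [transition_matrix(a, m) for a in np.clip(sched.alpha_t, 0.0, 1.0)]
            )
        return cls(Q_x=mats["x"], Q_c=mats["c"], Q_y=mats["y"])
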