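"""State augmentation for Bayesian parameter estimation.

Static parameters are appended to the state vector and given small
artificial stochastic dynamics with a time-decaying diffusion

    sigma_theta(t) = a_theta / (t - b_theta)^2,

so the parameter cloud explores early and freezes as data accumulate.
Positive parameters use geometric noise d(theta) = theta sigma(t) dW
(propagated by the exact log-space geometric-Brownian increment, which
preserves positivity for any draw); real-valued parameters use additive
noise d(theta) = sigma(t) dW.  The coefficients (a, b) are fixed by two
interpolation points (t0, sigma0), (t1, sigma1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .models import StateSpaceModel

__all__ = [
    "ArtificialDynamics",
    "ParameterSpec",
    "decay_coefficients",
    "propagate_parameters",
    "build_augmented_model",
]


def decay_coefficients(t0: float, sigma0: float, t1: float, sigma1: float
                       ) -> Tuple[float, float]:
    """Solve sigma(t) = a/(t-b)^2 through (t0, sigma0) and (t1, sigma1).

    With r = sqrt(sigma0/sigma1) > 1 the pole sits at
    b = t0 + (t1-t0)/(1-r) < t0, and a = sigma0 (t0-b)^2, so sigma is
    strictly decreasing on [t0, inf).
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if not 0 < sigma1 < sigma0:
        raise ValueError("require 0 < sigma1 < sigma0 for a decaying schedule")
    r = np.sqrt(sigma0 / sigma1)
    b = t0 + (t1 - t0) / (1.0 - r)
    a = sigma0 * (t0 - b) ** 2
    return float(a), float(b)


@dataclass
class ArtificialDynamics:
    """Decaying-diffusion noise schedule for one augmented parameter."""

    kind: str                    # "geometric" | "additive"
    a_theta: float = 0.0
    b_theta: float = 0.0
    sigma_of_t: Optional[Callable[[float], float]] = None

    def __post_init__(self):
        if self.kind not in ("geometric", "additive"):
            raise ValueError(f"unknown dynamics kind {self.kind!r}")

    @classmethod
    def from_interpolation(cls, kind: str, t0: float, sigma0: float,
                           t1: float, sigma1: float) -> "ArtificialDynamics":
        a, b = decay_coefficients(t0, sigma0, t1, sigma1)
        return cls(kind=kind, a_theta=a, b_theta=b)

    @classmethod
    def frozen(cls, kind: str = "geometric") -> "ArtificialDynamics":
        """No artificial noise (sigma identically 0)."""
        return cls(kind=kind, sigma_of_t=lambda t: 0.0)

    def sigma(self, t: float) -> float:
        if self.sigma_of_t is not None:
            return float(self.sigma_of_t(t))
        return self.a_theta / (t - self.b_theta) ** 2


def propagate_parameters(theta: np.ndarray, dyn: Sequence[ArtificialDynamics],
                         t: float, dt: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Advance parameter columns by their artificial dynamics over [t, t+dt].

    ``theta`` has shape (n, P); geometric parameters are multiplied by
    exp(sigma sqrt(dt) z - sigma^2 dt / 2), additive parameters receive
    sigma sqrt(dt) z.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    theta = np.asarray(theta, dtype=float)
    out = theta.copy()
    n = theta.shape[0]
    for p, d in enumerate(dyn):
        s = d.sigma(t)
        if s == 0.0:
            continue
        z = rng.standard_normal(n)
        if d.kind == "geometric":
            out[:, p] = theta[:, p] * np.exp(s * np.sqrt(dt) * z
                                             - 0.5 * s * s * dt)
        else:
            out[:, p] = theta[:, p] + s * np.sqrt(dt) * z
    return out


@dataclass
class ParameterSpec:
    """Prior and artificial dynamics for one augmented parameter."""

    name: str
    prior_sampler: Callable[[np.random.Generator, int], np.ndarray]
    dynamics: ArtificialDynamics


def build_augmented_model(
    dynamic_dim: int,
    drift: Callable[[np.ndarray, np.ndarray, float], np.ndarray],
    diffusion: Callable[[np.ndarray, np.ndarray, float], np.ndarray],
    initial_sampler: Callable[[np.random.Generator, int], np.ndarray],
    parameters: Sequence[ParameterSpec],
    state_names: Optional[Sequence[str]] = None,
    wiener_dim: Optional[int] = None,
) -> StateSpaceModel:
    """State-space model over the concatenated vector (q, theta).

    ``drift(q, theta, t)`` and ``diffusion(q, theta, t)`` describe the
    dynamic block given the per-particle parameter values (shapes
    (n, nq) and (n, P)); the parameter block follows its artificial
    dynamics.  Each transition does one Euler–Maruyama step on q and an
    exact geometric/additive increment on theta.
    """
    nq = dynamic_dim
    P = len(parameters)
    names = list(state_names) if state_names is not None \
        else [f"q{i+1}" for i in range(nq)]
    pnames = [p.name for p in parameters]
    clash = set(names) & set(pnames)
    if clash or len(set(names)) != len(names) or len(set(pnames)) != len(pnames):
        raise ValueError(f"state/parameter name collision: {sorted(clash)}")
    m = wiener_dim if wiener_dim is not None else nq
    dyn = [p.dynamics for p in parameters]

    def full_initial(rng: np.random.Generator, n: int) -> np.ndarray:
        q0 = np.asarray(initial_sampler(rng, n), dtype=float)
        if q0.ndim == 1:
            q0 = q0[:, None]
        cols = [np.asarray(p.prior_sampler(rng, n), dtype=float).reshape(n)
                for p in parameters]
        return np.column_stack([q0] + cols) if P else q0

    def full_drift(x: np.ndarray, t: float) -> np.ndarray:
        a = np.zeros_like(x)
        a[:, :nq] = drift(x[:, :nq], x[:, nq:], t)
        return a

    def full_diffusion(x: np.ndarray, t: float) -> np.ndarray:
        b = diffusion(x[:, :nq], x[:, nq:], t)
        b = np.asarray(b, dtype=float)
        if b.ndim == 2:
            out = np.zeros((nq + P, m))
            out[:nq, :] = b
        else:
            out = np.zeros((x.shape[0], nq + P, m))
            out[:, :nq, :] = b
        return out

    def step(x: np.ndarray, t: float, dt: float,
             rng: np.random.Generator) -> np.ndarray:
        out = x.copy()
        q, theta = x[:, :nq], x[:, nq:]
        eta = rng.standard_normal((x.shape[0], m))
        a = drift(q, theta, t)
        b = np.asarray(diffusion(q, theta, t), dtype=float)
        if b.ndim == 2:
            diff = eta @ b.T
        else:
            diff = np.einsum("nij,nj->ni", b, eta)
        out[:, :nq] = q + a * dt + np.sqrt(dt) * diff
        if P:
            out[:, nq:] = propagate_parameters(theta, dyn, t, dt, rng)
        return out

    return StateSpaceModel(
        dim=nq + P,
        drift=full_drift,
        diffusion=full_diffusion,
        initial_sampler=full_initial,
        wiener_dim=m,
        coord_names=names + pnames,
        custom_step=step,
    )
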