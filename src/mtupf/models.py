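"""Continuous-time Markov state processes defined by Itô SDEs.

A :class:`StateSpaceModel` bundles the drift ``a(x, t)``, the diffusion
matrix ``B(x, t)`` and an initial-state sampler of the SDE

    dX_t = a(X_t, t) dt + B(X_t, t) dW_t,

together with an optional importance-sampling proposal.  All time
quantities are in hours.  Filters advance particle clouds through
:meth:`StateSpaceModel.step`, which defaults to the Euler–Maruyama scheme;
models with exactly sampleable sub-dynamics (e.g. geometric Brownian
parameter noise) may override it.

Vectorization convention: particle states are arrays of shape ``(n, dim)``;
``drift`` maps ``(n, dim) -> (n, dim)`` and ``diffusion`` maps
``(n, dim) -> (dim, m)`` (shared across particles) or ``(n, dim, m)``
(state-dependent), where ``m`` is the dimension of the driving Wiener
process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "StateSpaceModel",
    "ProposalKernel",
    "euler_maruyama_step",
    "simulate_path",
    "transition_log_ratio",
    "get_model",
    "register_model",
]


@dataclass
class ProposalKernel:
    """Importance-sampling proposal with pointwise density ratios.

    ``log_density_ratio`` evaluates the logarithm of the Radon–Nikodym
    derivative of the model transition kernel with respect to the proposal
    kernel; ``initial_log_ratio`` the same for the initial laws.  When the
    proposal coincides with the model kernel both are identically 0.
    """

    sample_step: Callable[[np.ndarray, float, float, np.random.Generator], np.ndarray]
    log_density_ratio: Callable[[np.ndarray, np.ndarray, float, float], np.ndarray]
    initial_log_ratio: Callable[[np.ndarray], np.ndarray]

    @staticmethod
    def prior() -> "ProposalKernel":
        """The bootstrap choice: sample from the model kernel itself."""
        return ProposalKernel(
            sample_step=lambda state, t_from, t_to, rng: state,
            log_density_ratio=lambda x_to, x_from, t_from, t_to: np.zeros(
                np.shape(x_to)[0] if np.ndim(x_to) > 1 else ()
            ),
            initial_log_ratio=lambda x: np.zeros(
                np.shape(x)[0] if np.ndim(x) > 1 else ()
            ),
        )


@dataclass
class StateSpaceModel:
    dim: int
    drift: Callable[[np.ndarray, float], np.ndarray]
    diffusion: Callable[[np.ndarray, float], np.ndarray]
    initial_sampler: Callable[[np.random.Generator, int], np.ndarray]
    wiener_dim: Optional[int] = None
    proposal: Optional[ProposalKernel] = None
    coord_names: Optional[list] = None
    # optional exact / structured transition; signature (states, t, dt, rng)
    custom_step: Optional[Callable] = None

    def __post_init__(self):
        if self.wiener_dim is None:
            self.wiener_dim = self.dim

    def sample_initial(self, rng: np.random.Generator, n: int) -> np.ndarray:
        states = np.asarray(self.initial_sampler(rng, n), dtype=float)
        if states.shape != (n, self.dim):
            raise ValueError(
                f"initial_sampler returned shape {states.shape}, "
                f"expected {(n, self.dim)}"
            )
        return states

    def step(self, states: np.ndarray, t: float, dt: float,
             rng: np.random.Generator) -> np.ndarray:
        """Advance all particles from t to t + dt."""
        if self.custom_step is not None:
            return self.custom_step(states, t, dt, rng)
        noise = rng.standard_normal((states.shape[0], self.wiener_dim))
        return euler_maruyama_step(states, self, t, dt, noise)


def _check_finite(arr: np.ndarray, name: str, t: float) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(
            f"{name} returned non-finite values at t={t:g}"
        )
    return arr


def euler_maruyama_step(state: np.ndarray, model: StateSpaceModel, t: float,
                        dt: float, noise: np.ndarray) -> np.ndarray:
    """One Euler–Maruyama step: state + a·dt + B·sqrt(dt)·eta.

    Accepts a single state vector ``(dim,)`` or a batch ``(n, dim)``; the
    noise must match the Wiener dimension (``(m,)`` or ``(n, m)``).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    state = np.asarray(state, dtype=float)
    single = state.ndim == 1
    x = state[None, :] if single else state
    eta = np.asarray(noise, dtype=float)
    eta = eta[None, :] if eta.ndim == 1 else eta

    a = _check_finite(model.drift(x, t), "drift", t)
    b = _check_finite(model.diffusion(x, t), "diffusion", t)
    if b.ndim == 2:  # shared matrix (dim, m)
        diff_term = eta @ b.T
    else:  # (n, dim, m)
        diff_term = np.einsum("nij,nj->ni", b, eta)
    out = x + a * dt + np.sqrt(dt) * diff_term
    return out[0] if single else out


def simulate_path(model: StateSpaceModel, t_grid: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Simulate one path of the model on a strictly increasing grid.

    Returns an array of shape ``(len(t_grid), dim)`` whose first row is a
    draw from the initial distribution.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-d array")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    path = np.empty((t_grid.size, model.dim))
    state = model.sample_initial(rng, 1)
    path[0] = state[0]
    for k in range(1, t_grid.size):
        dt = t_grid[k] - t_grid[k - 1]
        state = model.step(state, t_grid[k - 1], dt, rng)
        path[k] = state[0]
    return path


def transition_log_ratio(kernel: Optional[ProposalKernel], state_to,
                         state_from, t_from: float, t_to: float):
    """Log Radon–Nikodym derivative of model vs proposal kernel.

    Returns 0 for the bootstrap (prior) proposal.  ``-inf`` indicates a
    transition outside the proposal's support.
    """
    if t_to <= t_from:
        raise ValueError("t_to must exceed t_from")
    if kernel is None:
        state_to = np.asarray(state_to)
        return np.zeros(state_to.shape[0] if state_to.ndim > 1 else ())
    return kernel.log_density_ratio(state_to, state_from, t_from, t_to)


# ---------------------------------------------------------------------------
# model registry (used by the CLI)

_REGISTRY: dict = {}


def register_model(name: str, factory: Callable[..., StateSpaceModel]) -> None:
    _REGISTRY[name] = factory


def get_model(name: str, **kwargs) -> StateSpaceModel:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return factory(**kwargs)
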