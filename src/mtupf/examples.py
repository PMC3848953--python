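"""Ready-made estimation setups for the built-in example models.

The motivating example estimates theta = (alpha, beta) of the linear SDE
dq = (-alpha q + beta) dt + sigma dW by augmenting the state with the
parameters under geometric artificial noise with the decaying schedule
sigma_theta(t) = 5.43/(t + 3.29)^2 (whose initial level is 0.5), priors
alpha ~ Log-N(log 2, 1), beta ~ Log-N(log 6, 1), and the measurement
design of :mod:`mtupf.synthetic`.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .augmentation import ArtificialDynamics, ParameterSpec, \
    build_augmented_model
from .models import StateSpaceModel, register_model
from .observations import Observation, gaussian_value_density
from .synthetic import MotivatingConfig, motivating_model, \
    motivating_time_density

__all__ = [
    "motivating_dynamics_schedule",
    "motivating_estimation_model",
    "motivating_observations",
    "motivating_simulation_model",
]

#: the example's artificial-noise schedule sigma_theta(t) = a/(t-b)^2
MOTIVATING_A = 5.43
MOTIVATING_B = -3.29


def motivating_dynamics_schedule() -> ArtificialDynamics:
    return ArtificialDynamics(kind="geometric", a_theta=MOTIVATING_A,
                              b_theta=MOTIVATING_B)


def motivating_estimation_model(cfg: Optional[MotivatingConfig] = None,
                                with_noise: bool = True) -> StateSpaceModel:
    """Augmented model (q, alpha, beta) with priors and artificial noise."""
    cfg = cfg or MotivatingConfig()
    dyn = motivating_dynamics_schedule() if with_noise \
        else ArtificialDynamics.frozen()

    def lognormal(median):
        return lambda rng, n: np.exp(np.log(median)
                                     + rng.standard_normal(n))

    specs = [
        ParameterSpec("alpha", lognormal(2.0), dyn),
        ParameterSpec("beta", lognormal(6.0), dyn),
    ]
    return build_augmented_model(
        dynamic_dim=1,
        drift=lambda q, th, t: -th[:, [0]] * q + th[:, [1]],
        diffusion=lambda q, th, t: np.array([[cfg.sigma]]),
        initial_sampler=lambda rng, n: np.exp(
            cfg.mu_q0 + cfg.sigma_q0 * rng.standard_normal((n, 1))),
        parameters=specs,
        state_names=["q"],
        wiener_dim=1,
    )


def motivating_simulation_model(alpha: float, beta: float,
                                cfg: Optional[MotivatingConfig] = None
                                ) -> StateSpaceModel:
    """State-only model with the parameters fixed (simulation runs)."""
    cfg = cfg or MotivatingConfig()
    return motivating_model(alpha, beta, cfg.sigma, cfg.mu_q0, cfg.sigma_q0)


def motivating_observations(times: Sequence[float],
                            values: Sequence[float],
                            sigma_y: float,
                            cfg: Optional[MotivatingConfig] = None,
                            with_time_density: bool = True
                            ) -> List[Observation]:
    """Observations on the (possibly augmented) model; q is coordinate 0."""
    cfg = cfg or MotivatingConfig()
    obs = []
    for j, (t_hat, y) in enumerate(zip(times, values)):
        td = motivating_time_density(float(t_hat), cfg) \
            if with_time_density else None
        obs.append(Observation(
            index=j, value=float(y), intended_time=float(t_hat),
            value_log_density=lambda y_, s, t, sy=sigma_y:
                gaussian_value_density(y_, s[:, 0], sy),
            time_density=td))
    return obs


register_model("motivating", lambda **kw: motivating_estimation_model(**kw))


def _leucine_factory(population_file=None, **kw):
    from .leucine import build_population_model, read_population_file
    if population_file is None:
        raise ValueError("the leucine model requires population_file=...")
    model, _ = build_population_model(read_population_file(population_file),
                                      **kw)
    return model


register_model("leucine", _leucine_factory)
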