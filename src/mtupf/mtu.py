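"""MTU particle filter: filtering under measurement-time uncertainty.

When the time of each measurement is itself a random variable with
density gamma_j, the filter weight of a particle path x_[t0,t] is the
product over observations of partial weights

    w_{j,t} = 1 - gamma_bar_{j,t} + w_bar_{j,t},

where gamma_bar_{j,t} is the cdf of gamma_j at t and
w_bar_{j,t} = int_{t0}^t g_j(y_j | x_s, s) gamma_j(s) ds accumulates the
time-marginalized likelihood contribution of observation j.  Weights
therefore evolve continuously: instead of point updates at measurement
times, each discretization step integrates a sliver of every active
observation's likelihood.  This split form is numerically robust (the
naive integrand (g-1)*gamma accumulates catastrophic cancellation when g
is tiny) and uses the analytic cdf for gamma_bar whenever available.

Resampling with selection weights v multiplies a per-particle cumulative
product v_bar which divides the raw product weight (correction of the
selection bias); the data-likelihood estimate carries one factor
sum_i(v_i)/N per resampling event.  The discretization stepsize adapts to
the effective sample size: linear interpolation on the last ESS drop
between dt_max and dt_min, then halving until the predicted ESS of the
candidate step does not fall more than ``rel_drop`` (10%) below the
current ESS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .models import StateSpaceModel
from .observations import Observation
from .standard import (DegeneracyError, ResampleConfig, WeightedSample,
                       ess_from_log_weights, resample)
from .trace import FilterTrace, weighted_quantile

__all__ = [
    "MtuCloud",
    "StepsizeConfig",
    "partial_weight_step",
    "combined_weight",
    "combined_log_weights",
    "ess_from_log_weights",
    "predict_ess",
    "adaptive_stepsize",
    "run_mtu_filter",
    "mtu_likelihood",
]

log = logging.getLogger(__name__)


@dataclass
class StepsizeConfig:
    dt_max: float = 1e-2
    dt_min: float = 1e-6
    rel_drop: float = 0.10

    def __post_init__(self):
        if not 0 < self.dt_min <= self.dt_max:
            raise ValueError("require 0 < dt_min <= dt_max")
        if not 0 < self.rel_drop < 1:
            raise ValueError("rel_drop must lie in (0, 1)")


@dataclass
class MtuCloud:
    """Particle cloud with per-observation partial-weight accumulators.

    ``gamma_bar[j]`` is the cdf of observation j's time density at the
    current time (shared by all particles); ``w_bar[j, i]`` the particle-
    specific integral of g_j * gamma_j; ``log_v_bar[i]`` the log of the
    cumulative selection-weight product introduced by resampling.
    """

    states: np.ndarray           # (n, dim)
    gamma_bar: np.ndarray        # (M,)
    w_bar: np.ndarray            # (M, n)
    log_v_bar: np.ndarray        # (n,)
    time: float

    @classmethod
    def initial(cls, states: np.ndarray, n_obs: int, t0: float) -> "MtuCloud":
        n = states.shape[0]
        return cls(states=states, gamma_bar=np.zeros(n_obs),
                   w_bar=np.zeros((n_obs, n)), log_v_bar=np.zeros(n),
                   time=t0)

    @property
    def n_particles(self) -> int:
        return self.states.shape[0]


def _log_factors(gamma_bar: np.ndarray, w_bar: np.ndarray) -> np.ndarray:
    """log(1 - gamma_bar + w_bar) per observation and particle, (M, n)."""
    f = 1.0 - gamma_bar[:, None] + w_bar
    f = np.maximum(f, 0.0)  # guard tiny negative round-off
    with np.errstate(divide="ignore"):
        return np.log(f)


def combined_log_weights(cloud: MtuCloud) -> np.ndarray:
    """Log of the corrected combined weights prod_j(1-gb_j+wb_j) / v_bar."""
    return _log_factors(cloud.gamma_bar, cloud.w_bar).sum(axis=0) \
        - cloud.log_v_bar


def combined_weight(cloud: MtuCloud) -> np.ndarray:
    """Corrected combined weights on the linear scale."""
    return np.exp(combined_log_weights(cloud))


def partial_weight_step(cloud: MtuCloud, observations: Sequence[Observation],
                        t: float, dt: float,
                        g_lin: Optional[np.ndarray] = None) -> None:
    """Advance the accumulators (gamma_bar, w_bar) from t to t + dt in place.

    Both accumulators use the analytic cdf G_j: gamma_bar jumps to
    G_j(t + dt) and w_bar gains g_j(y_j | x_t, t) * (G_j(t+dt) - G_j(t)),
    the left-endpoint value of g times the exact time-density mass of the
    step.  This is exact for g constant over the step however sharply
    gamma_j is peaked (a plain g * gamma(t) * dt rule would need steps far
    below the density's width).  Outside the support of gamma_j both
    accumulators are unchanged.  ``g_lin`` may supply pre-computed g
    values (M, n) to avoid re-evaluation.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for j, obs in enumerate(observations):
        td = obs.time_density
        lo, hi = td.support
        if t + dt <= lo or t >= hi:
            continue
        gb_new = float(np.asarray(td.cdf(t + dt)))
        mass = gb_new - cloud.gamma_bar[j]
        if mass > 0.0:
            if g_lin is not None:
                g = g_lin[j]
            else:
                with np.errstate(over="ignore"):
                    g = np.exp(obs_log_g_safe(obs, cloud.states, t))
            cloud.w_bar[j] += g * mass
        cloud.gamma_bar[j] = gb_new
    cloud.time = t + dt


def predict_ess(cloud: MtuCloud, observations: Sequence[Observation],
                dt: float, g_lin: Optional[np.ndarray] = None) -> float:
    """ESS of the combined weights after a candidate step of length dt.

    Applies the partial-weight update to a copy of the accumulators
    without advancing the states.  Valid when sampling from the prior
    kernel, where the weight increment does not depend on the new states.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = cloud.time
    touched = []
    for j, obs in enumerate(observations):
        td = obs.time_density
        lo, hi = td.support
        if t + dt <= lo or t >= hi:
            continue
        gb_new = float(np.asarray(td.cdf(t + dt)))
        if gb_new != cloud.gamma_bar[j]:
            touched.append((j, gb_new))
    if not touched:
        return ess_from_log_weights(combined_log_weights(cloud))
    # rebuild the touched factors from scratch (no log subtraction: a
    # factor may sit at exactly 0 and revive when w_bar starts growing)
    untouched = np.setdiff1d(np.arange(len(observations)),
                             [j for j, _ in touched])
    logw = -cloud.log_v_bar.copy()
    if untouched.size:
        logw += _log_factors(cloud.gamma_bar[untouched],
                             cloud.w_bar[untouched]).sum(axis=0)
    for j, gb_new in touched:
        mass = gb_new - cloud.gamma_bar[j]
        if g_lin is not None:
            g = g_lin[j]
        else:
            with np.errstate(over="ignore"):
                g = np.exp(obs_log_g_safe(observations[j], cloud.states, t))
        f_new = np.maximum(1.0 - gb_new + cloud.w_bar[j] + g * mass, 0.0)
        with np.errstate(divide="ignore"):
            logw += np.log(f_new)
    return ess_from_log_weights(logw)


def obs_log_g_safe(obs: Observation, states: np.ndarray,
                   t: float) -> np.ndarray:
    """log g with NaN (overflowed states) mapped to -inf."""
    lg = obs.log_g(states, t)
    return np.where(np.isnan(lg), -np.inf, lg)


def adaptive_stepsize(ess_now: float, ess_prev: float, cloud: MtuCloud,
                      observations: Sequence[Observation],
                      cfg: StepsizeConfig,
                      g_lin: Optional[np.ndarray] = None,
                      dt_cap: Optional[float] = None,
                      predict: bool = True) -> float:
    """Choose the next stepsize from the ESS history and a prediction loop.

    Initial guess: linear interpolation between dt_max (ESS unchanged over
    the last accepted step) and dt_min (ESS dropped by N-1, the largest
    drop possible).  The guess is halved while the predicted ESS falls
    more than ``rel_drop`` below the current ESS, with dt_min as floor.
    ``dt_cap`` additionally bounds the step (support boundaries and the
    final time must land on grid points).
    """
    n = cloud.n_particles
    drop = min(max(ess_prev - ess_now, 0.0), n - 1.0)
    frac = drop / (n - 1.0) if n > 1 else 0.0
    dt = cfg.dt_max - (cfg.dt_max - cfg.dt_min) * frac
    if dt_cap is not None:
        dt = min(dt, dt_cap)
    if predict:
        while dt > cfg.dt_min:
            if predict_ess(cloud, observations, dt, g_lin) \
                    >= (1.0 - cfg.rel_drop) * ess_now:
                break
            dt = dt / 2.0
    dt = max(dt, cfg.dt_min)
    if dt_cap is not None:
        dt = min(dt, dt_cap)
    return dt


def mtu_likelihood(combined_weights: np.ndarray,
                   selection_sums: Sequence[float]) -> float:
    """Corrected data-likelihood estimate.

    Z_hat = (1/N^{l+1}) * prod_l (sum_i v_i at resampling l)
            * sum_i corrected combined weight_i,
    where ``combined_weights`` are already corrected by v_bar.
    """
    w = np.asarray(combined_weights, dtype=float)
    n = w.size
    z = w.sum() / n
    for s in selection_sums:
        z *= s / n
    return float(z)


def run_mtu_filter(
    model: StateSpaceModel,
    observations: Sequence[Observation],
    n_particles: int,
    stepsize: Optional[StepsizeConfig] = None,
    resample_config: Optional[ResampleConfig] = None,
    rng: Optional[np.random.Generator] = None,
    t0: float = 0.0,
    t_end: Optional[float] = None,
    track_coords: Optional[Sequence[int]] = None,
    record_every: int = 1,
) -> FilterTrace:
    """Run the MTU particle filter.

    Per accepted step: choose dt adaptively, advance the states by the
    model transition, integrate all partial weights, compute corrected
    combined weights, record ESS and the data-likelihood estimate, and
    resample (selection weights = current corrected combined weights,
    selecting the v_bar products alongside the states) when the ESS drops
    below the threshold.
    """
    cfg = stepsize or StepsizeConfig()
    rcfg = resample_config or ResampleConfig()
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    threshold = rcfg.threshold_for(n_particles)
    obs = list(observations)
    for o in obs:
        if o.time_density is None:
            raise ValueError(f"observation {o.index} lacks a time density")
        if o.time_density.support[0] < t0 - 1e-12:
            raise ValueError(
                f"observation {o.index} support starts before t0")
    if t_end is None:
        t_end = max((o.time_density.support[1] for o in obs), default=t0)
    names = model.coord_names or [f"x{i}" for i in range(model.dim)]
    track = list(track_coords) if track_coords is not None else []

    states = model.sample_initial(rng, n_particles)
    if model.proposal is not None:
        init_ratio = np.asarray(model.proposal.initial_log_ratio(states))
    else:
        init_ratio = None
    cloud = MtuCloud.initial(states, len(obs), t0)
    extra_logw = (init_ratio if init_ratio is not None
                  else np.zeros(n_particles))
    # support boundaries and t_end are forced grid points
    bounds = set()
    for o in obs:
        lo, hi = o.time_density.support
        for b in (lo, hi):
            if t0 < b < t_end:
                bounds.add(b)
    bounds.add(t_end)
    breakpoints = np.array(sorted(bounds))

    log_prefactor = 0.0  # sum over resampling events of log(sum v / N)
    logw = combined_log_weights(cloud) + extra_logw
    ess_now = ess_from_log_weights(logw)
    ess_prev = ess_now

    times: List[float] = [t0]
    ess_tr: List[float] = [ess_now]
    ll_tr: List[float] = [_loglik(log_prefactor, logw)]
    dts: List[float] = [np.nan]
    quant: dict = {names[c]: [weighted_quantile(states[:, c],
                                                np.exp(logw - logw.max()))]
                   for c in track}
    events: List[Tuple[float, float, float]] = []
    t = t0
    steps_since_record = 0
    prior_sampling = model.proposal is None

    while t < t_end - 1e-15:
        nxt = breakpoints[np.searchsorted(breakpoints, t + 1e-15)]
        g_lin = _eval_g(cloud, obs, t)
        cloud_logw_extra = extra_logw
        # adaptive_stepsize predicts from the cloud only (prior kernel);
        # with a non-prior proposal prediction is skipped (interp guess only)
        dt = _choose_dt(ess_now, ess_prev, cloud, obs, cfg, g_lin,
                        dt_cap=nxt - t, predict=prior_sampling,
                        extra_logw=cloud_logw_extra)
        # advance states, then integrate the partial weights (explicit
        # Euler: integrand at the left endpoint, independent of new states)
        new_states = model.step(cloud.states, t, dt, rng)
        if model.proposal is not None:
            extra_logw = extra_logw + np.asarray(
                model.proposal.log_density_ratio(new_states, cloud.states,
                                                 t, t + dt))
        partial_weight_step(cloud, obs, t, dt, g_lin=g_lin)
        cloud.states = new_states
        t = t + dt if t + dt < nxt - 1e-12 else float(nxt)
        cloud.time = t

        logw = combined_log_weights(cloud) + extra_logw
        ess_prev, ess_now = ess_now, ess_from_log_weights(logw)
        ess_pre_resample = ess_now  # what the trace records (degeneracy
        # diagnostics are about the cloud before any rescue)

        if ess_now < threshold:
            m = logw.max()
            v = np.exp(logw - m)
            sum_v_log = m + np.log(v.sum())
            events.append((t, ess_now, float(np.exp(sum_v_log))))
            sample = WeightedSample(cloud.states, v, t)
            idx, _ = resample(sample, v, rcfg.scheme, rng)
            cloud.states = cloud.states[idx].copy()
            cloud.w_bar = cloud.w_bar[:, idx].copy()
            # select the cumulative products alongside the states and
            # multiply by the selection weights: v = w/v_bar, so
            # v_bar_new = v_bar[idx] * v[idx], i.e. + logw[idx] in logs,
            # which makes every corrected weight exactly 1 after selection
            cloud.log_v_bar = cloud.log_v_bar[idx] + logw[idx]
            extra_logw = extra_logw[idx]
            log_prefactor += sum_v_log - np.log(n_particles)
            log.info("resampled at t=%.6g: ESS %.1f -> %.1f", t, ess_now,
                     float(n_particles))
            logw = combined_log_weights(cloud) + extra_logw
            ess_now = ess_from_log_weights(logw)

        steps_since_record += 1
        if steps_since_record >= record_every or t >= t_end - 1e-15:
            steps_since_record = 0
            times.append(t)
            ess_tr.append(ess_pre_resample)
            ll_tr.append(_loglik(log_prefactor, logw))
            dts.append(dt)
            if track:
                w_lin = np.exp(logw - logw.max())
                for c in track:
                    quant[names[c]].append(
                        weighted_quantile(cloud.states[:, c], w_lin))

    w_final = np.exp(logw - logw.max())
    return FilterTrace(
        times=np.asarray(times),
        ess=np.asarray(ess_tr),
        loglik=np.asarray(ll_tr),
        stepsizes=np.asarray(dts),
        quantiles={k: np.asarray(v) for k, v in quant.items()},
        resampling_events=events,
        final_states=cloud.states,
        final_weights=w_final,
        coord_names=list(names),
        metadata={"log_prefactor": log_prefactor},
    )


def _eval_g(cloud: MtuCloud, obs: Sequence[Observation], t: float
            ) -> np.ndarray:
    """g_j(y_j | x_t, t) for every observation active at t, (M, n)."""
    g = np.zeros((len(obs), cloud.n_particles))
    for j, o in enumerate(obs):
        lo, hi = o.time_density.support
        if lo <= t < hi:
            # runaway particles (overflowed states) count as impossible
            with np.errstate(over="ignore"):
                g[j] = np.exp(obs_log_g_safe(o, cloud.states, t))
    return g


def _choose_dt(ess_now, ess_prev, cloud, obs, cfg, g_lin, dt_cap, predict,
               extra_logw):
    n = cloud.n_particles
    drop = min(max(ess_prev - ess_now, 0.0), n - 1.0)
    frac = drop / (n - 1.0) if n > 1 else 0.0
    dt = cfg.dt_max - (cfg.dt_max - cfg.dt_min) * frac
    dt = min(dt, dt_cap)
    if predict:
        while dt > cfg.dt_min:
            if _predict_ess_with_extra(cloud, obs, dt, g_lin, extra_logw) \
                    >= (1.0 - cfg.rel_drop) * ess_now:
                break
            dt = dt / 2.0
    dt = max(dt, cfg.dt_min)
    return min(dt, dt_cap)


def _predict_ess_with_extra(cloud, obs, dt, g_lin, extra_logw):
    if not np.any(extra_logw):
        return predict_ess(cloud, obs, dt, g_lin)
    tmp = MtuCloud(states=cloud.states, gamma_bar=cloud.gamma_bar.copy(),
                   w_bar=cloud.w_bar.copy(),
                   log_v_bar=cloud.log_v_bar - extra_logw, time=cloud.time)
    return predict_ess(tmp, obs, dt, g_lin)


def _loglik(log_prefactor: float, logw: np.ndarray) -> float:
    m = logw.max()
    if not np.isfinite(m):
        return -np.inf
    return float(log_prefactor + m + np.log(np.exp(logw - m).sum())
                 - np.log(logw.size))
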