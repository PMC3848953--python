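"""Standard particle filter: sequential importance sampling with resampling.

Measurement times are fixed and known.  Between measurements the particle
cloud is propagated on a fixed Euler–Maruyama grid; at each measurement
time t_k the unnormalized weights are multiplied by the observation
density g_k(y_k | x, t_k) (times the proposal density ratio when a
non-bootstrap proposal is used), resampling is triggered when the
effective sample size drops below a threshold, and the data-likelihood
estimate is accumulated recursively from the weight ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .models import StateSpaceModel
from .observations import Observation
from .trace import QUANTILES, FilterTrace, weighted_quantile

__all__ = [
    "WeightedSample",
    "ResampleConfig",
    "DegeneracyError",
    "ess",
    "resample",
    "likelihood_ratio_update",
    "log_likelihood_ratio_update",
    "filter_expectation",
    "run_standard_filter",
]

log = logging.getLogger(__name__)


class DegeneracyError(RuntimeError):
    """All particle weights vanished; the filter cannot continue."""

    def __init__(self, message: str, trace: Optional[FilterTrace] = None):
        super().__init__(message)
        self.trace = trace


@dataclass
class WeightedSample:
    states: np.ndarray      # (n, dim)
    weights: np.ndarray     # (n,) unnormalized, nonnegative
    time: float

    def normalized(self) -> np.ndarray:
        total = self.weights.sum()
        if not total > 0:
            raise DegeneracyError("all particle weights are zero")
        return self.weights / total


@dataclass
class ResampleConfig:
    scheme: str = "systematic"   # multinomial | stratified | systematic
    threshold: Optional[float] = None   # default n/2

    def __post_init__(self):
        if self.scheme not in ("multinomial", "stratified", "systematic"):
            raise ValueError(f"unknown resampling scheme {self.scheme!r}")

    def threshold_for(self, n: int) -> float:
        thr = n / 2 if self.threshold is None else self.threshold
        if not 0 < thr <= n:
            raise ValueError(f"threshold {thr} outside (0, {n}]")
        return thr


def ess(weights: np.ndarray) -> float:
    """Effective sample size 1 / sum(normalized weights^2), in [1, N]."""
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if not total > 0:
        raise DegeneracyError("all particle weights are zero")
    wn = w / total
    return float(1.0 / np.sum(wn * wn))


def ess_from_log_weights(logw: np.ndarray) -> float:
    """ESS computed from log-scale weights (shift-invariant)."""
    m = np.max(logw)
    if not np.isfinite(m):
        raise DegeneracyError("all combined weights are zero")
    w = np.exp(logw - m)
    s = w.sum()
    return float(s * s / np.sum(w * w))


def _select_indices(p: np.ndarray, scheme: str,
                    rng: np.random.Generator) -> np.ndarray:
    n = p.size
    if scheme == "multinomial":
        return rng.choice(n, size=n, p=p)
    cum = np.cumsum(p)
    cum[-1] = 1.0
    if scheme == "stratified":
        u = (np.arange(n) + rng.random(n)) / n
    else:  # systematic
        u = (np.arange(n) + rng.random()) / n
    return np.searchsorted(cum, u, side="left")


def resample(sample: WeightedSample, selection_weights: np.ndarray,
             scheme: str, rng: np.random.Generator
             ) -> Tuple[np.ndarray, WeightedSample]:
    """Select particles by v and correct the weights by w/v.

    Each index is selected with marginal probability v_i / sum(v); the
    corrected unnormalized weight of a selected particle is w/v evaluated
    at the selected index, which removes the selection bias.  With the
    original-PF choice v = w all corrected weights equal 1.
    """
    v = np.asarray(selection_weights, dtype=float)
    total = v.sum()
    if not total > 0:
        raise DegeneracyError("all selection weights are zero")
    idx = _select_indices(v / total, scheme, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(v[idx] > 0, sample.weights[idx] / v[idx], 0.0)
    new = WeightedSample(states=sample.states[idx].copy(),
                         weights=corrected, time=sample.time)
    return idx, new


def log_likelihood_ratio_update(prev_weights: np.ndarray, log_g: np.ndarray,
                                log_ratio: Optional[np.ndarray] = None
                                ) -> float:
    """Log of the estimated likelihood ratio Z_{t_k} / Z_{t_{k-1}}.

    log( sum(rho * g * w_prev) / sum(w_prev) ), computed through a
    log-sum-exp reduction so very small densities do not underflow.
    """
    w = np.asarray(prev_weights, dtype=float)
    lg = np.asarray(log_g, dtype=float)
    if log_ratio is not None:
        lg = lg + np.asarray(log_ratio, dtype=float)
    if w.shape != lg.shape:
        raise ValueError("weight and density arrays must have equal length")
    total = w.sum()
    if not total > 0:
        raise DegeneracyError("all particle weights are zero")
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
    m = np.max(lg + logw)
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.sum(np.exp(lg + logw - m)) / total))


def likelihood_ratio_update(prev_weights: np.ndarray, log_g: np.ndarray,
                            log_ratio: Optional[np.ndarray] = None) -> float:
    """Estimated likelihood ratio Z_{t_k} / Z_{t_{k-1}} on the linear scale."""
    out = log_likelihood_ratio_update(prev_weights, log_g, log_ratio)
    return float(np.exp(out))


def filter_expectation(sample: WeightedSample, h: Callable) -> float:
    """Weighted empirical filter expectation sum(w h(x)) / sum(w)."""
    vals = np.asarray([h(x) for x in sample.states], dtype=float)
    wn = sample.normalized()
    return float(np.sum(wn * vals))


def run_standard_filter(
    model: StateSpaceModel,
    observations: Sequence[Observation],
    n_particles: int,
    dt: float,
    resample_config: Optional[ResampleConfig] = None,
    rng: Optional[np.random.Generator] = None,
    t0: float = 0.0,
    t_end: Optional[float] = None,
    track_coords: Optional[Sequence[int]] = None,
) -> FilterTrace:
    """Run the standard particle filter with fixed measurement times.

    Observations are taken at their intended times, which must be strictly
    increasing; grid steps are split so every measurement time is hit
    exactly.  Returns a :class:`FilterTrace` holding the ESS and cumulative
    log-likelihood over the grid and the final weighted cloud.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    cfg = resample_config or ResampleConfig()
    threshold = cfg.threshold_for(n_particles)

    # ties are allowed (population data: several patients share nominal
    # times); tied observations are applied at the same grid point
    obs = sorted(observations, key=lambda o: o.intended_time)
    obs_times = np.array([o.intended_time for o in obs])
    if obs_times.size and not np.all(np.diff(obs_times) >= 0):
        raise ValueError("observation times must be nondecreasing")
    if obs_times.size and obs_times[0] <= t0:
        raise ValueError("observation times must exceed t0")
    if t_end is None:
        t_end = float(obs_times[-1]) if obs_times.size else t0
    names = model.coord_names or [f"x{i}" for i in range(model.dim)]
    track = list(track_coords) if track_coords is not None else []

    # all weight arithmetic is carried in log space: tiny observation
    # densities (e.g. a lumped sd far below the time-jitter scale) must
    # degrade the ESS, not underflow the whole cloud to zero
    states = model.sample_initial(rng, n_particles)
    logw = np.zeros(n_particles)
    if model.proposal is not None:
        logw = np.asarray(model.proposal.initial_log_ratio(states),
                          dtype=float)

    def lin(lw):
        return np.exp(lw - np.max(lw))

    times: List[float] = [t0]
    ess_tr: List[float] = [ess_from_log_weights(logw)]
    ll_tr: List[float] = [0.0]
    quant: dict = {names[c]: [weighted_quantile(states[:, c], lin(logw))]
                   for c in track}
    events: List[Tuple[float, float, float]] = []
    log_lik = 0.0

    # build the grid: regular steps split at measurement times and t_end
    cuts = np.unique(np.concatenate(
        [obs_times[obs_times <= t_end], [t_end]]))
    next_obs = 0
    t = t0
    while t < t_end - 1e-15:
        t_cut = cuts[np.searchsorted(cuts, t + 1e-15)]
        step = min(dt, t_cut - t)
        new_states = model.step(states, t, step, rng)
        if model.proposal is not None:
            ratio = np.asarray(model.proposal.log_density_ratio(
                new_states, states, t, t + step), dtype=float)
        else:
            ratio = None
        states = new_states
        t = t + step if t + step < t_cut - 1e-12 else t_cut
        # measurement update
        while next_obs < len(obs) and abs(obs[next_obs].intended_time - t) < 1e-12:
            o = obs[next_obs]
            lg = o.log_g(states, t)
            lg = np.where(np.isnan(lg), -np.inf, lg)
            logw_new = logw + lg + (ratio if ratio is not None else 0.0)
            if not np.any(np.isfinite(logw_new)):
                raise DegeneracyError(
                    f"all weights vanished at measurement {o.index} (t={t:g})",
                    trace=_make_trace(times, ess_tr, ll_tr, quant, events,
                                      states, lin(logw), names),
                )
            log_lik += log_likelihood_ratio_update(lin(logw), lg, ratio)
            logw = logw_new
            next_obs += 1
        cur_ess = ess_from_log_weights(logw)
        ess_pre_resample = cur_ess  # traces show the cloud before rescue
        if cur_ess < threshold:
            v = lin(logw)
            events.append((t, cur_ess, float(v.sum())))
            sample = WeightedSample(states, v, t)
            idx, sample = resample(sample, v, cfg.scheme, rng)
            log.info("resampled at t=%.6g: ESS %.1f -> %.1f", t, cur_ess,
                     float(n_particles))
            # selection weights equal the particle weights, so the
            # corrected log-weights are all equal after selection
            states = sample.states
            logw = np.zeros(n_particles)
        times.append(t)
        ess_tr.append(ess_pre_resample)
        ll_tr.append(log_lik)
        for c in track:
            quant[names[c]].append(
                weighted_quantile(states[:, c], lin(logw)))

    return _make_trace(times, ess_tr, ll_tr, quant, events, states,
                       lin(logw), names)


def _make_trace(times, ess_tr, ll_tr, quant, events, states, weights,
                names) -> FilterTrace:
    return FilterTrace(
        times=np.asarray(times),
        ess=np.asarray(ess_tr),
        loglik=np.asarray(ll_tr),
        quantiles={k: np.asarray(v) for k, v in quant.items()},
        resampling_events=events,
        final_states=states,
        final_weights=weights,
        coord_names=list(names),
    )
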