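"""Observation value densities g_j and measurement-time densities gamma_j.

Each observation j carries a measured value y_j, a conditional log-density
``log g_j(y_j | x_t, t)`` of the value given the state, and a
:class:`TimeDensity` describing where on the time axis the measurement may
actually have been taken.  For the standard particle filter the time
density degenerates to the intended time; for the MTU filter its pdf/cdf
drive the partial-weight ODEs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "TimeDensity",
    "Observation",
    "truncated_normal_time_density",
    "clipped_normal_time_density",
    "gaussian_value_density",
    "lognormal_ratio_density",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class TimeDensity:
    """Probability density of a measurement time on [t0, inf).

    pdf vanishes outside ``support``; cdf runs from 0 at the lower support
    bound and is nondecreasing.  The cdf is the analytic antiderivative
    whenever the constructor can supply one.  ``total_mass`` is normally 1;
    a *deficient* density (total mass < 1) models a measurement window that
    extends before the observation horizon: the missing mass is the chance
    that the measurement predates t0, in which case it carries no
    information and the partial weight keeps a 1 - total_mass floor.
    """

    pdf: Callable[[float], float]
    cdf: Callable[[float], float]
    support: Tuple[float, float]
    total_mass: float = 1.0

    def __post_init__(self):
        lo, hi = self.support
        if not lo < hi:
            raise ValueError(f"empty time-density support [{lo}, {hi}]")
        if not 0.0 < self.total_mass <= 1.0:
            raise ValueError("total_mass must lie in (0, 1]")


@dataclass
class Observation:
    index: int
    value: float
    intended_time: float
    value_log_density: Callable  # (y, states (n,dim), t) -> (n,) log g
    time_density: Optional[TimeDensity] = None

    def log_g(self, states: np.ndarray, t: float) -> np.ndarray:
        return np.asarray(self.value_log_density(self.value, states, t), float)


def truncated_normal_time_density(t_hat: float, sd: float, lo: float,
                                  hi: float) -> TimeDensity:
    """Normal kernel with mean t_hat and std sd, truncated to [lo, hi]."""
    if not lo < hi:
        raise ValueError(f"empty support [{lo}, {hi}]")
    if sd <= 0:
        raise ValueError("sd must be positive")
    a, b = (lo - t_hat) / sd, (hi - t_hat) / sd
    dist = stats.truncnorm(a, b, loc=t_hat, scale=sd)

    def pdf(t):
        t = np.asarray(t, dtype=float)
        out = np.where((t < lo) | (t > hi), 0.0, dist.pdf(np.clip(t, lo, hi)))
        return out if out.ndim else float(out)

    def cdf(t):
        t = np.asarray(t, dtype=float)
        out = dist.cdf(np.clip(t, lo, hi))
        return out if out.ndim else float(out)

    return TimeDensity(pdf=pdf, cdf=cdf, support=(lo, hi))


def clipped_normal_time_density(t_hat: float, sd: float, halfwidth: float,
                                t0: float) -> TimeDensity:
    """Normal kernel truncated at t_hat +- halfwidth, clipped (not
    renormalized) at the observation start t0.

    The density is normalized over the symmetric window; when t0 cuts into
    it, the mass below t0 is *not* redistributed: the measurement may have
    occurred before observation began, and that event is uninformative.
    The returned density is then deficient (total_mass < 1).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    win_lo, hi = t_hat - halfwidth, t_hat + halfwidth
    if hi <= t0:
        raise ValueError("measurement window lies entirely before t0")
    a, b = -halfwidth / sd, halfwidth / sd
    dist = stats.truncnorm(a, b, loc=t_hat, scale=sd)
    lo = max(win_lo, t0)
    pre_mass = float(dist.cdf(lo))

    def pdf(t):
        t = np.asarray(t, dtype=float)
        out = np.where((t < lo) | (t > hi), 0.0, dist.pdf(np.clip(t, lo, hi)))
        return out if out.ndim else float(out)

    def cdf(t):
        t = np.asarray(t, dtype=float)
        out = dist.cdf(np.clip(t, lo, hi)) - pre_mass
        return out if out.ndim else float(out)

    return TimeDensity(pdf=pdf, cdf=cdf, support=(lo, hi),
                       total_mass=1.0 - pre_mass)


def gaussian_value_density(y, q, sigma_y: float):
    """Log-density of y ~ N(q, sigma_y^2); vectorized over q."""
    if sigma_y <= 0:
        raise ValueError("sigma_y must be positive")
    q = np.asarray(q, dtype=float)
    z = (y - q) / sigma_y
    return -0.5 * z * z - np.log(sigma_y) - 0.5 * _LOG_2PI


def lognormal_ratio_density(y1, q1, Q1, p1: float, sigma: float):
    """Log-density of the tracer/tracee ratio observation.

    y1 = p1 * (q1/Q1) * xi with xi ~ Log-N(0, sigma^2), i.e.
    log y1 ~ N(log(p1*q1/Q1), sigma^2), including the 1/y1 Jacobian.
    Particles with q1 <= 0 cannot produce a positive ratio and get
    log-density -inf (documented contract, not an exception).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if np.any(np.asarray(Q1) <= 0):
        raise ValueError("Q1 must be positive")
    if np.any(np.asarray(y1) <= 0):
        raise ValueError("y1 must be positive")
    q1 = np.asarray(q1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.log(p1) + np.log(q1) - np.log(Q1)
        z = (np.log(y1) - mu) / sigma
        out = -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI - np.log(y1)
    return np.where(q1 > 0, out, -np.inf) if np.ndim(q1) else (
        float(out) if q1 > 0 else -np.inf
    )
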