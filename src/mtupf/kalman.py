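"""Maximum-likelihood baseline: exact Kalman filtering for the linear model.

The one-state example dq = (-alpha q + beta) dt + sigma dW with Gaussian
observations at fixed times is, conditioned on the initial state and the
parameters, Gaussian linear, so the continuous/discrete Kalman filter is
exact: between measurements the moments follow the linear moment ODEs

    m' = -alpha m + beta,      P' = -2 alpha P + sigma^2,

which integrate in closed form; at a measurement the standard scalar
update applies.  The negative log-likelihood is the prediction-error
decomposition  1/2 sum_j [log det R_j + eps_j^2 / R_j] + (M/2) log 2 pi.
Maximum-likelihood estimation minimizes it locally from prior-sampled
starting values (log-reparameterized to keep alpha, beta positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

__all__ = [
    "kalman_filter_linear",
    "negative_log_likelihood",
    "ml_estimate",
    "MlRunResult",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _ou_moments(m0: float, p0: float, alpha: float, beta: float,
                sigma: float, dt: float) -> Tuple[float, float]:
    """Closed-form mean/variance propagation of the linear SDE over dt."""
    if alpha == 0.0:
        return m0 + beta * dt, p0 + sigma * sigma * dt
    e = np.exp(-alpha * dt)
    mean = beta / alpha + (m0 - beta / alpha) * e
    var = p0 * e * e + sigma * sigma / (2.0 * alpha) * (1.0 - e * e)
    return float(mean), float(var)


def kalman_filter_linear(alpha: float, beta: float, sigma: float,
                         q0: float, times: Sequence[float],
                         values: Sequence[float], sigma_y: float,
                         t0: float = 0.0, p0: float = 0.0
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Exact continuous/discrete Kalman recursion.

    Returns the per-observation residuals eps_j = y_j - yhat_{j|j-1} and
    the predicted observation variances R_{j|j-1} = P_pred + sigma_y^2.
    The initial state is the fixed value q0 (variance p0, default 0).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size and not np.all(np.diff(times) > 0):
        raise ValueError("observation times must be strictly increasing")
    if sigma_y <= 0:
        raise ValueError("sigma_y must be positive")
    m, p = float(q0), float(p0)
    t = t0
    residuals = np.empty(times.size)
    R = np.empty(times.size)
    for j, (tj, yj) in enumerate(zip(times, values)):
        m, p = _ou_moments(m, p, alpha, beta, sigma, tj - t)
        R[j] = p + sigma_y * sigma_y
        if R[j] <= 0 or not np.isfinite(R[j]):
            raise FloatingPointError("singular predicted observation "
                                     f"variance at observation {j}")
        residuals[j] = yj - m
        gain = p / R[j]
        m = m + gain * residuals[j]
        p = p * (1.0 - gain)
        t = tj
    return residuals, R


def negative_log_likelihood(theta: Sequence[float], q0: float,
                            times: Sequence[float],
                            values: Sequence[float], sigma: float,
                            sigma_y: float) -> float:
    """Prediction-error NLL of (alpha, beta) given the fixed initial state."""
    alpha, beta = theta
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return 0.0
    eps, R = kalman_filter_linear(alpha, beta, sigma, q0, times, values,
                                  sigma_y)
    return float(0.5 * np.sum(np.log(R) + eps * eps / R)
                 + 0.5 * times.size * _LOG_2PI)


@dataclass
class MlRunResult:
    alpha: float
    beta: float
    nll: float
    q0: float
    converged: bool


def ml_estimate(times: Sequence[float], values: Sequence[float],
                sigma: float, sigma_y: float,
                rng: np.random.Generator, n_runs: int = 100,
                prior_log_medians: Tuple[float, float] = (np.log(2.0),
                                                          np.log(6.0)),
                prior_log_sd: float = 1.0,
                q0_log_mean: float = 0.0, q0_log_sd: float = 0.1,
                tol: float = 1e-8) -> List[MlRunResult]:
    """Repeated local ML estimation from prior-sampled starting points.

    Per run: draw (alpha, beta) starting values from the log-normal
    priors and q0 from its true initial distribution, then minimize the
    NLL over log(alpha), log(beta) with the sampled q0 held fixed.
    Optimizer non-convergence is flagged in the result, not raised.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results: List[MlRunResult] = []
    for _ in range(n_runs):
        la0 = prior_log_medians[0] + prior_log_sd * rng.standard_normal()
        lb0 = prior_log_medians[1] + prior_log_sd * rng.standard_normal()
        q0 = float(np.exp(q0_log_mean + q0_log_sd * rng.standard_normal()))

        def nll_log(z):
            with np.errstate(over="ignore"):
                return negative_log_likelihood(np.exp(z), q0, times, values,
                                               sigma, sigma_y)

        res = optimize.minimize(nll_log, np.array([la0, lb0]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": tol,
                                         "maxiter": 2000})
        alpha, beta = np.exp(res.x)
        results.append(MlRunResult(float(alpha), float(beta),
                                   float(res.fun), q0, bool(res.success)))
    return results
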