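"""Four-compartment tracer/tracee plasma-leucine kinetics with mixed effects.

A bolus of labelled leucine (tracer, mass q_i in mg per compartment) is
injected into plasma (compartment 1) and exchanges with an intrahepatic
compartment (2) and two body-protein pools (3, 4); outputs leave from
compartment 1 (degradation, rate k01) and compartment 2 (towards apoB
synthesis, fixed rate k11_2 = 0.01/h).  Each internal flux k_{j,i} carries
its source compartment's noise grouping (q_i dt + sigma_i dW_i), so
internal transport conserves tracer mass both in drift and in noise; only
the two output channels remove mass.

The endogenous leucine (tracee, Q_i) is in steady state with constant
input U1, giving the closed form

    Q1 = (k11_2 + k12) U1 / (k01 (k11_2 + k12) + k11_2 k12).

The measured quantity is the plasma tracer/tracee ratio
y1 = p1 q1/Q1 * xi with log-normal noise xi ~ Log-N(0, sigma_y1^2).
Mixed effects: the degradation rate splits into group means (k01_c
control, k01_d diabetes) times a per-patient log-normal factor
zeta_p = exp(eta_p), eta_p ~ N(0, sigma_eta^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .augmentation import ArtificialDynamics, ParameterSpec, \
    build_augmented_model
from .models import StateSpaceModel
from .observations import Observation, lognormal_ratio_density, \
    truncated_normal_time_density

__all__ = [
    "LeucineParams",
    "PatientRecord",
    "leucine_drift_diffusion",
    "steady_state_Q1",
    "patient_k01",
    "read_population_file",
    "write_population_file",
    "build_population_model",
    "PopulationConfig",
]

#: fixed constants (identifiability): apoB-synthesis drain, plasma fraction,
#: diffusion parameters, observation noise sd (of log xi)
K11_2 = 0.01     # 1/h
P1 = 0.65
SIGMA_I = (3.0, 3.0, 3.0, 3.0)
SIGMA_Y1 = 0.5

#: measurement-time density of the study: sd 0.001 h, truncated +-0.01 h
TIME_SD = 0.001
TIME_HALFWIDTH = 0.01


@dataclass
class LeucineParams:
    """Transfer coefficients (1/h) and tracee input (mg/h).

    Derived constraints k21 = k12 and k34 = 0.1 k43 hold by construction;
    only the free coefficients are stored.
    """

    k01_c: float
    k01_d: float
    k12: float
    k13: float
    k31: float
    k43: float
    U1: float

    def __post_init__(self):
        for name in ("k01_c", "k01_d", "k12", "k13", "k31", "k43", "U1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k21(self) -> float:
        return self.k12

    @property
    def k34(self) -> float:
        return 0.1 * self.k43


@dataclass
class PatientRecord:
    id: str
    group: str                   # "control" | "diabetes"
    u10: float                   # tracer bolus (mg), sets q1(0)
    times: List[float]
    values: List[float]

    def __post_init__(self):
        if self.group not in ("control", "diabetes"):
            raise ValueError(f"unknown group label {self.group!r}")
        if len(self.times) != len(self.values):
            raise ValueError(
                f"patient {self.id}: {len(self.times)} times vs "
                f"{len(self.values)} values")
        t = np.asarray(self.times, dtype=float)
        if t.size and (np.any(t < 0) or np.any(np.diff(t) < 0)):
            raise ValueError(f"patient {self.id}: times must be "
                             "nonnegative and nondecreasing")
        if any(v <= 0 for v in self.values):
            raise ValueError(f"patient {self.id}: values must be positive")


def _flux_matrix(k01, k12, k13, k31, k43):
    """Net flux-coefficient matrix A with drift = A q (columns = source)."""
    return np.array([
        [-(k12 + k01 + k31), k12,            k13,               0.0],
        [k12,               -(K11_2 + k12),  0.0,               0.0],
        [k31,                0.0,           -(k13 + k43),  0.1 * k43],
        [0.0,                0.0,            k43,         -0.1 * k43],
    ])


def leucine_drift_diffusion(q: np.ndarray, params: LeucineParams,
                            k01: Optional[float] = None
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Drift vector and structured 4x4 diffusion matrix at state q.

    Each flux term carries the grouping (q_i dt + sigma_i dW_i) of its
    source compartment i, so column i of the diffusion matrix is sigma_i
    times the net flux-coefficient vector of compartment i.
    """
    if k01 is None:
        k01 = params.k01_c
    A = _flux_matrix(k01, params.k12, params.k13, params.k31, params.k43)
    q = np.asarray(q, dtype=float)
    drift = q @ A.T if q.ndim == 2 else A @ q
    diffusion = A * np.asarray(SIGMA_I)[None, :]
    return drift, diffusion


def steady_state_Q1(params: LeucineParams, k01: float) -> float:
    """Steady-state plasma tracee mass Q1 (mg) for constant input U1."""
    denom = k01 * (K11_2 + params.k12) + K11_2 * params.k12
    if denom <= 0:
        raise ValueError("steady-state denominator must be positive")
    return (K11_2 + params.k12) * params.U1 / denom


def patient_k01(group: str, zeta_p: float, k01_c: float,
                k01_d: float) -> float:
    """Patient degradation rate: zeta_p times the group mean."""
    if zeta_p <= 0:
        raise ValueError("zeta_p must be positive")
    if group == "diabetes":
        return zeta_p * k01_d
    if group == "control":
        return zeta_p * k01_c
    raise ValueError(f"unknown group label {group!r}")


# ---------------------------------------------------------------------------
# population file IO ("Additional file 1" dialect): one record per patient,
#   id,group,u10 \n times... \n values... \n blank line

def read_population_file(path) -> List[PatientRecord]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    records: List[PatientRecord] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            header = [s.strip() for s in lines[i].split(",")]
            if len(header) != 3:
                raise ValueError(f"expected 'id,group,initial', got "
                                 f"{lines[i]!r}")
            pid, group, u10 = header[0], header[1], float(header[2])
            times = [float(s) for s in lines[i + 1].split(",")]
            values = [float(s) for s in lines[i + 2].split(",")]
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"{path}: parse error in record starting at line {i + 1}: "
                f"{exc}") from exc
        try:
            records.append(PatientRecord(pid, group, u10, times, values))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 1}: {exc}") from exc
        i += 3
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate patient ids")
    return records


def write_population_file(records: Sequence[PatientRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.id},{r.group},{r.u10!r}\n")
            fh.write(",".join(repr(float(t)) for t in r.times) + "\n")
            fh.write(",".join(repr(float(v)) for v in r.values) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# population model: augmented state (q^(1:P), shared params, eta_(1:P))

_SHARED = ("k01_c", "k01_d", "k12", "k13", "k31", "k43", "U1")


@dataclass
class PopulationConfig:
    """Priors and artificial-dynamics settings for a population run."""

    # prior log-sd for the shared log-normal priors
    prior_sd: float = 1.0
    U1_prior_median: float = 100.0
    eta_prior_sd: float = 0.5
    # artificial-noise interpolation points: sigma(t1) = sigma(t0)/10 at t1=2h
    noise_t0: float = 0.0
    noise_t1: float = 2.0
    noise_sigma0: float = 0.5
    noise_sigma0_eta: float = 1.0
    estimate_parameters: bool = True
    fixed: Optional[Dict[str, float]] = None  # used when not estimating


def build_population_model(records: Sequence[PatientRecord],
                           config: Optional[PopulationConfig] = None
                           ) -> Tuple[StateSpaceModel, List[Observation]]:
    """Augmented mixed-effects model coupling all patients.

    The state vector is (q_1:4 per patient, 7 shared parameters, one eta
    per patient): dimension 4P + 7 + P.  Patient p's initial condition is
    (u10_p, 0, 0, 0); the shared flux parameters enter every patient's
    drift, and patient p's degradation rate is exp(eta_p) times the group
    mean.  Returns the model and the ratio observations with their
    truncated-normal time densities.
    """
    cfg = config or PopulationConfig()
    records = list(records)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    P = len(records)
    nq = 4 * P
    sig = np.asarray(SIGMA_I)

    def drift(q, theta, t):
        out = np.empty_like(q)
        k01c, k01d, k12, k13, k31, k43 = (theta[:, i] for i in range(6))
        for p, rec in enumerate(records):
            grp = k01d if rec.group == "diabetes" else k01c
            k01 = np.exp(theta[:, 7 + p]) * grp
            qp = q[:, 4 * p:4 * p + 4]
            out[:, 4 * p + 0] = (-(k12 + k01 + k31) * qp[:, 0]
                                 + k12 * qp[:, 1] + k13 * qp[:, 2])
            out[:, 4 * p + 1] = (k12 * qp[:, 0] - (K11_2 + k12) * qp[:, 1])
            out[:, 4 * p + 2] = (k31 * qp[:, 0] - (k13 + k43) * qp[:, 2]
                                 + 0.1 * k43 * qp[:, 3])
            out[:, 4 * p + 3] = (k43 * qp[:, 2] - 0.1 * k43 * qp[:, 3])
        return out

    def diffusion(q, theta, t):
        n = q.shape[0]
        out = np.zeros((n, nq, nq))
        k01c, k01d, k12, k13, k31, k43 = (theta[:, i] for i in range(6))
        for p, rec in enumerate(records):
            grp = k01d if rec.group == "diabetes" else k01c
            k01 = np.exp(theta[:, 7 + p]) * grp
            s = slice(4 * p, 4 * p + 4)
            blk = np.zeros((n, 4, 4))
            blk[:, 0, 0] = -(k12 + k01 + k31)
            blk[:, 0, 1] = k12
            blk[:, 0, 2] = k13
            blk[:, 1, 0] = k12
            blk[:, 1, 1] = -(K11_2 + k12)
            blk[:, 2, 0] = k31
            blk[:, 2, 2] = -(k13 + k43)
            blk[:, 2, 3] = 0.1 * k43
            blk[:, 3, 2] = k43
            blk[:, 3, 3] = -0.1 * k43
            out[:, s, s] = blk * sig[None, None, :]
        return out

    def initial_q(rng, n):
        q0 = np.zeros((n, nq))
        for p, rec in enumerate(records):
            q0[:, 4 * p] = rec.u10
        return q0

    if cfg.estimate_parameters:
        geo = ArtificialDynamics.from_interpolation(
            "geometric", cfg.noise_t0, cfg.noise_sigma0, cfg.noise_t1,
            cfg.noise_sigma0 / 10.0)
        add = ArtificialDynamics.from_interpolation(
            "additive", cfg.noise_t0, cfg.noise_sigma0_eta, cfg.noise_t1,
            cfg.noise_sigma0_eta / 10.0)

        def lognormal_prior(median):
            return lambda rng, n: np.exp(
                np.log(median) + cfg.prior_sd * rng.standard_normal(n))

        specs = [ParameterSpec(name, lognormal_prior(1.0), geo)
                 for name in _SHARED[:-1]]
        specs.append(ParameterSpec(
            "U1", lognormal_prior(cfg.U1_prior_median), geo))
        specs += [
            ParameterSpec(
                f"eta_{rec.id}",
                lambda rng, n, sd=cfg.eta_prior_sd: sd * rng.standard_normal(n),
                add)
            for rec in records
        ]
    else:
        fixed = cfg.fixed or {}
        missing = [k for k in _SHARED if k not in fixed]
        if missing:
            raise ValueError(f"fixed parameter values missing: {missing}")
        frozen_g = ArtificialDynamics.frozen("geometric")
        frozen_a = ArtificialDynamics.frozen("additive")
        specs = [ParameterSpec(
            name, lambda rng, n, v=fixed[name]: np.full(n, v), frozen_g)
            for name in _SHARED]
        specs += [ParameterSpec(
            f"eta_{rec.id}",
            lambda rng, n, v=fixed.get(f"eta_{rec.id}", 0.0): np.full(n, v),
            frozen_a)
            for rec in records]

    state_names = [f"q{i+1}_{rec.id}" for rec in records for i in range(4)]
    model = build_augmented_model(
        dynamic_dim=nq, drift=drift, diffusion=diffusion,
        initial_sampler=initial_q, parameters=specs,
        state_names=state_names, wiener_dim=nq)

    observations: List[Observation] = []
    idx = 0
    for p, rec in enumerate(records):
        diabetic = rec.group == "diabetes"

        def log_density(y, states, t, p=p, diabetic=diabetic):
            q1 = states[:, 4 * p]
            th = states[:, nq:]
            k01_grp = th[:, 1] if diabetic else th[:, 0]
            k01 = np.exp(th[:, 7 + p]) * k01_grp
            k12, U1 = th[:, 2], th[:, 6]
            # per-particle steady-state tracee mass
            denom = k01 * (K11_2 + k12) + K11_2 * k12
            Q1 = (K11_2 + k12) * U1 / denom
            return lognormal_ratio_density(y, q1, Q1, P1, SIGMA_Y1)

        for t_hat, y in zip(rec.times, rec.values):
            lo = max(0.0, t_hat - TIME_HALFWIDTH)
            td = truncated_normal_time_density(
                t_hat, TIME_SD, lo, t_hat + TIME_HALFWIDTH)
            observations.append(Observation(
                index=idx, value=y, intended_time=t_hat,
                value_log_density=log_density, time_density=td))
            idx += 1
    return model, observations
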