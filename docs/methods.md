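# Methods

## State-space model

The state process is an Itô SDE dX_t = a(X_t, t) dt + B(X_t, t) dW_t on
[t0, ∞), simulated with the Euler–Maruyama scheme (`StateSpaceModel.step`;
models may override the transition with an exact sampler where one exists).
Observations are value densities g_j(y_j | x_t, t); measurement times are
random with densities γ_j carrying a pdf, an analytic cdf and a compact
support.  Time is in hours throughout; the filters never step across a
support boundary or the final time — those points are forced onto the grid.

## Standard particle filter

Sequential importance sampling from the model kernel (bootstrap proposal;
a `ProposalKernel` with pointwise log density ratios is supported), weight
update w ← ϱ·g·w at each measurement time, systematic resampling by default
(stratified and multinomial available) triggered when the ESS
1/Σ(normalized w)² falls below a threshold (default N/2), with the exact
w/v weight correction.  All weight arithmetic is in log space: with very
small measurement variances every g underflows linear doubles, and the
correct behaviour is a collapsed ESS — not a crash.  The marginal data
likelihood is accumulated recursively from the ratio estimates
Σ(ϱ·g·w)/Σw (log-sum-exp).

## MTU particle filter

Each observation j contributes a partial weight
w_{j,t} = 1 − γ̄_{j,t} + w̄_{j,t}; the particle weight is the product over
observations divided by the cumulative selection-weight product v̄
introduced by resampling.  Numerical choices:

- γ̄ always comes from the analytic cdf (users without a closed form can
  supply a numerically accumulated one).  The split 1 − γ̄ + w̄ avoids the
  catastrophic accumulation of (g−1)·γ when g is tiny.
- w̄ advances by g(x_t, t)·(G(t+Δ) − G(t)): the left-endpoint value of g
  times the exact time-density mass of the step.  This rule is exact for
  g constant over the step regardless of how sharply γ is peaked; the
  naive g·γ(t)·Δ rule requires steps far below the density's width (the
  leucine time densities have sd 0.001 h) and noticeably biases the
  likelihood there.
- Per-observation factors are summed as logs; a factor exactly 0 marks a
  particle impossible without poisoning the others, and a zero factor can
  legitimately revive while the support is still open (w̄ may resume
  growing), which the ESS prediction handles by rebuilding the affected
  factors rather than adding log-increments.
- Resampling uses the current corrected combined weights as selection
  weights (the original-PF choice: corrected weights are exactly 1 after
  selection); v̄ is selected alongside the states and multiplied by the
  selection weight.  The likelihood estimate carries one factor
  Σv/N per resampling event, all in log space.
- NaN log-densities (runaway particles after an overflowed Euler step)
  are treated as −∞; such particles die at the next weight evaluation.

### Adaptive stepsize

The initial guess interpolates linearly between dt_max (no ESS change over
the last accepted step) and dt_min (ESS dropped by N−1), on the drop
clamped to [0, N−1] — the prose description fixes only the endpoints, so
the linear-in-drop form is this package's choice.  The guess is then
halved while the *predicted* ESS of the candidate step falls more than
10% (`rel_drop`) below the current ESS, with dt_min as a floor.  With the
bootstrap proposal the prediction needs no state sampling: the weight
increment depends only on the current states.  With a non-bootstrap
proposal the prediction loop is skipped and only the interpolation guess
is used.  Accepted steps always lie in [dt_min, dt_max] except where a
support boundary or the final time forces a shorter split.

## Parameter estimation by state augmentation

Static parameters join the state vector with artificial dynamics
dθ = θ·σ_θ(t)·dW (positive parameters; integrated by the exact geometric
increment θ·exp(σ√Δ·z − σ²Δ/2), which preserves positivity for every
draw) or dθ = σ_θ(t)·dW (real-valued parameters).  The decaying schedule
σ_θ(t) = a/(t−b)² is fixed by two interpolation points; with
r = √(σ0/σ1), b = t0 + (t1−t0)/(1−r) < t0 and a = σ0(t0−b)².  Estimates
are reported as weighted empirical medians of the final cloud with
(0.025, 0.25, 0.75, 0.975) quantiles.

An important consequence, documented because it shapes what the estimation
runs converge to: with artificial dynamics the filter targets the
posterior of a *time-varying* parameter path, not the static-parameter
posterior.  While σ_θ is non-negligible, the parameter cloud can drift
between early and late observations, and the final-time median leans
toward the late data and the prior.  On the one-state example (schedule
5.43/(t+3.29)², still ≈0.03 at t=10) this shifts the final α median
upward by roughly 10% relative to the exact static posterior computed by
an independent Kalman-quadrature oracle.  Users who want the static
posterior should shrink the late-time σ_θ faster than this default.

## The one-state example

dq = (−αq + β) dt + σ dW with σ=0.05, q0 ~ Log-N(0, 0.1²), Gaussian value
noise sd 0.005, intended times (0.5, 1, 2, 4) h, time densities
N(t̂, 0.3²) truncated at t̂ ± 1.  Where the ±1 window extends before the
observation start t0 = 0 (the t̂ = 0.5 observation), the density is
*clipped, not renormalized*: the ≈0.048 pre-t0 mass is the probability
that the measurement predates observation and carries no information, so
its partial weight keeps a 1 − γ̄_∞ floor.  This choice reproduces the
published comparison values; renormalizing instead shifts the exact
posterior for (α, β) from ≈(1.07, 3.15) to ≈(1.23, 3.61) (Kalman-oracle
grid computation).  Estimation uses priors α ~ Log-N(log 2, 1),
β ~ Log-N(log 6, 1), geometric artificial noise with the schedule above,
10,000 particles, steps in [10⁻⁶, 10⁻²] h, horizon 10 h.

## The plasma-leucine model

Four tracer compartments (plasma, intrahepatic, two protein pools) with
mass-conserving noise: each flux k_{j,i} carries its source compartment's
grouping (q_i dt + σ_i dW_i), so internal transport cancels in both drift
and diffusion columns and only the two output channels (k_{0,1} from
plasma, fixed k_{11,2}=0.01/h from the hepatic compartment) remove mass.
σ_i = 3 fixed; q(0) = (u_{1,0}, 0, 0, 0) from the bolus.  The tracee is
the analytic steady state Q1 = (k_{11,2}+k_{1,2})U1 /
(k_{0,1}(k_{11,2}+k_{1,2}) + k_{11,2}k_{1,2}) — no tracee dynamics are
integrated.  Output: y1 = p1·q1/Q1·ξ, ξ ~ Log-N(0, 0.5²), p1 = 0.65
fixed.  Mixed effects: k_{0,1}(p) = exp(η_p)·k_{0,1}^{group}, η_p ~
N(0, 0.5²) a priori.  The population model is one augmented state vector
(4 states per patient, 7 shared parameters, one η per patient); priors
Log-N(0,1) for the rates, Log-N(log 100, 1) for U1.  Time densities are
truncated normals with sd 0.001 h cut at ±0.01 h.  Euler noise may push
tracer masses negative; the ratio log-density returns −∞ for q1 ≤ 0,
which self-penalizes such particles — no clipping.  Default horizon 1 h.

## Synthetic data

`generate_motivating_dataset` simulates a true path at the example's
parameters, draws each actual time from its truncated-normal density
(conditioned on t ≥ t0) and each value from N(q(T_j), σ_y²);
`paper_dataset` returns the published realization used by the comparison
runs.  `generate_leucine_population` draws per-patient η_p, integrates
the tracer SDE at the patient's rate, jitters each nominal time by the
study's time density and applies the log-normal ratio noise; records
serialize bit-exactly through the population-file dialect, and the true
per-patient parameters go to a sidecar, never into the data file.  The
generators emulate the *structure* of the study (bolus design, two
groups, ratio output, early-dense sampling) but not its real biology —
passing recovery tests shows the estimation machinery works under the
model's own assumptions, not that the model fits real patients.  The
synthetic default schedule is 6–8 points in (0, 1] h; the real study
sampled to 8 h.

## ML baseline

For the linear example the continuous/discrete Kalman filter is exact
conditioned on (q0, θ): closed-form Ornstein–Uhlenbeck moment propagation
between measurements, scalar updates at them, and the prediction-error
NLL ½Σ[log R_j + ε_j²/R_j] + (M/2)log 2π.  `ml_estimate` repeats local
minimization (Nelder–Mead on (log α, log β), tolerance 10⁻⁸) from
prior-sampled starts with q0 drawn from its true distribution, flagging
non-convergence per run.  Only the exact linear filter is implemented —
no EKF/UKF.

## Problem sizes used in the test suite

The acceptance-style tests run the comparison pipelines at 500–2,000
particles with 3–6 replicate seeds, and the population recovery test uses
20 runs of a 4-patient population at 2,000 particles; the full-size
configuration (10,000 particles, 10 replicates) lives in
`scripts/acceptance.py`.  Monte Carlo assertions use 3 standard errors
calibrated from the replicates themselves.

## Known limitations

- Measurement times must be independent; order constraints can only be
  imposed through disjoint supports.
- The likelihood reference measure for the values is Lebesgue.
- Online/delayed estimation with finite-support densities is not
  implemented; all runs are offline.
- The Rao–Blackwellizable linear substructure of the leucine model is not
  exploited.
- With a non-bootstrap proposal the ESS prediction (and hence most of the
  benefit of the adaptive stepsize) is unavailable.
- Euler–Maruyama only; no higher-order SDE schemes.
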