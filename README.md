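# mtupf — particle filtering under measurement-time uncertainty

When concentrations are estimated from blood or tissue samples, the time at
which a sample was actually drawn is rarely the time written on the protocol
sheet.  In kinetic experiments this matters: early after a bolus, concentrations
change so fast that a few minutes of timing error translates into a large,
state-dependent value error.  The standard practice of lumping the timing error
into an inflated measurement variance mis-specifies the observation model and
can wreck parameter estimates.

`mtupf` implements a continuous-time sequential Monte Carlo method — the
**MTU particle filter** — in which each measurement time *T_j* is itself a
random variable with a known density γ_j.  For an Itô state process
dX_t = a(X_t, t) dt + B(X_t, t) dW_t observed through value densities
g_j(y_j | x_t, t), the filter weight of a particle path is the product of
per-observation *partial weights*

    w_{j,t} = 1 − γ̄_{j,t} + w̄_{j,t},
    γ̄_{j,t} = ∫_{t0}^{t} γ_j(s) ds,
    w̄_{j,t} = ∫_{t0}^{t} g_j(y_j | x_s, s) γ_j(s) ds,

which evolve *continuously*: instead of point likelihood updates at fixed
measurement times, every discretization step integrates a sliver of each active
observation's likelihood.  Because weights change gradually, the stepsize can
adapt to the effective sample size (ESS), which prevents the abrupt weight
collapse that plagues the standard filter when measurement variances are small.
Resampling uses selection weights with exact bias corrections, and the marginal
data likelihood is estimated with the matching multiplicative corrections per
resampling event.

The package provides:

- `mtupf.mtu` — the MTU particle filter: partial-weight integration, ESS
  prediction, adaptive stepsize, corrected likelihood estimator;
- `mtupf.standard` — the standard particle filter (sequential importance
  sampling, multinomial/stratified/systematic resampling, recursive likelihood
  estimate), fully in log-weight space;
- `mtupf.augmentation` — Bayesian parameter estimation by state augmentation
  with decaying artificial dynamics σ_θ(t) = a/(t−b)², geometric (positivity
  preserving) or additive;
- `mtupf.kalman` — the exact continuous/discrete Kalman filter and
  maximum-likelihood baseline for linear models;
- `mtupf.leucine` — a four-compartment plasma-leucine tracer/tracee model with
  two-group mixed effects (control vs diabetes degradation rates, per-patient
  log-normal factors);
- `mtupf.synthetic` — generators for both example designs, including the
  published four-measurement dataset;
- a `mtupf` command-line tool wrapping all of the above.

## Worked example

The one-state example dq = (−αq + β) dt + σ dW (true α=1, β=3, σ=0.05) is
observed four times; the intended times are 0.5, 1, 2, 4 h but the actual
sampling times are jittered by a truncated normal with sd 0.3 h.  Estimating
(α, β) from the published measurement values with the MTU filter:

```sh
mtupf filter-mtu -n 2000 --seed 7 --horizon 10 --out mtu.csv
```

writes a trace CSV (time, ESS, cumulative log-likelihood, accepted stepsize,
weighted quantiles) plus an estimate table and a metadata file.  With this
small particle count the run printed:

```
 name  median  q0.025  q0.25  q0.5  q0.75  q0.975
alpha   0.952   0.201  0.517 0.952  1.921   6.173
 beta   2.868   0.737  1.566 2.868  5.637  19.298
final loglik -4.799
min ESS 946
```

The weighted medians land near the true (1, 3) even though the measurement
noise sd is only 0.005 — far below the value changes induced by the time
jitter.  The ESS never fell below 946 of 2000.  For comparison, the standard
filter forced to treat the intended times as exact collapses to an ESS of ~1
at the first measurement when given the honest sd 0.005
(`mtupf filter-standard --sigma-y 0.005 ...`), and with an inflated, lumped
sd of 0.5 it reaches α ≈ 1.16 but with a lower data likelihood than the MTU
run.  The Kalman-based maximum-likelihood baseline
(`mtupf ml-estimate`) is biased far from the truth on this data for every
lumped variance, reproducing the failure mode that motivates separate
time-uncertainty modelling.

The mixed-effects workflow runs the same way on a population file
(one record per patient: id/group/bolus line, times line, values line):

```sh
mtupf simulate-leucine --seed 1 --n-control 2 --n-diabetes 2 --out pop.txt
mtupf leucine-estimate --population pop.txt -n 2000 --out leucine.csv
```

which estimates the shared transfer coefficients, the two group-level
degradation rates and the per-patient random effects jointly from the
tracer/tracee ratio measurements.

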