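import numpy as np
import pytest

from mtupf.models import StateSpaceModel
from mtupf.mtu import (MtuCloud, StepsizeConfig, adaptive_stepsize,
                       combined_log_weights, combined_weight,
                       ess_from_log_weights, mtu_likelihood,
                       partial_weight_step, predict_ess, run_mtu_filter)
from mtupf.observations import (Observation, TimeDensity,
                                gaussian_value_density,
                                truncated_normal_time_density)
from mtupf.standard import DegeneracyError, ResampleConfig, \
    run_standard_filter


def uniform_time_density(lo, hi):
    width = hi - lo
    return TimeDensity(
        pdf=lambda t: (1.0 / width) if lo <= np.min(t) <= hi else
        np.where((np.asarray(t) >= lo) & (np.asarray(t) <= hi),
                 1.0 / width, 0.0),
        cdf=lambda t: np.clip((np.asarray(t) - lo) / width, 0.0, 1.0),
        support=(lo, hi))


def constant_g_obs(index, value, t_hat, td, g_value):
    return Observation(
        index=index, value=value, intended_time=t_hat,
        value_log_density=lambda y, s, t: np.full(s.shape[0],
                                                  np.log(g_value)),
        time_density=td)


class TestPartialWeightStep:
    def test_before_support_unchanged(self):
        cloud = MtuCloud.initial(np.zeros((3, 1)), 1, 0.0)
        obs = constant_g_obs(0, 1.0, 5.0, uniform_time_density(4.0, 6.0), 2.0)
        partial_weight_step(cloud, [obs], 0.0, 0.5)
        assert np.all(cloud.gamma_bar == 0.0)
        assert np.all(cloud.w_bar == 0.0)

    def test_unit_g_keeps_factor_one(self):
        cloud = MtuCloud.initial(np.zeros((2, 1)), 1, 0.0)
        td = uniform_time_density(0.0, 1.0)
        obs = constant_g_obs(0, 1.0, 0.5, td, 1.0)
        t = 0.0
        for _ in range(10):
            partial_weight_step(cloud, [obs], t, 0.1)
            t += 0.1
            factors = 1.0 - cloud.gamma_bar[0] + cloud.w_bar[0]
            np.testing.assert_allclose(factors, 1.0, atol=1e-12)

    def test_single_euler_step_hand_values(self):
        # gamma(t) = 0.5 on [0, 2], g = 2, dt = 0.1 from (0, 0)
        cloud = MtuCloud.initial(np.zeros((1, 1)), 1, 0.0)
        obs = constant_g_obs(0, 1.0, 1.0, uniform_time_density(0.0, 2.0), 2.0)
        partial_weight_step(cloud, [obs], 0.0, 0.1)
        assert cloud.gamma_bar[0] == pytest.approx(0.05)
        assert cloud.w_bar[0, 0] == pytest.approx(0.10)
        assert combined_weight(cloud)[0] == pytest.approx(1.05)

    def test_accumulators_nondecreasing(self):
        cloud = MtuCloud.initial(np.zeros((2, 1)), 1, 0.0)
        td = truncated_normal_time_density(0.5, 0.2, 0.0, 1.0)
        obs = constant_g_obs(0, 1.0, 0.5, td, 0.7)
        t, prev_gb, prev_wb = 0.0, 0.0, np.zeros(2)
        for _ in range(20):
            partial_weight_step(cloud, [obs], t, 0.05)
            t += 0.05
            assert cloud.gamma_bar[0] >= prev_gb - 1e-15
            assert np.all(cloud.w_bar[0] >= prev_wb - 1e-15)
            prev_gb, prev_wb = cloud.gamma_bar[0], cloud.w_bar[0].copy()
        assert cloud.gamma_bar[0] == pytest.approx(1.0, abs=1e-9)


class TestCombinedWeight:
    def test_no_observations_is_inverse_vbar(self):
        cloud = MtuCloud.initial(np.zeros((2, 1)), 0, 0.0)
        cloud.log_v_bar = np.log(np.array([1.0, 4.0]))
        np.testing.assert_allclose(combined_weight(cloud),
                                   [1.0, 0.25])

    def test_initial_state_weight_is_one(self):
        cloud = MtuCloud.initial(np.zeros((3, 1)), 2, 0.0)
        np.testing.assert_allclose(combined_weight(cloud), 1.0)

    def test_hand_computed_product(self):
        cloud = MtuCloud.initial(np.zeros((1, 1)), 2, 0.0)
        cloud.gamma_bar = np.array([0.05, 0.3])
        cloud.w_bar = np.array([[0.10], [0.2]])   # factors 1.05, 0.9
        cloud.log_v_bar = np.array([np.log(3.0)])
        assert combined_weight(cloud)[0] == pytest.approx(0.315)

    def test_zero_factor_short_circuits_to_zero(self):
        cloud = MtuCloud.initial(np.zeros((2, 1)), 2, 0.0)
        cloud.gamma_bar = np.array([1.0, 0.5])
        cloud.w_bar = np.array([[0.0, 0.4], [0.6, 0.6]])
        w = combined_weight(cloud)
        assert w[0] == 0.0
        assert w[1] > 0.0


class TestPredictEss:
    def test_no_mass_crossed_keeps_current_ess(self):
        cloud = MtuCloud.initial(np.zeros((4, 1)), 1, 0.0)
        cloud.w_bar[0] = np.array([0.0, 0.1, 0.2, 0.3])
        cloud.gamma_bar[0] = 0.2
        obs = constant_g_obs(0, 1.0, 5.0, uniform_time_density(4.0, 6.0), 2.0)
        current = ess_from_log_weights(combined_log_weights(cloud))
        assert predict_ess(cloud, [obs], 0.5) == pytest.approx(current)

    def test_identical_particles_predict_full_ess(self):
        cloud = MtuCloud.initial(np.ones((5, 1)), 1, 0.0)
        obs = constant_g_obs(0, 1.0, 0.5, uniform_time_density(0.0, 1.0), 3.0)
        assert predict_ess(cloud, [obs], 0.1) == pytest.approx(5.0)

    def test_two_particle_hand_computation(self):
        # particles with g = (2, 1); gamma = 0.5, dt = 0.1 from (0, 0)
        td = uniform_time_density(0.0, 2.0)
        obs = Observation(
            index=0, value=1.0, intended_time=1.0,
            value_log_density=lambda y, s, t: np.log(np.array([2.0, 1.0])),
            time_density=td)
        cloud = MtuCloud.initial(np.zeros((2, 1)), 1, 0.0)
        got = predict_ess(cloud, [obs], 0.1)
        w = np.array([1.0 - 0.05 + 0.10, 1.0 - 0.05 + 0.05])
        wn = w / w.sum()
        assert got == pytest.approx(1.0 / np.sum(wn**2))

    def test_prediction_matches_actual_step(self, rng):
        # for the prior kernel the predicted ESS equals the ESS after the
        # accumulator update with the same dt
        td = truncated_normal_time_density(0.5, 0.2, 0.0, 1.0)
        g_vals = rng.random(6) + 0.1
        obs = Observation(
            index=0, value=1.0, intended_time=0.5,
            value_log_density=lambda y, s, t: np.log(g_vals),
            time_density=td)
        cloud = MtuCloud.initial(np.zeros((6, 1)), 1, 0.0)
        partial_weight_step(cloud, [obs], 0.0, 0.2)
        cloud.time = 0.2
        predicted = predict_ess(cloud, [obs], 0.1)
        partial_weight_step(cloud, [obs], 0.2, 0.1)
        actual = ess_from_log_weights(combined_log_weights(cloud))
        assert predicted == pytest.approx(actual)


class TestAdaptiveStepsize:
    def setup_method(self):
        self.cfg = StepsizeConfig(dt_max=1e-2, dt_min=1e-6, rel_drop=0.10)

    def test_unchanged_ess_gives_dt_max(self):
        cloud = MtuCloud.initial(np.zeros((10, 1)), 0, 0.0)
        dt = adaptive_stepsize(10.0, 10.0, cloud, [], self.cfg)
        assert dt == pytest.approx(self.cfg.dt_max)

    def test_full_drop_gives_dt_min(self):
        cloud = MtuCloud.initial(np.zeros((10, 1)), 0, 0.0)
        dt = adaptive_stepsize(1.0, 10.0, cloud, [], self.cfg)
        assert dt == pytest.approx(self.cfg.dt_min)

    def test_linear_interpolation_between(self):
        n = 11
        cloud = MtuCloud.initial(np.zeros((n, 1)), 0, 0.0)
        # drop of half of (N-1)
        dt = adaptive_stepsize(n - 5.0, n, cloud, [], self.cfg)
        expected = self.cfg.dt_max - (self.cfg.dt_max - self.cfg.dt_min) * 0.5
        assert dt == pytest.approx(expected)

    def test_violating_prediction_floors_at_dt_min(self):
        # two particles, one of which dies instantly: predicted ESS ~ 1
        # for every dt, so halving runs into the floor
        td = uniform_time_density(0.0, 1.0)
        obs = Observation(
            index=0, value=1.0, intended_time=0.5,
            value_log_density=lambda y, s, t:
            np.array([np.log(1e8), -np.inf]),
            time_density=td)
        cloud = MtuCloud.initial(np.zeros((2, 1)), 1, 0.0)
        cloud.gamma_bar[0] = 0.5
        cloud.w_bar[0] = np.array([0.5, 0.5])
        dt = adaptive_stepsize(2.0, 2.0, cloud, [obs], self.cfg)
        assert dt == pytest.approx(self.cfg.dt_min)

    def test_result_always_within_bounds(self, rng):
        cloud = MtuCloud.initial(np.zeros((8, 1)), 0, 0.0)
        for _ in range(50):
            e_now = 1.0 + 7.0 * rng.random()
            e_prev = 1.0 + 7.0 * rng.random()
            dt = adaptive_stepsize(e_now, e_prev, cloud, [], self.cfg)
            assert self.cfg.dt_min <= dt <= self.cfg.dt_max


class TestMtuLikelihood:
    def test_no_resampling_is_mean_weight(self):
        w = np.array([0.5, 1.5, 1.0])
        assert mtu_likelihood(w, []) == pytest.approx(1.0)

    def test_unit_weights_one_resampling(self):
        # all weights 1, selection weights 1: (1/N^2) * N * N = 1
        assert mtu_likelihood(np.ones(5), [5.0]) == pytest.approx(1.0)

    def test_three_particle_two_resampling_bookkeeping_oracle(self):
        # explicit selection-tracking oracle: every quantity enumerated
        n = 3
        w_s1 = np.array([2.0, 0.5, 1.5])        # uncorrected weights at s1
        v1 = w_s1.copy()                         # selection weights at s1
        iota1 = np.array([0, 2, 2])              # selection map at s1
        # after s1: growth factors to s2 per surviving lineage slot
        growth12 = np.array([1.2, 0.8, 2.0])
        v2 = np.array([0.9, 1.1, 0.6])
        iota2 = np.array([1, 1, 2])
        growth2t = np.array([0.7, 1.0, 1.3])     # factors from s2 to t

        # oracle: uncorrected path weight at t for final slot i is the
        # product of the selected lineage's weights; v_bar is the product
        # of the selection weights picked up at each event
        w_t = np.empty(n)
        v_bar = np.empty(n)
        for i in range(n):
            j2 = iota2[i]          # slot selected at s2
            j1 = iota1[j2]         # original particle index
            w_t[i] = w_s1[j1] * growth12[j2] * growth2t[i]
            v_bar[i] = v1[j1] * v2[j2]
        z_oracle = (1.0 / n**3) * v1.sum() * v2.sum() * np.sum(w_t / v_bar)

        # implementation route: corrected weights maintained recursively
        corr = w_s1 / v1                      # correction at s1
        corr = corr[iota1]                    # selection at s1
        corr = corr * growth12                # evolve to s2
        corr = (corr / v2)[iota2]             # correct + select at s2
        corr = corr * growth2t                # evolve to t
        z_impl = mtu_likelihood(corr, [v1.sum(), v2.sum()])
        assert z_impl == pytest.approx(z_oracle, rel=1e-12)


def _linear_fixed_model(alpha, beta, sigma, q0):
    return StateSpaceModel(
        dim=1,
        drift=lambda x, t: -alpha * x + beta,
        diffusion=lambda x, t: np.array([[sigma]]),
        initial_sampler=lambda rng, n: np.full((n, 1), q0),
        coord_names=["q"],
    )


def _gaussian_obs(times, values, sigma_y, time_sd, halfwidth, t0=0.0):
    obs = []
    for j, (t_hat, y) in enumerate(zip(times, values)):
        lo = max(t0, t_hat - halfwidth)
        td = truncated_normal_time_density(t_hat, time_sd, lo,
                                           t_hat + halfwidth)
        obs.append(Observation(
            index=j, value=float(y), intended_time=float(t_hat),
            value_log_density=lambda yy, s, t, sy=sigma_y:
            gaussian_value_density(yy, s[:, 0], sy),
            time_density=td))
    return obs


class TestRunMtuFilter:
    def test_no_observations_keeps_unit_weights(self):
        model = _linear_fixed_model(1.0, 3.0, 0.05, 1.0)
        trace = run_mtu_filter(model, [], 100,
                               StepsizeConfig(1e-2, 1e-6),
                               rng=np.random.default_rng(0), t_end=0.5)
        assert np.all(trace.ess == 100.0)
        assert np.all(trace.loglik == 0.0)
        np.testing.assert_allclose(trace.final_weights, 1.0)

    def test_weight_is_one_before_first_support(self):
        model = _linear_fixed_model(1.0, 3.0, 0.05, 1.0)
        obs = _gaussian_obs([0.8], [2.2], 0.1, 0.05, 0.15)
        trace = run_mtu_filter(model, obs, 60, StepsizeConfig(1e-2, 1e-6),
                               rng=np.random.default_rng(1), t_end=1.0)
        before = trace.times < 0.65 - 1e-9
        np.testing.assert_allclose(trace.ess[before], 60.0)
        np.testing.assert_allclose(trace.loglik[before], 0.0, atol=1e-12)

    def test_same_seed_identical(self):
        model = _linear_fixed_model(1.0, 3.0, 0.05, 1.0)
        obs = _gaussian_obs([0.4], [1.8], 0.1, 0.1, 0.3)
        kw = dict(n_particles=150, stepsize=StepsizeConfig(1e-2, 1e-6),
                  t_end=1.0)
        t1 = run_mtu_filter(model, obs, rng=np.random.default_rng(9), **kw)
        t2 = run_mtu_filter(model, obs, rng=np.random.default_rng(9), **kw)
        np.testing.assert_array_equal(t1.loglik, t2.loglik)
        np.testing.assert_array_equal(t1.final_states, t2.final_states)

    def test_accepted_steps_within_bounds_and_boundaries_hit(self):
        model = _linear_fixed_model(1.0, 3.0, 0.05, 1.0)
        obs = _gaussian_obs([0.3, 0.7], [1.6, 2.3], 0.05, 0.05, 0.1)
        cfg = StepsizeConfig(dt_max=2e-2, dt_min=1e-5)
        trace = run_mtu_filter(model, obs, 200, cfg,
                               rng=np.random.default_rng(2), t_end=1.0)
        dts = trace.stepsizes[1:]
        assert np.all(dts <= cfg.dt_max + 1e-12)
        # boundary splits may be shorter than dt_min; all others obey it
        for b in (0.2, 0.4, 0.6, 0.8, 1.0):
            assert np.any(np.isclose(trace.times, b, atol=1e-12))

    def test_support_before_t0_rejected(self):
        model = _linear_fixed_model(1.0, 3.0, 0.05, 1.0)
        obs = _gaussian_obs([0.1], [1.2], 0.1, 0.1, 0.3, t0=-0.5)
        with pytest.raises(ValueError):
            run_mtu_filter(model, obs, 50, rng=np.random.default_rng(0),
                           t_end=1.0)

    def test_point_mass_limit_matches_standard_filter(self):
        # criterion: as the time densities shrink to (near) point masses
        # the MTU filter reduces to the standard filter
        alpha, beta, sigma, q0, sigma_y = 1.0, 3.0, 0.05, 1.0, 0.05
        times, values = [0.3, 0.6], [1.75, 2.25]
        n, n_seeds = 400, 6
        diff_ll = []
        mtu_means, std_means = [], []
        for seed in range(n_seeds):
            model = _linear_fixed_model(alpha, beta, sigma, q0)
            obs_mtu = _gaussian_obs(times, values, sigma_y,
                                    time_sd=1e-4, halfwidth=5e-4)
            tr_m = run_mtu_filter(model, obs_mtu, n,
                                  StepsizeConfig(5e-3, 1e-6),
                                  rng=np.random.default_rng(100 + seed),
                                  t_end=0.7)
            obs_std = [Observation(
                index=j, value=float(y), intended_time=float(t),
                value_log_density=lambda yy, s, t_, sy=sigma_y:
                gaussian_value_density(yy, s[:, 0], sy))
                for j, (t, y) in enumerate(zip(times, values))]
            tr_s = run_standard_filter(model, obs_std, n, 5e-3,
                                       rng=np.random.default_rng(100 + seed),
                                       t_end=0.7)
            diff_ll.append(tr_m.loglik[-1] - tr_s.loglik[-1])
            w_m = tr_m.final_weights / tr_m.final_weights.sum()
            w_s = tr_s.final_weights / tr_s.final_weights.sum()
            mtu_means.append(np.sum(w_m * tr_m.final_states[:, 0]))
            std_means.append(np.sum(w_s * tr_s.final_states[:, 0]))
        diff_ll = np.asarray(diff_ll)
        se = diff_ll.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(diff_ll.mean()) < 3 * se + 5e-3
        dmean = np.asarray(mtu_means) - np.asarray(std_means)
        se_m = dmean.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(dmean.mean()) < 3 * se_m + 1e-3

    def test_likelihood_invariant_to_resampling_threshold(self):
        # Z_hat is unbiased whatever the threshold: frequent-resampling and
        # no-resampling estimates agree in expectation
        alpha, beta, sigma, q0, sigma_y = 1.0, 3.0, 0.1, 1.0, 0.1
        times, values = [0.3, 0.6], [1.7, 2.3]
        n, n_seeds = 300, 12
        z_hi, z_no = [], []
        for seed in range(n_seeds):
            model = _linear_fixed_model(alpha, beta, sigma, q0)
            obs = _gaussian_obs(times, values, sigma_y, 0.05, 0.15)
            tr1 = run_mtu_filter(model, obs, n, StepsizeConfig(5e-3, 1e-6),
                                 ResampleConfig(threshold=0.9 * n),
                                 np.random.default_rng(2000 + seed),
                                 t_end=0.8)
            tr2 = run_mtu_filter(model, obs, n, StepsizeConfig(5e-3, 1e-6),
                                 ResampleConfig(threshold=1.0),
                                 np.random.default_rng(4000 + seed),
                                 t_end=0.8)
            z_hi.append(np.exp(tr1.loglik[-1]))
            z_no.append(np.exp(tr2.loglik[-1]))
        z_hi, z_no = np.asarray(z_hi), np.asarray(z_no)
        se = np.sqrt(z_hi.var(ddof=1) / n_seeds + z_no.var(ddof=1) / n_seeds)
        assert abs(z_hi.mean() - z_no.mean()) < 3 * se + 1e-4
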