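"""Delayed step-input model: closed form, window selection, bin fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from terseq import synthetic
from terseq.kinetics import (BinDelayEstimate, DegenerateSeriesError,
                             KineticParams, estimate_ci, fit_bin,
                             model_solution, select_timepoints)


def numeric_ode(params, times):
    """Independent oracle: adaptive integration of the step-input ODE."""
    k = params.mu + params.gamma

    def theta(t):
        on = 1.0 if t >= params.T_d else 0.0
        return on if params.direction == "increase" else 1.0 - on

    x0 = (params.s_b / k if params.direction == "increase"
          else (params.s_b + params.s_a) / k)

    def rhs(t, x):
        return params.s_b + theta(t) * params.s_a - k * x[0]

    t_end = max(float(np.max(times)), params.T_d) + 1.0
    sol = solve_ivp(rhs, (0.0, t_end), [x0], t_eval=np.asarray(times, float),
                    rtol=1e-10, atol=1e-12, max_step=5.0, method="LSODA")
    return sol.y[0]


class TestModelSolution:
    def test_steady_states_and_half_relaxation(self):
        p = KineticParams(s_b=0.5, s_a=0.5, T_d=30.0, mu=0.0, gamma=0.01)
        t_half = 30.0 + np.log(2) / 0.01
        x = model_solution(p, [0.0, 30.0, t_half, 30.0 + 2000.0])
        assert x[0] == pytest.approx(50.0)
        assert x[1] == pytest.approx(50.0)
        assert x[2] == pytest.approx(75.0)
        assert x[3] == pytest.approx(100.0, rel=1e-6)

    def test_no_step_gives_constant_basal_level(self):
        p = KineticParams(s_b=0.8, s_a=0.0, T_d=100.0, mu=0.001, gamma=0.004)
        x = model_solution(p, np.linspace(0, 600, 13))
        assert np.allclose(x, 0.8 / 0.005)

    def test_decrease_mirrors_increase(self):
        up = KineticParams(s_b=1.0, s_a=2.0, T_d=40.0, mu=0.0, gamma=0.01,
                           direction="increase")
        down = KineticParams(s_b=1.0, s_a=2.0, T_d=40.0, mu=0.0, gamma=0.01,
                             direction="decrease")
        t = np.linspace(0, 600, 61)
        # the two trajectories sum to low + high at every time
        assert np.allclose(model_solution(up, t) + model_solution(down, t),
                           (1.0 + 3.0) / 0.01)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_numeric_integration(self, seed):
        rng = np.random.default_rng(seed)
        p = KineticParams(
            s_b=rng.uniform(0, 2), s_a=rng.uniform(0, 2),
            T_d=rng.uniform(0, 300), mu=rng.uniform(0, 0.002),
            gamma=rng.uniform(5e-4, 0.02),
            direction=rng.choice(["increase", "decrease"]))
        t = np.sort(rng.uniform(0, 600, size=8))
        x = model_solution(p, t)
        assert np.allclose(x, numeric_ode(p, t), rtol=1e-6, atol=1e-9)

    def test_continuous_at_onset_and_monotone_after(self):
        for direction in ("increase", "decrease"):
            p = KineticParams(s_b=0.5, s_a=1.5, T_d=77.0, mu=0.0,
                              gamma=0.005, direction=direction)
            eps = 1e-9
            x = model_solution(p, [77.0 - eps, 77.0, 77.0 + eps])
            assert x[1] == pytest.approx(x[0], abs=1e-6)
            after = model_solution(p, np.linspace(77.0, 900.0, 200))
            d = np.diff(after)
            assert np.all(d >= -1e-12) if direction == "increase" \
                else np.all(d <= 1e-12)

    def test_zero_rate_constant_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(s_b=1, s_a=1, T_d=0, mu=0.0, gamma=0.0)


class TestSelectTimepoints:
    def test_transient_peak_keeps_prefix_to_peak(self):
        # fast rise to a peak at the 3rd timepoint, then decline
        m = [10, 80, 150, 90, 40, 20]
        assert select_timepoints(m).tolist() == [0, 1, 2]

    def test_delayed_rise_then_fall_keeps_four_points(self):
        # flat for three points, response through the 4th, then reversal
        m = [10, 10, 11, 120, 70, 30]
        assert select_timepoints(m).tolist() == [0, 1, 2, 3]

    def test_monotone_series_keeps_full_design(self):
        m = [10, 12, 30, 80, 150, 200]
        assert select_timepoints(m).tolist() == list(range(6))

    def test_small_reversal_within_noise_is_ignored(self):
        m = [10, 12, 30, 80, 150, 140]  # 10/190 range: below threshold
        assert select_timepoints(m).tolist() == list(range(6))

    def test_constant_series_keeps_full_design(self):
        assert select_timepoints([5.0] * 6).tolist() == list(range(6))

    def test_minimum_length_enforced(self):
        m = [10, 100, 20, 15, 12, 11]  # peak at 2nd point
        assert len(select_timepoints(m)) >= 3
        with pytest.raises(ValueError):
            select_timepoints([1.0, 2.0])


class TestFitBin:
    def test_noise_free_recovery_on_study_grid(self, flat_design, truth_factory):
        k = 0.01
        p = KineticParams(s_b=0.5, s_a=0.5, T_d=45.0, mu=0.0, gamma=k)
        times = np.asarray(flat_design.sample_times)
        series = np.repeat(model_solution(p, times)[:, None], 3, axis=1)
        est = fit_bin(series, times, gamma=k, seed=0)
        assert est.T_d_hat == pytest.approx(45.0, abs=1.0)
        assert est.sse < 1e-10

    def test_decrease_recovery(self):
        k = 0.005
        p = KineticParams(s_b=0.3, s_a=1.2, T_d=20.0, mu=0.0, gamma=k,
                          direction="decrease")
        times = np.asarray(synthetic.SAMPLE_TIMES_S)
        series = np.repeat(model_solution(p, times)[:, None], 3, axis=1)
        est = fit_bin(series, times, gamma=k, seed=0)
        assert est.params.direction == "decrease"
        assert est.T_d_hat == pytest.approx(20.0, abs=1.0)

    def test_constant_series_degenerates_to_zero_step(self):
        times = np.asarray(synthetic.SAMPLE_TIMES_S)
        series = np.full((times.size, 3), 42.0)
        k = 0.004
        est = fit_bin(series, times, gamma=k, seed=0)
        assert est.params.s_a == pytest.approx(0.0, abs=1e-6)
        assert est.params.s_b == pytest.approx(42.0 * k, rel=1e-6)
        assert est.T_d_hat == pytest.approx(0.0, abs=1e-6)  # tie broken low

    def test_all_zero_series_raises(self):
        times = np.asarray(synthetic.SAMPLE_TIMES_S)
        with pytest.raises(DegenerateSeriesError):
            fit_bin(np.zeros((times.size, 3)), times, gamma=0.004, seed=0)

    def test_noise_free_bias_below_one_second_across_delays(self):
        k = np.log(2) / 240.0
        times = np.asarray(synthetic.SAMPLE_TIMES_S)
        for td in (5, 20, 45, 70, 95, 120):
            p = KineticParams(s_b=20 * k, s_a=140 * k, T_d=float(td),
                              mu=0.0, gamma=k)
            series = np.repeat(model_solution(p, times)[:, None], 3, axis=1)
            est = fit_bin(series, times, gamma=k, seed=0)
            assert est.T_d_hat == pytest.approx(td, abs=1.0)

    def test_objective_no_worse_than_truth(self, truth_factory, flat_design):
        truth = truth_factory(dispersion=0.05)
        binned, tds = synthetic.simulate_operon(truth, flat_design, seed=5)
        times = np.asarray(flat_design.sample_times)
        for b in (0, 4, 8):
            series = binned.rpkm[b]
            est = fit_bin(series, times, gamma=truth.gamma, seed=1)
            p_true = KineticParams(s_b=truth.s_b, s_a=truth.s_a, T_d=tds[b],
                                   mu=0.0, gamma=truth.gamma)
            resid = series - model_solution(p_true, times)[:, None]
            sse_true = float(np.sum(resid**2))
            assert est.sse <= sse_true + 1e-8

    def test_gamma_cofit_when_unknown(self):
        k = np.log(2) / 180.0
        p = KineticParams(s_b=30 * k, s_a=200 * k, T_d=40.0, mu=0.0, gamma=k)
        times = np.asarray(synthetic.SAMPLE_TIMES_S)
        series = np.repeat(model_solution(p, times)[:, None], 3, axis=1)
        est = fit_bin(series, times, gamma=None, seed=0)
        assert est.gamma_source == "fitted"
        assert est.params.gamma == pytest.approx(k, rel=0.05)
        assert est.T_d_hat == pytest.approx(40.0, abs=2.0)

    def test_annealing_backend_agrees_with_profile(self):
        k = 0.005
        p = KineticParams(s_b=0.5, s_a=1.0, T_d=60.0, mu=0.0, gamma=k)
        times = np.asarray(synthetic.SAMPLE_TIMES_S)
        series = np.repeat(model_solution(p, times)[:, None], 3, axis=1)
        est = fit_bin(series, times, gamma=k, seed=3, method="anneal",
                      restarts=1)
        assert est.T_d_hat == pytest.approx(60.0, abs=3.0)


class TestEstimateCI:
    def _fit(self, series, times, k):
        return fit_bin(series, times, gamma=k, seed=0)

    def test_zero_noise_interval_is_tight(self):
        k = 0.004
        p = KineticParams(s_b=0.2, s_a=0.6, T_d=50.0, mu=0.0, gamma=k)
        times = np.asarray(synthetic.SAMPLE_TIMES_S)
        series = np.repeat(model_solution(p, times)[:, None], 3, axis=1)
        est = self._fit(series, times, k)
        lo, hi = estimate_ci(est, series, times, B=50, seed=0)
        assert hi - lo < 2.0
        assert lo <= est.T_d_hat <= hi

    def test_same_seed_reproduces_interval(self, truth_factory, flat_design):
        truth = truth_factory(dispersion=0.05, operon_length=300)
        binned, _ = synthetic.simulate_operon(truth, flat_design, seed=9)
        times = np.asarray(flat_design.sample_times)
        est = self._fit(binned.rpkm[0], times, truth.gamma)
        ci1 = estimate_ci(est, binned.rpkm[0], times, B=80, seed=4)
        ci2 = estimate_ci(est, binned.rpkm[0], times, B=80, seed=4)
        assert ci1 == ci2

    def test_rejects_no_resamples(self, truth_factory, flat_design):
        truth = truth_factory(operon_length=300)
        binned, _ = synthetic.simulate_operon(truth, flat_design, seed=9)
        times = np.asarray(flat_design.sample_times)
        est = self._fit(binned.rpkm[0], times, truth.gamma)
        with pytest.raises(ValueError):
            estimate_ci(est, binned.rpkm[0], times, B=0, seed=0)
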