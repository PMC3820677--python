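"""Estimator-level checks against closed forms and replicate oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import alchemycle as ac
from alchemycle.errors import SampleSizeError, ScheduleError


def _series(samples, lam=0.0, lam_target=1.0, **kw):
    return ac.EnergySeries(samples=np.asarray(samples, float), lam=lam,
                           lam_target=lam_target, **kw)


class TestSchedules:
    def test_uniform_four_windows(self):
        sched = ac.build_schedule("uniform", 4)
        assert np.allclose(sched.values, [0.0, 0.25, 0.5, 0.75, 1.0])

    def test_gauss_legendre_7_identities(self):
        gl7 = ac.build_schedule("gauss_legendre_7")
        assert gl7.weights.sum() == pytest.approx(1.0, rel=1e-14)
        assert np.allclose(gl7.values + gl7.values[::-1], 1.0, atol=1e-14)

    @pytest.mark.parametrize("degree", range(14))
    def test_gauss_legendre_7_is_exact_through_degree_13(self, degree):
        gl7 = ac.build_schedule("gauss_legendre_7")
        quad = float(gl7.weights @ gl7.values ** degree)
        assert quad == pytest.approx(1.0 / (degree + 1), rel=1e-13)

    def test_exponential_halves_window_count_qualitatively(self):
        """A charging leg needing >130 uniform windows needs far fewer
        exponentially spaced ones under the same 2 kT per-window bound."""
        probe = ac.quadratic_charging_probe(131.0)
        with pytest.raises(ScheduleError) as uni_err:
            ac.build_schedule("uniform", 130, target_per_window=2.0, probe=probe)
        assert uni_err.value.required_n == 131
        with pytest.raises(ScheduleError) as exp_err:
            ac.build_schedule("exponential", 66, target_per_window=2.0, probe=probe)
        n_exp = exp_err.value.required_n
        assert n_exp is not None and n_exp <= 0.65 * uni_err.value.required_n
        sched = ac.build_schedule("exponential", n_exp, target_per_window=2.0,
                                  probe=probe)
        g = probe(sched.values)
        assert np.max(np.abs(np.diff(g))) <= 2.0 + 1e-9

    def test_exponential_satisfiable_target_returns_schedule(self):
        probe = ac.quadratic_charging_probe(10.0)
        sched = ac.build_schedule("exponential", 12, target_per_window=2.0,
                                  probe=probe)
        assert sched.values[0] == 0.0 and sched.values[-1] == 1.0
        assert np.max(np.abs(np.diff(probe(sched.values)))) <= 2.0 + 1e-9

    def test_malformed_schedules_rejected(self):
        with pytest.raises(ScheduleError):
            ac.LambdaSchedule("uniform", [0.0, 0.5, 0.4, 1.0])
        with pytest.raises(ScheduleError):
            ac.LambdaSchedule("uniform", [0.1, 0.5, 1.0])
        with pytest.raises(ScheduleError):
            ac.build_schedule("uniform", 1)


class TestFEP:
    def test_zero_gaps_give_zero_free_energy(self, ctx_unit):
        windows = [_series(np.zeros(100), lam=l, lam_target=l + 0.25, window=i)
                   for i, l in enumerate([0.0, 0.25, 0.5, 0.75])]
        est = ac.fep_estimate(windows, ctx_unit)
        assert est.value == 0.0 and est.stderr == 0.0

    def test_two_point_exponential_average_by_hand(self, ctx_unit):
        kT = ctx_unit.kT
        w = _series([0.0, kT * math.log(2.0)])
        est = ac.fep_estimate([w], ctx_unit)
        assert est.value == pytest.approx(-kT * math.log(0.75), rel=1e-12)

    def test_harmonic_toy_recovers_closed_form(self, ctx_unit, harmonic_toy):
        sched = ac.build_schedule("uniform", 12)
        est = ac.fep_estimate(
            ac.sample_fep_windows(harmonic_toy, sched, ctx_unit, 10_000), ctx_unit)
        exact = harmonic_toy.analytic_delta_G(ctx_unit)
        assert abs(est.value - exact) < 3.0 * est.stderr

    def test_total_invariant_to_tiling_refinement(self, ctx_unit, harmonic_toy):
        coarse = ac.fep_estimate(ac.sample_fep_windows(
            harmonic_toy, ac.build_schedule("uniform", 8), ctx_unit, 20_000), ctx_unit)
        fine = ac.fep_estimate(ac.sample_fep_windows(
            harmonic_toy, ac.build_schedule("uniform", 24), ctx_unit, 20_000,
            seed=99), ctx_unit)
        assert abs(coarse.value - fine.value) < 3.0 * math.hypot(coarse.stderr,
                                                                 fine.stderr)

    def test_gap_and_overlap_tilings_rejected(self, ctx_unit):
        gap = [_series(np.zeros(50), 0.0, 0.4), _series(np.zeros(50), 0.6, 1.0)]
        with pytest.raises(ScheduleError):
            ac.fep_estimate(gap, ctx_unit)
        overlap = [_series(np.zeros(50), 0.0, 0.6), _series(np.zeros(50), 0.4, 1.0)]
        with pytest.raises(ScheduleError):
            ac.fep_estimate(overlap, ctx_unit)
        mixed = [_series(np.zeros(50), 0.0, 0.5),
                 _series(np.zeros(50), 0.5, 1.0, direction="backward")]
        with pytest.raises(ScheduleError):
            ac.fep_estimate(mixed, ctx_unit)


class TestTI:
    def test_constant_integrand(self, ctx_unit):
        gl7 = ac.build_schedule("gauss_legendre_7")
        nodes = [ac.EnergySeries(samples=np.full(50, 2.5), lam=l, weight=w,
                                 kind="dhdl", window=i)
                 for i, (l, w) in enumerate(zip(gl7.values, gl7.weights))]
        est = ac.ti_estimate(nodes, gl7, ctx_unit)
        assert est.value == pytest.approx(2.5, rel=1e-14)
        assert est.stderr == 0.0

    def test_quadratic_mean_force_integrates_exactly(self, ctx_unit):
        gl7 = ac.build_schedule("gauss_legendre_7")
        nodes = [ac.EnergySeries(samples=np.full(50, l * l), lam=l, weight=w,
                                 kind="dhdl", window=i)
                 for i, (l, w) in enumerate(zip(gl7.values, gl7.weights))]
        est = ac.ti_estimate(nodes, gl7, ctx_unit)
        assert est.value == pytest.approx(1.0 / 3.0, rel=1e-13)

    def test_harmonic_toy_recovers_closed_form(self, ctx_unit, harmonic_toy):
        gl7 = ac.build_schedule("gauss_legendre_7")
        est = ac.ti_estimate(
            ac.sample_ti_nodes(harmonic_toy, gl7, ctx_unit, 10_000), gl7, ctx_unit)
        exact = harmonic_toy.analytic_delta_G(ctx_unit)
        assert abs(est.value - exact) < 3.0 * est.stderr

    def test_node_series_mismatch_is_an_error(self, ctx_unit):
        gl7 = ac.build_schedule("gauss_legendre_7")
        nodes = [ac.EnergySeries(samples=np.zeros(50), lam=l, weight=w, kind="dhdl")
                 for l, w in zip(gl7.values[:5], gl7.weights[:5])]
        with pytest.raises(ScheduleError):
            ac.ti_estimate(nodes, gl7, ctx_unit)


class TestDirections:
    def test_forward_and_backward_agree_on_toy(self, ctx_unit, harmonic_toy):
        sched = ac.build_schedule("uniform", 12)
        fwd = ac.fep_estimate(ac.sample_fep_windows(
            harmonic_toy, sched, ctx_unit, 10_000), ctx_unit)
        bwd = ac.fep_estimate(ac.sample_fep_windows(
            harmonic_toy, sched, ctx_unit, 10_000, direction="backward", seed=4321),
            ctx_unit)
        h = ac.hysteresis(fwd, bwd)
        assert abs(h) < 3.0 * math.hypot(fwd.stderr, bwd.stderr)

    def test_hysteresis_of_printed_pair(self):
        fwd = ac.FreeEnergyEstimate(2.0, 0.4, "FEP", "forward")
        bwd = ac.FreeEnergyEstimate(-2.1, 0.5, "FEP", "backward")
        assert ac.hysteresis(fwd, bwd) == pytest.approx(-0.1)

    @given(st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_perfectly_converged_pair_has_zero_hysteresis(self, x):
        fwd = ac.FreeEnergyEstimate(x, 0.1, "FEP", "forward")
        bwd = ac.FreeEnergyEstimate(-x, 0.1, "FEP", "backward")
        assert ac.hysteresis(fwd, bwd) == 0.0

    def test_average_is_half_difference(self):
        fwd = ac.FreeEnergyEstimate(2.4, 0.4, "FEP", "forward")
        bwd = ac.FreeEnergyEstimate(-2.5, 0.5, "FEP", "backward")
        avg = ac.FreeEnergyEstimate.average(fwd, bwd)
        assert avg.value == pytest.approx(2.45)
        assert avg.stderr == pytest.approx(0.5 * math.hypot(0.4, 0.5))


class TestBlockError:
    def test_iid_matches_replicate_oracle(self):
        rng = np.random.default_rng(8)
        sigma, n = 2.0, 4096
        estimates = [ac.block_error(sigma * rng.standard_normal(n))
                     for _ in range(50)]
        assert np.mean(estimates) == pytest.approx(sigma / math.sqrt(n), rel=0.2)

    def test_ar1_inflates_error_over_naive(self):
        rng = np.random.default_rng(15)
        phi, n = 0.9, 20_000
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + math.sqrt(1 - phi * phi) * eps[i]
        naive = x.std(ddof=1) / math.sqrt(n)
        assert ac.block_error(x) >= 3.0 * naive

    def test_constant_series_has_zero_error(self):
        assert ac.block_error(np.full(1000, 3.7)) == 0.0

    def test_error_shrinks_like_inverse_sqrt_n(self):
        rng = np.random.default_rng(23)
        ratios = []
        for _ in range(5):
            small = ac.block_error(rng.standard_normal(1000))
            large = ac.block_error(rng.standard_normal(100_000))
            ratios.append(small / large)
        assert np.mean(ratios) == pytest.approx(10.0, rel=0.35)

    def test_too_few_samples_rejected(self):
        with pytest.raises(SampleSizeError):
            ac.block_error(np.arange(5.0))


class TestRunningAverage:
    def test_constant_series(self):
        s = _series(np.full(100, 1.5))
        assert np.all(ac.running_average(s) == 1.5)

    def test_alternating_series_decays_to_zero(self):
        a = 2.0
        s = _series(np.tile([a, -a], 500))
        partial = ac.running_average(s)
        k = np.arange(1, 1001)
        assert np.all(np.abs(partial) <= a / k + 1e-12)
        assert partial[-1] == pytest.approx(0.0, abs=1e-12)

    def test_fep_running_value_converges_to_window_estimate(self, ctx_unit,
                                                            harmonic_toy):
        sched = ac.LambdaSchedule("uniform", [0.0, 1.0])
        (w,) = ac.sample_fep_windows(harmonic_toy, sched, ctx_unit, 5000)
        running = ac.running_average(w, statistic="fep", ctx=ctx_unit)
        est = ac.fep_estimate([w], ctx_unit)
        assert running[-1] == pytest.approx(est.value, rel=1e-12)
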