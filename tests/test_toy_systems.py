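"""Generator-level checks: exact identities, Boltzmann statistics, file I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import alchemycle as ac
from alchemycle.errors import ConfigurationError, ParseError, SampleSizeError


class TestHarmonicAlchemy:
    def test_identity_transformation_gives_exactly_zero_gaps(self, ctx_unit):
        spec = ac.HarmonicAlchemySpec(k0=2.0, k1=2.0, mu0=0.5, mu1=0.5, seed=3)
        sched = ac.build_schedule("uniform", 5)
        for w in ac.sample_fep_windows(spec, sched, ctx_unit, 200):
            assert np.all(w.samples == 0.0)
        gl7 = ac.build_schedule("gauss_legendre_7")
        for node in ac.sample_ti_nodes(spec, gl7, ctx_unit, 200):
            assert np.all(node.samples == 0.0)

    def test_seed_determinism_is_bit_exact(self, ctx_unit, harmonic_toy):
        sched = ac.build_schedule("uniform", 8)
        a = ac.sample_fep_windows(harmonic_toy, sched, ctx_unit, 500)
        b = ac.sample_fep_windows(harmonic_toy, sched, ctx_unit, 500)
        for wa, wb in zip(a, b):
            assert np.array_equal(wa.samples, wb.samples)

    def test_closed_form_free_energy(self, ctx_unit, harmonic_toy):
        assert harmonic_toy.analytic_delta_G(ctx_unit) == pytest.approx(
            0.5 * math.log(4.0), rel=1e-12)

    def test_offset_shifts_free_energy_linearly(self, ctx_unit):
        base = ac.HarmonicAlchemySpec(k0=1.0, k1=3.0)
        shifted = ac.HarmonicAlchemySpec(k0=1.0, k1=3.0, offset=1.7)
        assert (shifted.analytic_delta_G(ctx_unit)
                - base.analytic_delta_G(ctx_unit)) == pytest.approx(1.7, abs=1e-12)

    def test_autocorrelation_time_is_respected(self, ctx_unit):
        spec = ac.HarmonicAlchemySpec(k0=1.0, k1=1.0, mu0=0.0, mu1=1.0, seed=9)
        sched = ac.LambdaSchedule("uniform", [0.0, 1.0])
        tau = 0.005  # ns; samples at 1 ps → φ = exp(-0.2)
        (w,) = ac.sample_fep_windows(spec, sched, ctx_unit, 200_000,
                                     autocorr_time=tau)
        x = w.samples - w.samples.mean()
        lag1 = float(x[:-1] @ x[1:] / (x @ x))
        assert lag1 == pytest.approx(math.exp(-0.001 / tau), abs=0.01)

    def test_rejects_bad_inputs(self, ctx_unit, harmonic_toy):
        with pytest.raises(ValueError):
            ac.HarmonicAlchemySpec(k0=-1.0, k1=1.0)
        with pytest.raises(ac.SampleSizeError):
            ac.sample_fep_windows(harmonic_toy, ac.build_schedule("uniform", 4),
                                  ctx_unit, n_samples=5)
        with pytest.raises(ac.ScheduleError):
            ac.sample_fep_windows(harmonic_toy, ac.build_schedule("gauss_legendre_7"),
                                  ctx_unit, 100)


class TestSoftCore:
    SPEC = ac.SoftCoreLJSpec(epsilon=1.0, sigma=1.0, shift_coeff=7.0)

    def test_decoupled_state_is_zero(self):
        r = np.linspace(0.0, 5.0, 50)
        assert np.all(ac.softcore_potential(r, 0.0, self.SPEC) == 0.0)

    def test_full_coupling_recovers_plain_lj_minimum(self):
        r_min = 2.0 ** (1.0 / 6.0)
        assert ac.softcore_potential(r_min, 1.0, self.SPEC) == pytest.approx(-1.0, rel=1e-12)

    def test_finite_at_contact_for_partial_coupling(self):
        # direct evaluation of the separation-shifted formula at r=0, λ=0.5
        lam, delta = 0.5, 7.0
        s3 = (1.0 / (delta * (1.0 - lam))) ** 3
        expected = lam * 4.0 * (s3 * s3 - s3)
        assert ac.softcore_potential(0.0, lam, self.SPEC) == pytest.approx(expected, rel=1e-12)
        assert math.isfinite(ac.softcore_potential(0.0, 0.999, self.SPEC))

    def test_switching_shape_on_repulsive_branch(self):
        """Inside the core (r < σ) the coupling curve dips by at most the
        shifted attraction, then rises monotonically into the LJ wall."""
        lams = np.linspace(0.0, 1.0, 201)
        for r in (0.0, 0.3, 0.6, 0.9):
            u = np.array([ac.softcore_potential(r, l, self.SPEC) for l in lams])
            d = np.diff(u)
            sign_changes = np.count_nonzero(np.diff(np.sign(d[np.abs(d) > 1e-13])))
            assert sign_changes <= 1          # one dip at most, then monotone rise
            assert u.min() >= -self.SPEC.epsilon   # 4ε·x(x−1) ≥ −ε on x = (σ²/d)³
            assert u[-1] > 0 or math.isinf(u[-1])

    @given(st.floats(0.0, 0.999), st.floats(0.0, 4.0))
    @settings(max_examples=80, deadline=None)
    def test_continuity_in_both_arguments(self, lam, r):
        # continuous everywhere except the bare-LJ singularity (λ=1, r=0)
        eps = 1e-7
        u0 = ac.softcore_potential(r, lam, self.SPEC)
        u1 = ac.softcore_potential(r + eps, lam + eps, self.SPEC)
        assert abs(u1 - u0) < 1e-3 * (1.0 + abs(u0))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ac.softcore_potential(1.0, 1.5, self.SPEC)
        with pytest.raises(ValueError):
            ac.softcore_potential(-0.1, 0.5, self.SPEC)


class TestLangevin:
    def test_restrained_flat_potential_reproduces_boltzmann_variance(self, ctx300):
        """An unbiased harmonic well must show var = kT/k within 2% at 1e6 steps."""
        flat = ac.BindingPotential1D("flat")
        k = 10.0
        lang = ac.LangevinParams(diffusion=50.0, timestep=2e-5, n_steps=1_000_000, seed=5)
        rng = np.random.default_rng(5)
        traj = ac.langevin_trajectory(flat, lang, ctx300, z0=0.0,
                                      n_steps=lang.n_steps, rng=rng,
                                      bias_k=k, bias_center=0.0)
        assert traj.var() == pytest.approx(ctx300.kT / k, rel=0.02)

    def test_umbrella_window_variance_on_flat_potential(self, ctx300):
        flat = ac.BindingPotential1D("flat", bulk_onset=2.0)
        pull = ac.PullProtocol(k=30.0)
        lang = ac.LangevinParams(diffusion=50.0, timestep=5e-5, n_steps=60_000, seed=11)
        windows = ac.run_umbrella_protocol(flat, pull, lang, ctx300, margin=0.5)
        w = windows[2]
        assert w.samples.var() == pytest.approx(ctx300.kT / pull.k, rel=0.05)

    def test_near_zero_temperature_collapses_to_bias_minimum(self):
        cold = ac.ThermoContext(temperature=0.5)   # kT ≈ 1e-3 kcal/mol
        pot = ac.BindingPotential1D("gaussian_well", depth=-6.0, width=1.5)
        lang = ac.LangevinParams(diffusion=0.05, timestep=1e-4, n_steps=4000, seed=2)
        windows = ac.run_umbrella_protocol(pot, ac.PullProtocol(), lang, cold,
                                           margin=0.5)
        z = np.linspace(-1.0, pot.bulk_onset + 1.5, 4001)
        for w in windows:
            u = pot.energy(z) + w.bias(z)
            z_min = z[np.argmin(u)]
            assert abs(w.samples[-1000:].mean() - z_min) < 0.05

    def test_fixed_seed_reproduces_windows(self, ctx300):
        pot = ac.BindingPotential1D("gaussian_well", depth=-4.0, width=1.0)
        lang = ac.LangevinParams(diffusion=50.0, timestep=1e-4, n_steps=500, seed=21)
        a = ac.run_umbrella_protocol(pot, ac.PullProtocol(), lang, ctx300)
        b = ac.run_umbrella_protocol(pot, ac.PullProtocol(), lang, ctx300)
        for wa, wb in zip(a, b):
            assert np.array_equal(wa.samples, wb.samples)

    def test_span_not_covering_bulk_is_a_configuration_error(self, ctx300):
        pot = ac.BindingPotential1D("gaussian_well", depth=-4.0, width=1.0)
        lang = ac.LangevinParams(n_steps=200, seed=0)
        with pytest.raises(ConfigurationError):
            ac.run_umbrella_protocol(pot, ac.PullProtocol(), lang, ctx300,
                                     margin=-20.0)


class TestPotentialForms:
    def test_square_well_energy_and_bulk(self):
        pot = ac.BindingPotential1D("square_well", depth=-5.0, center=2.0, width=4.0)
        assert pot.energy(2.0) == -5.0
        assert pot.energy(10.0) == 0.0
        assert pot.bulk_onset == pytest.approx(4.0)

    def test_tabulated_matches_its_table(self):
        z = np.linspace(-2, 10, 500)
        w = -3.0 * np.exp(-0.5 * z ** 2)
        pot = ac.BindingPotential1D("tabulated", z_grid=z, values=w)
        assert pot.energy(0.0) == pytest.approx(-3.0, abs=1e-3)
        assert pot.well_position == pytest.approx(0.0, abs=0.05)

    def test_rejects_positive_depth_and_nonvanishing_bulk(self):
        with pytest.raises(ValueError):
            ac.BindingPotential1D("gaussian_well", depth=1.0, width=1.0)
        with pytest.raises(ValueError):
            ac.BindingPotential1D("gaussian_well", depth=-5.0, width=1.0,
                                  bulk_onset=0.5)


class TestFixtureFiles:
    def test_round_trip_is_bit_exact(self, tmp_path, ctx_unit, harmonic_toy):
        sched = ac.build_schedule("uniform", 3)
        fep = ac.sample_fep_windows(harmonic_toy, sched, ctx_unit, 50)
        gl7 = ac.build_schedule("gauss_legendre_7")
        ti = ac.sample_ti_nodes(harmonic_toy, gl7, ctx_unit, 50)
        flat = ac.BindingPotential1D("flat", bulk_onset=1.0)
        lang = ac.LangevinParams(n_steps=300, seed=1)
        umb = ac.run_umbrella_protocol(flat, ac.PullProtocol(), lang, ctx_unit,
                                       margin=0.5)
        written = ac.write_fixture_files(tmp_path, fep, ti, umb, ctx_unit)
        for orig, path in zip(fep, written["fep"]):
            back = ac.read_fep_window(path)
            assert np.array_equal(back.samples, orig.samples)
            assert back.lam == orig.lam and back.lam_target == orig.lam_target
        for orig, path in zip(ti, written["ti"]):
            back = ac.read_ti_node(path)
            assert np.array_equal(back.samples, orig.samples)
            assert back.weight == orig.weight
        for orig, path in zip(umb, written["umbrella"]):
            back = ac.read_umbrella_window(path)
            assert np.array_equal(back.samples, orig.samples)
            assert back.center == orig.center

    def test_empty_sample_set_is_refused(self):
        with pytest.raises(SampleSizeError):
            ac.EnergySeries(samples=np.array([]), lam=0.0)

    def test_nan_sample_names_the_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("# lambda0\t0.0\n# lambda1\t0.5\n0\t1.0\n1\tnan\n")
        with pytest.raises(ParseError) as err:
            ac.read_fep_window(p)
        assert err.value.line == 4

    def test_malformed_row_is_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("# center_angstrom\t1.0\n# force_constant_kcal_mol_A2\t30.0\n"
                     "0.1\t2.0\tsurplus\n")
        with pytest.raises(ParseError):
            ac.read_umbrella_window(p)


class TestBenchmarkConstruction:
    def test_stage_targets_sum_to_pmf_route_ddg(self, ctx300):
        bench = ac.two_channel_benchmark(ctx300, seed=1)
        for toy in bench.values():
            total = sum(toy.stage_targets(ctx300).values())
            assert total == pytest.approx(toy.ddG_analytic, abs=1e-9)

    def test_channels_differ_by_the_coupling_term(self, ctx300):
        bench = ac.two_channel_benchmark(ctx300, seed=1)
        a, b = bench["channelA"], bench["channelB"]
        assert a.coupling_kcal > b.coupling_kcal
        assert a.mutant.depth - a.wild.depth == pytest.approx(a.coupling_kcal)
        assert b.mutant.depth - b.wild.depth == pytest.approx(b.coupling_kcal)
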