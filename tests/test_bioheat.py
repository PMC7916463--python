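from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from photoseed.bioheat import (
    RefinementReport,
    SolverSettings,
    perfusion_coefficient,
    refine_to_asymptote,
    solve_bioheat,
    thermal_conductivity,
)
from photoseed.phantom import GLAND, GLAND_MATERIAL, TissuePhantom
from photoseed.synthetic import make_toy_phantom

GLAND_RATE = 1050 * 3617 * 5.0e-4 / (1041 * 2960)   # perfusion relaxation, 1/s
GLAND_OFFSET = 700 / (1050 * 3617 * 5.0e-4)         # Qmet / (rho_b c_b wb0), K


class TestThermalConductivity:
    def test_reference_temperature_returns_lambda37(self):
        assert thermal_conductivity(293.15, 0.48) == 0.48

    @pytest.mark.parametrize(
        "T,lam,expected",
        [(310.15, 0.48, 0.5029), (323.15, 0.21, 0.2276)],
    )
    def test_linear_law_values(self, T, lam, expected):
        assert thermal_conductivity(T, lam) == pytest.approx(expected, rel=1e-3)

    def test_extreme_cold_clamped_at_floor(self):
        assert thermal_conductivity(100.0, 0.21, coeff=0.01, floor=0.01) == 0.01


class TestPerfusionCoefficient:
    @pytest.mark.parametrize(
        "omega,expected",
        [(0.0, 1.0), (0.05, 1.6), (0.1, 0.9), (0.5, 0.5), (1.0, 0.0), (2.0, 0.0)],
    )
    def test_branch_values(self, omega, expected):
        assert perfusion_coefficient(omega, 1.0) == pytest.approx(expected)

    def test_continuity_at_both_breakpoints(self):
        eps = 1e-12
        for brk in (0.1, 1.0):
            lo = perfusion_coefficient(brk - eps, 1.0)
            hi = perfusion_coefficient(brk + eps, 1.0)
            assert abs(lo - hi) < 1e-9

    @given(st.floats(min_value=0.0, max_value=3.0))
    @hyp_settings(derandomize=True, max_examples=200)
    def test_no_discontinuity_anywhere(self, omega):
        eps = 1e-9
        lo = perfusion_coefficient(max(omega - eps, 0.0), 1.0)
        hi = perfusion_coefficient(omega + eps, 1.0)
        assert abs(hi - lo) < 1e-6

    def test_negative_damage_rejected(self):
        with pytest.raises(ValueError):
            perfusion_coefficient(-0.1, 1.0)


class TestSolverBasics:
    def test_equilibrium_stays_exactly_uniform(self, inert_gland_cube):
        s = SolverSettings(dt=1.0, duration=10.0, t_init=310.15,
                           boundary="insulated", snapshot_every=10.0)
        h = solve_bioheat(inert_gland_cube, np.zeros(inert_gland_cube.shape), s)
        np.testing.assert_allclose(h.final_temperature, 310.15, atol=1e-9)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SolverSettings(dt=-1.0)
        with pytest.raises(ValueError):
            SolverSettings(boundary="periodic")
        with pytest.raises(ValueError):
            SolverSettings(dt=1.0, snapshot_every=0.5)

    def test_source_grid_mismatch_raises(self, inert_gland_cube):
        with pytest.raises(ValueError, match="match"):
            solve_bioheat(inert_gland_cube, np.zeros((3, 3, 3)), SolverSettings())

    def test_maximum_principle_without_sources(self, inert_gland_cube):
        ph = inert_gland_cube
        s = SolverSettings(dt=5.0, duration=100.0, t_init=320.0,
                           bc_temperature=310.0, boundary="fixed",
                           coupling="one-way", snapshot_every=5.0)
        h = solve_bioheat(ph, np.zeros(ph.shape), s)
        for T in h.temperatures:
            assert T.max() <= 320.0 + 1e-9
            assert T.min() >= 310.0 - 1e-9

    def test_probe_traces_sampled_every_step(self, inert_gland_cube):
        s = SolverSettings(dt=1.0, duration=10.0, boundary="insulated",
                           snapshot_every=5.0)
        h = solve_bioheat(inert_gland_cube, np.zeros(inert_gland_cube.shape), s,
                          probes={"c": (3e-3, 3e-3, 3e-3)})
        assert len(h.probe_times) == 11
        assert len(h.probe_temperature["c"]) == 11
        assert np.all(np.diff(h.times) > 0)


class TestSlabClosedForm:
    def slab_rise(self, Q=1.0e4, dt=100.0, duration=30000.0, spacing=None):
        ph, ref = make_toy_phantom("slab")
        if spacing is not None:
            import photoseed.phantom as pm

            L = 0.02
            n = int(round(L / spacing))
            labels = np.zeros((n, 1, 1), dtype=np.uint8)
            ph = TissuePhantom(labels, (spacing,) * 3, ph.materials)
        s = SolverSettings(
            dt=dt, duration=duration, t_init=293.15, bc_temperature=293.15,
            boundary=("fixed", "insulated", "insulated"),
            conductivity_coeff=0.0, coupling="one-way", snapshot_every=duration,
        )
        h = solve_bioheat(ph, np.full(ph.shape, Q), s)
        return h, float(h.final_temperature.max() - 293.15), ref["max_rise"](Q)

    def test_steady_peak_matches_parabolic_solution(self):
        _, rise, analytic = self.slab_rise()
        assert analytic == pytest.approx(2.381, rel=1e-3)
        assert rise == pytest.approx(analytic, rel=1e-6)

    def test_refinement_sequence_converges(self):
        def run(h):
            hist, rise, _ = self.slab_rise(spacing=h)
            return hist, rise

        rep = refine_to_asymptote(run, 2.0e-3, factor=2.0, tolerance=1e-3,
                                  max_levels=3)
        assert rep.converged
        _, _, analytic = self.slab_rise()
        assert rep.interface_temperatures[-1] == pytest.approx(analytic, rel=0.01)


class TestPerfusionRelaxation:
    def run_uniform_gland(self, dt=2.0, duration=15000.0):
        labels = np.full((4, 4, 4), GLAND, dtype=np.uint8)
        ph = TissuePhantom(labels, (1e-3,) * 3, {GLAND: GLAND_MATERIAL})
        s = SolverSettings(dt=dt, duration=duration, t_init=312.15,
                           t_blood=310.15, boundary="insulated",
                           coupling="one-way", snapshot_every=duration)
        return solve_bioheat(ph, np.zeros(ph.shape), s,
                             probes={"c": (2e-3, 2e-3, 2e-3)})

    def test_relaxes_to_metabolic_offset(self):
        h = self.run_uniform_gland()
        offset = float(h.final_temperature.mean() - 310.15)
        assert offset == pytest.approx(GLAND_OFFSET, rel=5e-3)
        assert GLAND_OFFSET == pytest.approx(0.369, rel=2e-3)

    def test_relaxation_rate_matches_scalar_ode(self):
        h = self.run_uniform_gland()
        t, T = h.probe_times, h.probe_temperature["c"]
        y = T - (310.15 + GLAND_OFFSET)
        mask = t <= 3000
        rate = -np.polyfit(t[mask], np.log(np.abs(y[mask])), 1)[0]
        assert rate == pytest.approx(GLAND_RATE, rel=5e-3)
        assert GLAND_RATE == pytest.approx(6.16e-4, rel=1e-3)


class TestCouplingAndConservation:
    def test_energy_balance_insulated_no_perfusion(self, inert_gland_cube):
        ph = inert_gland_cube
        Q = 5.0e4
        s = SolverSettings(dt=1.0, duration=20.0, t_init=310.15,
                           boundary="insulated", snapshot_every=1.0,
                           conductivity_coeff=0.0)
        h = solve_bioheat(ph, np.full(ph.shape, Q), s)
        rho_c = ph.rho_c_field()
        vol = ph.voxel_volume
        power_in = Q * ph.labels.size * vol
        for T0, T1, dt in zip(h.temperatures, h.temperatures[1:], np.diff(h.times)):
            stored = float(np.sum(rho_c * (T1 - T0)) * vol / dt)
            assert stored == pytest.approx(power_in, rel=0.01)

    def test_two_way_equals_one_way_while_damage_is_null(self, inert_gland_cube):
        # at 250 K the Arrhenius rate underflows float64 resolution, so the
        # damage feedback path is exercised with Omega numerically zero
        ph = inert_gland_cube
        src = np.zeros(ph.shape)
        src[3, 3, 3] = 1.0e5
        base = dict(dt=1.0, duration=20.0, t_init=250.0, t_blood=250.0,
                    bc_temperature=250.0, boundary="fixed", snapshot_every=20.0)
        h2 = solve_bioheat(ph, src, SolverSettings(coupling="two-way", **base))
        h1 = solve_bioheat(ph, src, SolverSettings(coupling="one-way", **base))
        np.testing.assert_array_equal(h2.final_temperature, h1.final_temperature)

    def test_pointwise_monotone_in_power(self, small_seed_phantom):
        from photoseed.optics import fluence, heat_source
        from photoseed.phantom import LaserBeam

        ph = small_seed_phantom
        ex, ey, ez = ph.extent
        s = SolverSettings(dt=2.0, duration=120.0, snapshot_every=120.0)
        finals = []
        for p0 in (0.5, 1.0, 2.0):
            beam = LaserBeam(p0=p0, entry_point=(ex / 2, ey / 2, ez),
                             direction=(0, 0, -1.0))
            q = heat_source(fluence(ph, beam), ph)
            finals.append(solve_bioheat(ph, q, s).final_temperature)
        assert np.all(finals[1] >= finals[0] - 1e-9)
        assert np.all(finals[2] >= finals[1] - 1e-9)


class TestRefineToAsymptote:
    def test_infinite_tolerance_returns_after_first_solve(self):
        calls = []

        def run(h):
            calls.append(h)
            return None, 1.0

        rep = refine_to_asymptote(run, 1e-3, tolerance=np.inf)
        assert len(calls) == 1 and rep.converged

    def test_diverging_sequence_raises(self):
        vals = iter([1.0, 2.0, 4.0, 8.0, 17.0])

        def run(h):
            return None, next(vals)

        with pytest.raises(RuntimeError, match="diverge"):
            refine_to_asymptote(run, 1e-3, tolerance=1e-9, max_levels=5)

    def test_report_carries_full_sequence(self):
        vals = iter([5.0, 4.5, 4.45])

        def run(h):
            return None, next(vals)

        rep = refine_to_asymptote(run, 4e-3, tolerance=0.1, max_levels=5)
        assert isinstance(rep, RefinementReport)
        assert rep.spacings == [4e-3, 2e-3, 1e-3]
        assert rep.converged
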