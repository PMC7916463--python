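import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from photoseed.calorimetry import (
    HeatingCurve,
    ViabilityCount,
    cell_viability,
    conversion_efficiency,
    delta_T,
    initial_rate,
    read_heating_curve,
    relative_viability,
    summarize_batch,
)
from photoseed.synthetic import CurveGeneratorSpec, make_heating_curve


def line_curve(slope=0.06, baseline=25.0, duration=300.0, **meta):
    t = np.arange(duration + 1)
    return HeatingCurve(t, baseline + slope * t, **meta)


class TestHeatingCurveValidation:
    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            HeatingCurve(np.array([0.0]), np.array([25.0]))

    def test_rejects_nonzero_start_and_nonmonotone_times(self):
        with pytest.raises(ValueError):
            HeatingCurve(np.array([1.0, 2.0]), np.array([25.0, 26.0]))
        with pytest.raises(ValueError):
            HeatingCurve(np.array([0.0, 2.0, 1.0]), np.array([25.0, 26.0, 27.0]))

    def test_csv_roundtrip_and_header_check(self, tmp_path):
        p = tmp_path / "curve.csv"
        p.write_text("time_s,temp_C\n0,25.0\n1,25.1\n2,25.2\n")
        c = read_heating_curve(p, p0=0.5, a810=1.54)
        assert c.times[-1] == 2.0 and c.p0 == 0.5
        bad = tmp_path / "bad.csv"
        bad.write_text("t,T\n0,25\n1,26\n")
        with pytest.raises(ValueError, match="columns"):
            read_heating_curve(bad)


class TestInitialRate:
    def test_noiseless_line_recovers_slope_exactly(self):
        assert initial_rate(line_curve(slope=0.06)) == pytest.approx(0.06, abs=1e-12)

    def test_constant_curve_has_zero_rate(self):
        assert initial_rate(line_curve(slope=0.0)) == pytest.approx(0.0, abs=1e-12)

    def test_saturating_curve_slope_between_endpoint_tangents(self):
        spec = CurveGeneratorSpec(rise=27.5, tau=180.0, noise_sd=0.0)
        curve, truth = make_heating_curve(spec)
        fit = initial_rate(curve, window=30.0)
        # dense finite-difference oracle over [0, 30 s]
        tt = np.linspace(0, 30, 30001)
        dense = 27.5 / 180.0 * np.exp(-tt / 180.0)
        assert dense.min() < fit < dense.max()
        assert fit == pytest.approx(0.139, abs=0.002)
        assert truth.initial_slope == pytest.approx(0.153, abs=0.001)

    def test_window_must_contain_two_samples(self):
        c = HeatingCurve(np.array([0.0, 40.0]), np.array([25.0, 27.0]))
        with pytest.raises(ValueError):
            initial_rate(c, window=30.0)


class TestConversionEfficiency:
    def test_reference_arithmetic(self):
        c = line_curve(p0=0.5, a810=1.54, m_w=0.5)
        eta = conversion_efficiency(c, rate=0.06)
        assert eta == pytest.approx(0.259, abs=0.001)

    def test_zero_rate_gives_zero(self):
        c = line_curve(p0=0.5, a810=1.54)
        assert conversion_efficiency(c, 0.0) == 0.0

    def test_opaque_limit_drops_absorbance_factor(self):
        c = line_curve(p0=0.5, a810=500.0, m_w=0.5)
        eta = conversion_efficiency(c, 0.06)
        assert eta == pytest.approx(0.5 * 4.185 * 0.06 / 0.5, rel=1e-12)

    def test_zero_absorbance_with_heating_is_an_error(self):
        c = line_curve(p0=0.5, a810=0.0)
        with pytest.raises(ZeroDivisionError):
            conversion_efficiency(c, 0.06)

    @given(st.floats(min_value=-20, max_value=20))
    @hyp_settings(derandomize=True, max_examples=50)
    def test_invariant_to_constant_temperature_offset(self, offset):
        base = line_curve(p0=0.5, a810=1.54)
        shifted = HeatingCurve(base.times, base.temperatures + offset,
                               p0=0.5, a810=1.54)
        r0, r1 = initial_rate(base), initial_rate(shifted)
        assert conversion_efficiency(base, r0) == pytest.approx(
            conversion_efficiency(shifted, r1), rel=1e-9)


class TestDeltaT:
    def test_linear_curve_rise_over_5_min(self):
        assert delta_T(line_curve(slope=0.05)) == pytest.approx(15.0)

    def test_constant_curve_has_zero_rise(self):
        assert delta_T(line_curve(slope=0.0)) == 0.0

    def test_saturating_curve_approaches_plateau(self):
        spec = CurveGeneratorSpec(rise=27.46, tau=180.0, noise_sd=0.0,
                                  duration=3600.0)
        curve, _ = make_heating_curve(spec)
        assert delta_T(curve, endpoint=3600.0) == pytest.approx(27.46, abs=0.01)

    def test_endpoint_beyond_data_raises(self):
        c = line_curve(duration=100.0)
        with pytest.raises(ValueError, match="beyond"):
            delta_T(c, endpoint=300.0)


class TestViability:
    def test_printed_formula_orientation(self):
        r = cell_viability(ViabilityCount(total=113, viable=59))
        assert r.formula_pct == pytest.approx(47.8, abs=0.1)
        assert r.viable_pct == pytest.approx(52.2, abs=0.1)

    @pytest.mark.parametrize(
        "total,viable,formula",
        [(100, 100, 0.0), (100, 0, 100.0)],
    )
    def test_degenerate_counts(self, total, viable, formula):
        r = cell_viability(ViabilityCount(total=total, viable=viable))
        assert r.formula_pct == pytest.approx(formula)

    @given(st.integers(min_value=1, max_value=10000), st.data())
    @hyp_settings(derandomize=True, max_examples=100)
    def test_orientations_always_sum_to_100(self, total, data):
        viable = data.draw(st.integers(min_value=0, max_value=total))
        r = cell_viability(ViabilityCount(total=total, viable=viable))
        assert r.formula_pct + r.viable_pct == pytest.approx(100.0)

    def test_relative_viability_against_control(self):
        cond = ViabilityCount(total=100, viable=40)
        ctrl = ViabilityCount(total=100, viable=80)
        assert relative_viability(cond, ctrl) == pytest.approx(0.5)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ViabilityCount(total=0, viable=0)
        with pytest.raises(ValueError):
            ViabilityCount(total=10, viable=11)


class TestBatchSummary:
    def test_table_layout_two_samples_two_powers(self):
        curves = []
        for label, a810, wt in (("AuNP-5", 1.28, 5.0), ("AuNP-10", 1.54, 10.0)):
            for p0 in (0.5, 1.0):
                c, _ = make_heating_curve(
                    CurveGeneratorSpec(rise=20.0, tau=180.0, noise_sd=0.0),
                    label=label, p0=p0, a810=a810, au_wt_pct=wt,
                )
                curves.append(c)
        df = summarize_batch(curves)
        assert list(df.columns) == [
            "sample", "au_wt_pct", "P0_W", "dTdt_C_per_s", "deltaT_C", "eta_pct"]
        assert len(df) == 4
        assert set(df["P0_W"]) == {0.5, 1.0}

    def test_optional_control_subtraction(self):
        sample, _ = make_heating_curve(
            CurveGeneratorSpec(rise=20.0, noise_sd=0.0), label="s",
            p0=1.0, a810=1.54)
        control, _ = make_heating_curve(
            CurveGeneratorSpec(rise=2.0, noise_sd=0.0), label="ctrl",
            p0=1.0, a810=1.54)
        plain = summarize_batch([sample])
        adjusted = summarize_batch([sample], control=control)
        assert adjusted["deltaT_C"][0] < plain["deltaT_C"][0]
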