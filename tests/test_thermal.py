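"""Formula oracles and invariants for indices, state and fluxes.

Hand-computed expected values were frozen from independent evaluation of
the printed closed forms (see docstrings of the module under test).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bovitherm import thermal
from bovitherm.thermal import PhysicalConstants

TA = st.floats(min_value=-10, max_value=45)
RH = st.floats(min_value=0.5, max_value=100)
U = st.floats(min_value=0, max_value=10)
QSR = st.floats(min_value=0, max_value=1200)


class TestDewPoint:
    def test_saturation_equals_air_temperature(self):
        assert thermal.dew_point(25, 100) == pytest.approx(25.0, abs=1e-9)

    def test_hand_value(self):
        # Magnus formula at Ta=25, RH=50, evaluated by hand
        assert thermal.dew_point(25, 50) == pytest.approx(13.857612540147446, rel=1e-12)

    def test_rh_zero_rejected(self):
        with pytest.raises(ValueError):
            thermal.dew_point(25, 0)

    @given(Ta=TA, RH=st.floats(min_value=1, max_value=99))
    @settings(max_examples=50, deadline=None)
    def test_below_air_temperature(self, Ta, RH):
        assert thermal.dew_point(Ta, RH) < Ta


class TestThi:
    def test_hand_value(self):
        assert thermal.thi(25, 50) == pytest.approx(71.775, rel=1e-12)

    def test_rh_100_reduces_to_linear(self):
        for Ta in (0.0, 15.0, 30.0):
            assert thermal.thi(Ta, 100) == pytest.approx(1.8 * Ta + 32, rel=1e-12)

    def test_pivot_temperature(self):
        # second factor vanishes at Ta = 26/1.8
        Ta = 26.0 / 1.8
        for rh in (0, 37, 100):
            assert thermal.thi(Ta, rh) == pytest.approx(58.0, rel=1e-12)

    @given(Ta=TA, RH=st.floats(min_value=0, max_value=100))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_ta(self, Ta, RH):
        assert thermal.thi(Ta + 0.5, RH) > thermal.thi(Ta, RH)

    def test_rh_direction_switches_at_pivot(self):
        assert thermal.thi(20, 80) > thermal.thi(20, 20)   # above 14.44 degC
        assert thermal.thi(10, 80) < thermal.thi(10, 20)   # below


class TestBghi:
    def test_hand_value(self):
        assert thermal.bghi(30, 15) == pytest.approx(76.9, rel=1e-12)

    def test_constant_offset(self):
        assert thermal.bghi(0, 0) == pytest.approx(41.5, rel=1e-12)

    def test_chained_with_dew_point(self):
        # at saturation Tdp = Ta = 30
        tdp = thermal.dew_point(30, 100)
        assert thermal.bghi(30, tdp) == pytest.approx(82.3, abs=1e-9)


class TestAthi:
    def test_hand_value(self):
        assert thermal.athi(25, 50, 1, 500) == pytest.approx(77.618, rel=1e-12)

    def test_rh_term_vanishes_at_14_4(self):
        vals = [thermal.athi(14.4, rh, 0, 0) for rh in (0, 50, 100)]
        assert all(v == pytest.approx(4.51 + 11.52 + 46.4, rel=1e-12) for v in vals)

    def test_linear_in_wind(self):
        delta = thermal.athi(25, 50, 2, 500) - thermal.athi(25, 50, 1, 500)
        assert delta == pytest.approx(-1.992, rel=1e-12)


class TestCci:
    def test_qsr_component_at_origin(self):
        assert thermal._cci_eq_qsr(0.0, 0.0) == pytest.approx(-2.0, rel=1e-12)

    def test_qsr_component_monotone(self):
        grid = np.linspace(0, 1000, 200)
        vals = thermal._cci_eq_qsr(grid, 25.0)
        assert np.all(np.diff(vals) > 0)

    def test_component_isolation(self):
        # CCI - Ta at Qsr=0 equals the sum of the three corrections
        got = thermal.cci(20, 50, 0.5, 0) - 20
        expect = (
            thermal._cci_eq_u(0.5)
            + thermal._cci_eq_qsr(0.0, 20.0)
            + thermal._cci_eq_rh(50.0, 20.0)
        )
        assert got == pytest.approx(float(expect), rel=1e-12)

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            thermal.cci(20, 50, -1, 0)

    def test_wind_correction_decreasing(self):
        grid = np.linspace(0, 10, 100)
        vals = thermal._cci_eq_u(grid)
        assert np.all(np.diff(vals) < 0)


class TestDhli:
    def test_monotone_in_tbg(self):
        grid = np.linspace(15, 45, 100)
        vals = thermal.dhli(grid, 50.0)
        assert np.all(np.diff(vals) > 0)

    def test_bounded_on_grid(self):
        tbg, rh = np.meshgrid(np.linspace(-10, 60, 40), np.linspace(1, 100, 40))
        vals = thermal.dhli(tbg, rh)
        assert np.all(np.isfinite(vals))
        assert vals.min() > -1.0 and vals.max() < 105.0

    def test_deterministic(self):
        assert thermal.dhli(30, 50) == thermal.dhli(30, 50)


class TestEtic:
    def test_all_corrections_vanish(self):
        assert thermal.etic(20, 100, 0, 0) == pytest.approx(20.0, rel=1e-12)

    def test_hand_value(self):
        # 30 - 0.0038*30*50 - 0.1173*1*9.2 = 23.22084
        assert thermal.etic(30, 50, 1, 0) == pytest.approx(23.22084, rel=1e-9)

    def test_wind_factor_zero_at_39_2(self):
        for u in (0, 1, 5):
            assert thermal.etic(39.2, 100, u, 0) == pytest.approx(39.2, rel=1e-12)


class TestStic:
    def test_vapor_term_vanishes_at_saturation(self):
        # at RH=100 the result is independent of the 10^ vapor term
        got = thermal.stic(25, 100, 0, 0)
        assert got == pytest.approx(1.73 * 25 + 16.08, rel=1e-12)

    def test_monotone_in_ta(self):
        grid = np.linspace(10, 40, 100)
        vals = thermal.stic(grid, 60.0, 0.5, 0.0)
        assert np.all(np.diff(vals) > 0)

    def test_deterministic(self):
        assert thermal.stic(30, 60, 1, 500) == thermal.stic(30, 60, 1, 500)


class TestThermalState:
    def test_coat_temperature_hand_value(self):
        st = thermal.thermal_state(20, 50, 1, 0)
        assert st.Tc == pytest.approx(32.52, rel=1e-12)

    def test_sweating_branches_at_35(self):
        # quadratic branch evaluated at Ts=35 gives 77.5025, linear 79.127;
        # the boundary itself belongs to the linear branch
        assert thermal._sweating_rate(34.99999) == pytest.approx(
            1.1665 * 34.99999**2 - 64.166 * 34.99999 + 894.35, rel=1e-9
        )
        assert float(thermal._sweating_rate(35.0)) == pytest.approx(79.127, rel=1e-9)
        quad_at_35 = 1.1665 * 35.0**2 - 64.166 * 35.0 + 894.35
        assert quad_at_35 == pytest.approx(77.5025, rel=1e-9)

    def test_vapor_pressure_hand_value(self):
        st = thermal.thermal_state(25, 50, 1, 0)
        assert st.Pe_a == pytest.approx(3.1686302003674944, rel=1e-12)

    def test_respiratory_frequency_hand_value(self):
        st = thermal.thermal_state(25, 50, 1, 0)
        assert st.Fr == pytest.approx(34.06430289328677, rel=1e-12)

    def test_trad_equals_ta(self):
        st = thermal.thermal_state(31.5, 40, 2, 600)
        assert st.Trad == 31.5

    def test_tidal_volume_floor(self):
        # at very low Ta the printed linear Vt would go negative
        st = thermal.thermal_state(-10, 50, 1, 0, PhysicalConstants(vt_floor=1e-4))
        assert st.Vt >= 1e-4

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            thermal.thermal_state(25, 0, 1, 0)
        with pytest.raises(ValueError):
            thermal.thermal_state(25, 50, -1, 0)

    @given(Ta=TA, RH=st.floats(min_value=1, max_value=100), U=U, Qsr=QSR)
    @settings(max_examples=100, deadline=None)
    def test_state_invariants(self, Ta, RH, U, Qsr):
        st_ = thermal.thermal_state(Ta, RH, U, Qsr)
        assert st_.Pe_a > 0 and st_.Pe_b > 0 and st_.Fr > 0 and st_.rr > 0
        assert st_.Nu >= 0


class TestNusselt:
    def test_zero_wind(self):
        assert thermal.nusselt(0.0) == 0.0

    def test_positive_and_increasing(self):
        grid = np.linspace(0.01, 10, 200)
        vals = thermal.nusselt(grid)
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) > 0)


class TestHeatFluxes:
    def test_evaporative_hand_value(self):
        st = thermal.thermal_state(25, 50, 1, 0)
        st.Rsw = 100.0
        fl = thermal.heat_fluxes(st, 25, 50)
        assert fl.Qevap == pytest.approx(100 * 2260 / 3600, rel=1e-12)

    def test_zero_sweating_zero_evaporation(self):
        st = thermal.thermal_state(25, 50, 1, 0)
        st.Rsw = 0.0
        assert thermal.heat_fluxes(st, 25, 50).Qevap == 0.0

    def test_equal_temperatures_zero_sensible(self):
        st = thermal.thermal_state(25, 50, 1, 0)
        st.Tc = 25.0
        st.Trad = 25.0
        fl = thermal.heat_fluxes(st, 25, 50)
        assert fl.Qconv == 0.0 and fl.Qrad == 0.0 and fl.Qsens == 0.0

    def test_qconv_sign_matches_temperature_difference(self):
        st = thermal.thermal_state(25, 50, 1, 0)
        assert np.sign(thermal.heat_fluxes(st, 25, 50).Qconv) == np.sign(st.Tc - 25)

    def test_qconv_zero_without_wind(self):
        st = thermal.thermal_state(25, 50, 0, 0)
        assert thermal.heat_fluxes(st, 25, 50).Qconv == 0.0

    def test_partition_identities_random_states(self, rng):
        n = 10_000
        Ta = rng.uniform(-10, 45, n)
        RH = rng.uniform(1, 100, n)
        U = rng.uniform(0, 10, n)
        Qsr = rng.uniform(0, 1200, n)
        st = thermal.thermal_state(Ta, RH, U, Qsr)
        fl = thermal.heat_fluxes(st, Ta, RH)
        assert np.array_equal(fl.Qlat, fl.Qresp + fl.Qevap)
        assert np.array_equal(fl.Qsens, fl.Qconv + fl.Qrad)

    def test_vapor_convention_switch(self):
        st = thermal.thermal_state(25, 50, 1, 0)
        actual = thermal.heat_fluxes(st, 25, 50, PhysicalConstants(ambient_vapor_actual=True))
        literal = thermal.heat_fluxes(st, 25, 50, PhysicalConstants(ambient_vapor_actual=False))
        assert actual.Qresp > literal.Qresp  # lower ambient vapor => more loss


class TestBatchMode:
    def test_vectorized_equals_scalar(self, rng):
        import pandas as pd

        n = 50
        table = pd.DataFrame({
            "Ta": rng.uniform(10, 40, n),
            "Tbg": rng.uniform(10, 45, n),
            "RH": rng.uniform(20, 100, n),
            "U": rng.uniform(0, 5, n),
            "Qsr": rng.uniform(0, 1000, n),
        })
        out = thermal.compute_features(table)
        for i in range(0, n, 7):
            r = table.iloc[i]
            assert out["THI"].iloc[i] == thermal.thi(r.Ta, r.RH)
            assert out["ETIC"].iloc[i] == thermal.etic(r.Ta, r.RH, r.U, r.Qsr)
            assert out["CCI"].iloc[i] == thermal.cci(r.Ta, r.RH, r.U, r.Qsr)
            st = thermal.thermal_state(r.Ta, r.RH, r.U, r.Qsr)
            fl = thermal.heat_fluxes(st, r.Ta, r.RH)
            assert out["Qsens"].iloc[i] == pytest.approx(fl.Qsens, rel=1e-12)

    def test_all_indices_finite_on_grid(self):
        import pandas as pd

        ta, rh, u, qsr = np.meshgrid(
            np.linspace(-10, 45, 8), np.linspace(1, 100, 8),
            np.linspace(0, 10, 5), np.linspace(0, 1200, 5),
        )
        table = pd.DataFrame({
            "Ta": ta.ravel(), "Tbg": ta.ravel() + 1.0, "RH": rh.ravel(),
            "U": u.ravel(), "Qsr": qsr.ravel(),
        })
        out = thermal.compute_features(table)
        for col in thermal.INDEX_NAMES:
            assert np.all(np.isfinite(out[col]))

    def test_missing_column_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing environment"):
            thermal.compute_features(pd.DataFrame({"Ta": [20.0]}))


def test_constants_validated():
    with pytest.raises(ValueError):
        PhysicalConstants(S=-1.0)
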