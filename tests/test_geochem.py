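"""Electron and ¹³C mass-balance arithmetic, rounding policy and the
carbonate-speciation equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve

from fesip import geochem as g
from fesip.errors import (
    ConfigError,
    MeasurementInconsistencyError,
    UndefinedRatioError,
)


class TestRounding:
    @pytest.mark.parametrize("x, ndigits, expected", [
        (0.5, 0, 1.0), (-0.5, 0, -1.0), (2.5, 0, 3.0),
        (26.33, 0, 26.0), (35.17, 0, 35.0), (4.649, 1, 4.6),
    ])
    def test_half_away_from_zero(self, x, ndigits, expected):
        assert g.round_half_away(x, ndigits) == expected

    @pytest.mark.parametrize("x, expected", [
        (73.958, 74.0), (83.87, 84.0), (4.615, 4.6), (0.145, 0.15),
        (11.03, 11.0), (192.4, 190.0), (0.0, 0.0),
    ])
    def test_two_significant_figures(self, x, expected):
        assert g.round_sig(x, 2) == expected


class TestElectronStoichiometry:
    @pytest.mark.parametrize("acetate, electrons", [
        (24.0, 192.0),   # fully oxidized acetate, 8 e- per mole
        (17.0, 136.0),
        (0.0, 0.0),
    ])
    def test_yield(self, acetate, electrons):
        assert g.acetate_electron_yield(acetate) == electrons

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            g.acetate_electron_yield(-1.0)

    @given(a=st.floats(0, 1e4), b=st.floats(0, 1e4))
    @settings(max_examples=50, derandomize=True)
    def test_linearity(self, a, b):
        assert g.acetate_electron_yield(a + b) == pytest.approx(
            g.acetate_electron_yield(a) + g.acetate_electron_yield(b)
        )


class TestElectronBalance:
    @pytest.mark.parametrize("fe2, eprod, percent", [
        (142.0, 192.0, 74.0), (234.0, 279.0, 84.0), (23.0, 164.0, 14.0),
        (60.0, 194.0, 31.0), (6.0, 130.0, 4.6), (15.0, 136.0, 11.0),
        (0.0, 192.0, 0.0),
    ])
    def test_percent_to_fe(self, fe2, eprod, percent):
        bal = g.electron_balance(fe2, eprod)
        assert bal.percent_to_fe == percent
        assert bal.e_to_fe == fe2  # one electron per Fe(III) -> Fe(II)

    def test_zero_production_undefined(self):
        with pytest.raises(UndefinedRatioError):
            g.electron_balance(10.0, 0.0)

    def test_over_100_percent_flagged_not_clamped(self):
        with pytest.warns(UserWarning, match="exceeds production"):
            bal = g.electron_balance(300.0, 192.0)
        assert bal.exceeds_production
        assert bal.percent_to_fe_raw > 100.0


class TestIronPools:
    @pytest.mark.parametrize("total, fe2, fe3", [
        (155.0, 75.0, 80.0), (63.0, 63.0, 0.0), (75.0, 20.0, 55.0),
    ])
    def test_reducible_fe3_by_difference(self, total, fe2, fe3):
        assert g.reducible_fe3(total, fe2) == fe3

    @given(total=st.floats(0, 500), fe2=st.floats(0, 500))
    @settings(max_examples=50, derandomize=True)
    def test_iron_conservation(self, total, fe2):
        if fe2 > total:
            with pytest.raises(MeasurementInconsistencyError):
                g.reducible_fe3(total, fe2)
        else:
            assert fe2 + g.reducible_fe3(total, fe2) == total

    def test_inconsistency_names_time_point(self):
        with pytest.raises(MeasurementInconsistencyError, match="day 2.5"):
            g.reducible_fe3(60.0, 70.0, time_day=2.5)

    @pytest.mark.parametrize("fe, units", [(140.0, 28.0), (5.0, 1.0), (0.0, 0.0)])
    def test_ferrihydrite_formula_units(self, fe, units):
        # Fe5HO8·4H2O carries five Fe per formula unit
        assert g.ferrihydrite_formula_units(fe) == units


class TestLabeledGas:
    @pytest.mark.parametrize("gas, atom, labeled", [
        (10.0, 50.0, 5.0), (12.4, 80.0, 9.92), (7.0, 0.0, 0.0),
    ])
    def test_amount(self, gas, atom, labeled):
        assert g.labeled_gas_amount(gas, atom) == pytest.approx(labeled)

    @pytest.mark.parametrize("atom", [-1.0, 101.0])
    def test_atom_percent_domain(self, atom):
        with pytest.raises(ValueError):
            g.labeled_gas_amount(1.0, atom)


def _oracle_dissolved(gas_umol, ph, sys):
    """Independent numerical solve of the coupled Henry/dissociation system.

    Unknowns [CO2(aq), HCO3-, CO3--]; residuals are the three equilibrium
    laws at fixed headspace partial pressure and pH.
    """
    p = gas_umol * 1e-6 * g.R_L_ATM * sys.temperature_k / sys.v_gas_l
    h = 10.0 ** (-ph)
    k1, k2 = 10.0 ** (-sys.pk1), 10.0 ** (-sys.pk2)

    def residuals(x):
        co2aq, hco3, co3 = x
        return [co2aq - sys.kh * p, hco3 * h - k1 * co2aq, co3 * h - k2 * hco3]

    sol = fsolve(residuals, [1e-5, 1e-5, 1e-8], full_output=False)
    return float(sum(sol)) * sys.v_liquid_l * 1e6


class TestDissolvedCO2:
    def test_zero_gas_zero_pool(self):
        assert g.dissolved_co2(0.0, 7.7) == 0.0

    def test_monotone_in_ph(self):
        assert g.dissolved_co2(2.6, 5.0) < g.dissolved_co2(2.6, 7.7)

    @given(gas=st.floats(0.01, 50), k=st.floats(0.1, 10))
    @settings(max_examples=50, derandomize=True)
    def test_homogeneous_degree_one_in_gas(self, gas, k):
        assert g.dissolved_co2(k * gas, 7.0) == pytest.approx(
            k * g.dissolved_co2(gas, 7.0), rel=1e-12
        )

    def test_agrees_with_numerical_equilibrium_solver(self):
        sys = g.CarbonateSystem()
        rng = np.random.default_rng(42)
        for _ in range(100):
            gas = rng.uniform(0.1, 30.0)
            ph = rng.uniform(5.0, 9.0)
            ours = g.dissolved_co2(gas, ph, sys)
            oracle = _oracle_dissolved(gas, ph, sys)
            assert ours == pytest.approx(oracle, rel=1e-6)

    def test_nonphysical_volumes_rejected(self):
        with pytest.raises(ConfigError):
            g.CarbonateSystem(v_gas_l=-1.0)


class TestRecoveryAndSuppression:
    @pytest.mark.parametrize("ch4, co2, dis, recovery", [
        (7.6, 4.1, 8.0, 33.0), (13.0, 2.7, 2.8, 31.0), (0.0, 0.0, 0.0, 0.0),
    ])
    def test_recovery_integer_percent(self, ch4, co2, dis, recovery):
        assert g.c13_recovery(ch4, co2, dis, 60.0).recovery == recovery

    def test_zero_added_undefined(self):
        with pytest.raises(UndefinedRatioError):
            g.c13_recovery(1.0, 1.0, 1.0, 0.0)

    @pytest.mark.parametrize("treat, ctrl, percent", [
        (6.5, 10.0, 35.0), (10.0, 10.0, 0.0), (12.0, 10.0, -20.0),
    ])
    def test_suppression(self, treat, ctrl, percent):
        assert g.suppression_percent(treat, ctrl) == pytest.approx(percent)

    def test_zero_control_undefined(self):
        with pytest.raises(UndefinedRatioError):
            g.suppression_percent(1.0, 0.0)


class TestDomainTypes:
    def test_ctr_must_have_zero_fe(self):
        with pytest.raises(ConfigError):
            g.MicrocosmSpec("NF", "CTR", fe_added_umol_per_g=140.0)
        with pytest.raises(ConfigError):
            g.MicrocosmSpec("NF", "FER", fe_added_umol_per_g=0.0)

    def test_series_rejects_fe2_above_total(self):
        with pytest.raises(MeasurementInconsistencyError, match="day 1"):
            g.BiogeochemSeries(
                time_days=[0.0, 1.0], fe2=[40.0, 70.0], total_fe=[63.0, 63.0],
                acetate=[3.3, 1.0], ch4_total=[0.0, 1.0], co2_total=[0.0, 2.0],
                atom13_ch4=[1.1, 50.0], atom13_co2=[1.1, 20.0], ph=[7.5, 7.5],
            )

    def test_series_rejects_nonmonotone_time(self):
        with pytest.raises(MeasurementInconsistencyError):
            g.BiogeochemSeries(
                time_days=[0.0, 0.0], fe2=[40.0, 41.0], total_fe=[63.0, 63.0],
                acetate=[3.3, 1.0], ch4_total=[0.0, 1.0], co2_total=[0.0, 2.0],
                atom13_ch4=[1.1, 50.0], atom13_co2=[1.1, 20.0], ph=[7.5, 7.5],
            )
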