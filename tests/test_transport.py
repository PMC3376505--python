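"""Electrodiffusion, carriers, ATP synthase, complex IV and the charge ODE."""

import numpy as np
import pytest
from scipy.optimize import brentq

from mitodyn import transport as tr
from mitodyn.constants import RT_OVER_F_MV


class TestGHK:
    def test_zero_at_equal_concentrations_and_zero_potential(self):
        assert tr.ghk_flux(1, 5.0, 5.0, 0.0, 10.0) == pytest.approx(0.0)

    def test_zero_at_nernst_potential(self):
        # c_in/c_out = exp(-z u) at equilibrium
        c_out, dpsi, z = 140.0, -90.0, 1
        c_in = c_out * np.exp(-z * dpsi / RT_OVER_F_MV)
        assert tr.ghk_flux(z, c_in, c_out, dpsi, 3.0) == pytest.approx(
            0.0, abs=1e-9)

    def test_linear_limit_series_oracle(self):
        # at u = 1e-9 the flux matches P*(c_out - c_in) to 1e-6 relative
        u_mv = 1e-9 * RT_OVER_F_MV
        got = tr.ghk_flux(1, 3.0, 7.0, u_mv, 2.0)
        assert got == pytest.approx(2.0 * (7.0 - 3.0), rel=1e-6)

    def test_continuity_at_branch_point(self):
        lo = tr.ghk_flux(1, 3.0, 7.0, 0.9e-6 * RT_OVER_F_MV, 2.0)
        hi = tr.ghk_flux(1, 3.0, 7.0, 1.1e-6 * RT_OVER_F_MV, 2.0)
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_monotone_in_driving_term(self):
        dpsi = -120.0
        u = dpsi / RT_OVER_F_MV
        vals = [tr.ghk_flux(1, c_in, 140.0, dpsi, 1.0)
                for c_in in (10.0, 50.0, 100.0, 140.0 * np.exp(-u))]
        drives = [140.0 - c_in * np.exp(u)
                  for c_in in (10.0, 50.0, 100.0, 140.0 * np.exp(-u))]
        assert all(np.sign(v) == np.sign(d) or d == 0
                   for v, d in zip(vals, drives))
        assert vals == sorted(vals, reverse=True)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            tr.ghk_flux(1, -1.0, 5.0, -100.0, 1.0)


class TestAntiport:
    def test_zero_at_equilibrium_ratio(self):
        # zero exactly when c_in * h_out == c_out * h_in
        h_out = 6.0e-5
        h_in = 120.0 / 140.0 * h_out
        v = tr.cation_proton_antiport_flux(120.0, 140.0, h_in, h_out, 10.0)
        assert v == pytest.approx(0.0, abs=1e-15)

    def test_more_matrix_cation_increases_efflux(self):
        v1 = tr.cation_proton_antiport_flux(120.0, 140.0, 3.5e-5, 6.3e-5, 10.0)
        v2 = tr.cation_proton_antiport_flux(240.0, 140.0, 3.5e-5, 6.3e-5, 10.0)
        assert v2 > v1

    def test_equilibrium_cation_ratio_equals_proton_ratio(self):
        # the isolated antiporter's zero sits at c_in/c_out = h_in/h_out
        h_in, h_out = 3.0e-5, 6.0e-5
        c_out = 140.0
        f = lambda c_in: tr.cation_proton_antiport_flux(c_in, c_out, h_in,
                                                        h_out, 5.0)
        root = brentq(f, 1.0, 139.0)
        assert root / c_out == pytest.approx(h_in / h_out, rel=1e-9)


class TestANT:
    def test_symmetric_zero(self):
        assert tr.ant_flux(1.0, 1.0, 1.0, 1.0, 0.0, 5.0) == pytest.approx(0.0)

    def test_hyperpolarization_biases_export(self):
        args = (2.6, 7.4, 2.44, 0.06)
        v = [tr.ant_flux(*args, dpsi, 5.0) for dpsi in (-80.0, -120.0, -160.0)]
        assert v[0] < v[1] < v[2]

    def test_sign_flips_at_thermodynamic_ratio(self):
        dpsi = -120.0
        u = dpsi / RT_OVER_F_MV
        atp_m, adp_m, adp_c = 2.0, 8.0, 0.5
        # flux zero when (atp_c adp_m)/(atp_m adp_c) = exp(-u)
        atp_c_star = np.exp(-u) * atp_m * adp_c / adp_m
        f = lambda atp_c: tr.ant_flux(atp_m, adp_m, atp_c, adp_c, dpsi, 5.0)
        root = brentq(f, 1e-6, 1e3)
        assert root == pytest.approx(atp_c_star, rel=1e-9)


class TestSynthase:
    def test_zero_at_reversal_potential(self):
        p = tr.SynthaseParams(vmax=2.0, n_a=3.0, dg0_kj=31.9)
        dpsi_rev = tr.synthase_reversal_dpsi(7.45, 7.2, 2.6, 7.4, 3.8, p)
        assert tr.atp_synthase_flux(dpsi_rev, 7.45, 7.2, 2.6, 7.4, 3.8,
                                    p) == pytest.approx(0.0, abs=1e-12)

    def test_stronger_gradient_increases_synthesis(self):
        p = tr.SynthaseParams()
        v = [tr.atp_synthase_flux(d, 7.45, 7.2, 2.6, 7.4, 3.8, p)
             for d in (-120.0, -140.0, -160.0)]
        assert v[0] < v[1] < v[2]

    def test_hydrolysis_when_gradient_collapses(self):
        p = tr.SynthaseParams()
        assert tr.atp_synthase_flux(-20.0, 7.3, 7.2, 2.6, 7.4, 3.8, p) < 0


class TestComplexIV:
    def test_zero_without_reduced_cytochrome(self):
        assert tr.complex_iv_flux(0.0, 0.4, 0.03, -140.0, 100.0) == 0.0

    def test_zero_without_oxygen(self):
        assert tr.complex_iv_flux(0.3, 0.4, 0.0, -140.0, 100.0) == 0.0

    def test_second_order_in_reduced_fraction(self):
        v_half = tr.complex_iv_flux(0.2, 0.4, 0.03, -140.0, 100.0)
        v_full = tr.complex_iv_flux(0.4, 0.4, 0.03, -140.0, 100.0)
        assert v_half / v_full == pytest.approx(0.25, rel=1e-12)

    def test_hyperpolarization_attenuates(self):
        v1 = tr.complex_iv_flux(0.3, 0.4, 0.03, -160.0, 100.0, kappa=1.8)
        v2 = tr.complex_iv_flux(0.3, 0.4, 0.03, -120.0, 100.0, kappa=1.8)
        assert v1 < v2


class TestLoadAndLeak:
    def test_load_zero_cases(self):
        assert tr.atp_load_flux(0.0, 1.0, 0.1) == 0.0
        assert tr.atp_load_flux(2.4, 0.0, 0.1) == 0.0

    def test_load_linear_in_multiplier(self):
        v1 = tr.atp_load_flux(50.0, 1.0, 0.1, km_load=0.1)
        v2 = tr.atp_load_flux(50.0, 2.0, 0.1, km_load=0.1)
        assert v2 == pytest.approx(2.0 * v1)

    def test_nonohmic_leak_unity_at_reference(self):
        base = tr.ghk_flux(1, 3.5e-5, 6.3e-5, -140.0, 100.0)
        leak = tr.proton_leak_flux(3.5e-5, 6.3e-5, -140.0, 100.0,
                                   lambda_mv=14.0, dpsi_ref_mv=-140.0)
        assert leak == pytest.approx(base)

    def test_nonohmic_leak_grows_with_hyperpolarization(self):
        v = [tr.proton_leak_flux(3.5e-5, 6.3e-5, d, 100.0)
             for d in (-120.0, -140.0, -160.0)]
        assert v[0] < v[1] < v[2]


class TestMembranePotentialODE:
    def test_all_fluxes_zero(self):
        assert tr.membrane_potential_derivative({}, 1.45e-3) == 0.0

    def test_single_outward_pump(self):
        c = 1.45e-3
        d = tr.membrane_potential_derivative({"pump": (1.0, 0.5)}, c)
        assert d == pytest.approx(-0.5 / c)

    def test_array_form_matches_mapping(self):
        c = 1.45e-3
        d1 = tr.membrane_potential_derivative(
            {"a": (1.0, 0.2), "b": (-3.0, 0.1)}, c)
        d2 = tr.membrane_potential_derivative(
            np.array([0.2, 0.1]), c, charges=np.array([1.0, -3.0]))
        assert d1 == pytest.approx(d2)

    def test_untagged_flux_is_configuration_error(self):
        with pytest.raises(ValueError, match="charge-tagged"):
            tr.membrane_potential_derivative({"bad": 0.3}, 1.45e-3)

    def test_capacitance_must_be_positive(self):
        with pytest.raises(ValueError):
            tr.membrane_potential_derivative({}, 0.0)
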