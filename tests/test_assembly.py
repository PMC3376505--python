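"""Assembled ODE system: layout, conservation, integration, steady states."""

import numpy as np
import pytest

from mitodyn.assembly import (AssemblyError, ModelSystem, SCALAR_NAMES,
                              find_steady_state, integrate,
                              proton_stoichiometry_audit)
from mitodyn.config import generate_default_fixture


class TestLayout:
    def test_lumped_state_vector_length(self, reference_system):
        # 28 scalars + 96 complex I + 48 complex III + membrane potential
        assert reference_system.n_states == len(SCALAR_NAMES) + 96 + 48 + 1

    def test_full_variant_grows_by_1440(self, fixture_config):
        import copy
        cfg = copy.deepcopy(fixture_config)
        cfg.complex_i.variant = "full"
        full = ModelSystem(cfg)
        assert full.n_states == len(SCALAR_NAMES) + 1536 + 48 + 1

    def test_state_names_bijective(self, reference_system):
        names = reference_system.state_names()
        assert len(names) == reference_system.n_states
        assert len(set(names)) == len(names)


class TestConservation:
    def test_moiety_rows_annihilate_rhs(self, reference_system):
        # already asserted at assembly time; re-run explicitly
        reference_system.audit_conservation(n_trials=3, seed=5)

    def test_corrupted_moiety_is_detected(self, fixture_config):
        system = ModelSystem(fixture_config)
        system.moieties = system.moieties.copy()
        system.moieties[0, system.idx["Pyr_m"]] = 1.0  # NAD(H) + pyruvate??
        with pytest.raises(AssemblyError, match="not conserved"):
            system.audit_conservation()

    def test_nad_total_conserved_over_trajectory(self, reference_system,
                                                 reference_state):
        sol = integrate(reference_system, reference_state, 100.0, rtol=1e-8)
        ix = reference_system.idx
        tot = sol.y[ix["NAD"]] + sol.y[ix["NADH"]]
        assert np.max(np.abs(tot - tot[0])) < 1e-8 * tot[0]

    def test_conserved_moieties_drift_below_1e8_over_1e4_s(
            self, reference_system, reference_state):
        sol = integrate(reference_system, reference_state, 1.0e4, rtol=1e-8)
        y_end = sol.y[:, -1]
        t0 = reference_system.moieties @ reference_state
        t1 = reference_system.moieties @ y_end
        assert np.max(np.abs(t1 - t0) / np.abs(t0)) < 1e-8


class TestIntegration:
    def test_zero_horizon_returns_initial_state(self, reference_system,
                                                reference_state):
        sol = integrate(reference_system, reference_state, 0.0)
        assert np.array_equal(sol.y[:, -1], reference_state)

    def test_steady_state_is_fixed_point_of_dynamics(self, reference_system,
                                                     reference_state):
        obs0 = reference_system.observables(reference_state)
        sol = integrate(reference_system, reference_state, 100.0, rtol=1e-8)
        obs1 = reference_system.observables(sol.y[:, -1])
        for key in ("dpsi", "nadh_ratio", "atp_production", "share_leak"):
            assert obs1[key] == pytest.approx(obs0[key], rel=1e-6, abs=1e-9)


class TestSteadyState:
    def test_reference_converges_in_calibrated_window(self, reference_result):
        assert reference_result.converged
        assert reference_result.residual < 1e-8
        assert -150.0 <= reference_result.observables["dpsi"] <= -120.0

    def test_observables_recomputed_from_state(self, reference_system,
                                               reference_result):
        fresh = reference_system.observables(reference_result.state)
        assert fresh["nadh_ratio"] == pytest.approx(
            reference_result.observables["nadh_ratio"], rel=1e-12)

    def test_multistart_guesses_agree(self, reference_system,
                                      reference_state):
        """Two different valid guesses relax to the same reference steady
        state (uniqueness at the reference point).  The potassium/charge
        redistribution mode is orders of magnitude slower than every other
        relaxation, so at the solver's residual tolerance the practical
        uniqueness width is ~1 mV in the membrane potential and ~1% in the
        fast observables."""
        rng = np.random.default_rng(11)
        y2 = reference_state * np.exp(
            rng.normal(0.0, 0.03, len(reference_state)))
        y2[reference_system.i_dpsi] = \
            reference_state[reference_system.i_dpsi] + 3.0
        # project back onto the conserved manifold: same moiety totals
        M = reference_system.moieties
        resid = M @ reference_state - M @ y2
        y2 = y2 + M.T @ np.linalg.solve(M @ M.T, resid)
        np.clip(y2[:reference_system.i_dpsi], 0.0, None,
                out=y2[:reference_system.i_dpsi])
        res2 = find_steady_state(reference_system, y2, 1.0, pre_time=1.0)
        assert res2.converged
        a = reference_system.observables(reference_state)
        b = res2.observables
        assert b["dpsi"] == pytest.approx(a["dpsi"], abs=1.5)
        for key in ("nadh_ratio", "atp_production", "share_atp"):
            assert b[key] == pytest.approx(a[key], rel=0.02)

    def test_charge_balance_at_steady_state(self, reference_result):
        obs = reference_result.observables
        # total signed charge flux vanishes relative to its gross magnitude
        gross = (abs(obs["v_ant"]) + 3 * abs(obs["v_f1"]) + obs["j_h_leak"]
                 + abs(obs["j_k"]) + obs["protons_pumped"])
        assert abs(obs["charge_imbalance"]) < 1e-7 * gross

    def test_proton_balance_at_steady_state(self, reference_result):
        obs = reference_result.observables
        assert obs["proton_reentry"] == pytest.approx(obs["protons_pumped"],
                                                      rel=1e-6)

    def test_utilization_shares_sum_to_one(self, reference_result):
        obs = reference_result.observables
        total = (obs["share_leak"] + obs["share_k"] + obs["share_na"]
                 + obs["share_atp"])
        assert total == pytest.approx(1.0, abs=1e-9)


class TestAudit:
    def test_proton_counts_per_substrate(self, reference_system):
        counts = proton_stoichiometry_audit(reference_system)
        assert counts["nadh_path"] == 10
        assert counts["succinate_path"] == 6
        assert counts["complex_ii"] == 0

    def test_audit_on_full_variant(self, fixture_config):
        import copy
        cfg = copy.deepcopy(fixture_config)
        cfg.complex_i.variant = "full"
        counts = proton_stoichiometry_audit(ModelSystem(cfg))
        assert counts["nadh_path"] == 10
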