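"""Direct construction of the calibrated reference operating point.

Calibration of the free capacity parameters (Vmax values, permeabilities,
rate scales) proceeds by flux matching at a designed reference state: the
reference concentrations, membrane potential and pH are fixed first, the
reference TCA flux sets every pathway flux through the cycle stoichiometry
(four NADH, one ubiquinol from complex II and one GTP-equivalent per
pyruvate; 46 protons pumped per turn through the respiratory chain), the
proton re-entry is split 24% / 16% / 60% among leak, potassium cycling and
ATP synthesis (plus phosphate and substrate uptake), and every capacity
parameter is solved so that its flux law reproduces the designed flux at
the designed state.  Because each flux is linear in its own capacity
parameter, and a uniform rate scale moves a respiratory complex's
steady-state throughput linearly without changing its occupancy
distribution, this solve is exact in one pass.  The matrix proton, charge,
potassium and quinone balances then close identically, so the designed
state is a true steady state of the parameterized model.

TCA enzyme Vmax values are likewise solved by flux matching; the cycle's
control structure (the KGDHC ceiling, redox relief through the competitive
nucleotide site, mass-action feedback of the near-equilibrium reactions)
lives in the configured Km shapes, so calibration only scales capacities.
"""

from __future__ import annotations

import copy
import math

import numpy as np

from . import statespace as ss
from . import tca
from . import transport as tr
from .config import ModelConfig
from .constants import LN10, RT_OVER_F_MV, ph_to_mm

__all__ = ["design_reference", "DESIGNED_STATE"]

#: The substrate through which each enzyme's functional ceiling is probed
#: (saturating it while holding the rest of the designed state fixed).
PRIMARY_SUBSTRATE = {
    "PDH": "Pyr_m", "CS": "OA", "AC": "Cit", "IDH": "IsoCit",
    "KGDHC": "aKG", "SCS": "SucCoA", "SDH": "Suc", "FUM": "Fum",
    "MDH": "Mal",
}


def designed_state(cfg: ModelConfig) -> dict[str, float]:
    """The designed reference concentrations (mM), potential and pH."""
    keq_mdh = cfg.enzymes["MDH"].keq
    keq_ac = cfg.enzymes["AC"].keq
    r = cfg.calibration.nadh_ratio
    nadh = cfg.pools.nad_total * r / (1.0 + r)
    st = {
        "dpsi": cfg.calibration.dpsi_target, "ph_m": 7.45,
        "NADH": nadh, "NAD": cfg.pools.nad_total - nadh,
        "Pyr_m": 0.12,
        "ACoA": 0.03, "CoA": 0.19, "SucCoA": 0.03,
        "Cit": 0.25, "aKG": 0.20, "Suc": 0.10, "Fum": 0.035, "Mal": 0.10,
        "ATP_m": 2.6, "ADP_m": 7.4, "Pi_m": 3.8,
        "ATP_c": 2.44, "ADP_c": 0.06,
        "QH2_n": 1.25, "Q_n": 0.75, "QH2_p": 1.05, "Q_p": 0.95,
        "cytc_red": 0.32, "cytc_ox": 0.08,
        "K_m": 120.0, "Na_m": 8.0,
    }
    # near-equilibrium enzymes poised at 90% of equilibrium displacement
    st["IsoCit"] = 0.93 * keq_ac * st["Cit"]
    st["OA"] = 0.9 * keq_mdh * st["Mal"] * st["NAD"] / st["NADH"]
    # chloride has no active pathway: designed at its Nernst distribution
    u = st["dpsi"] / RT_OVER_F_MV
    st["Cl_m"] = cfg.clamps.cl_c * math.exp(u)
    return st


DESIGNED_STATE = designed_state


def _machine_flux_per_scale(rules, space, pools, dpsi, total, alpha,
                            rule_name: str) -> float:
    """Steady-state net flux of one rule class per unit uniform rate scale.

    The machine's internal steady state is invariant under a uniform
    scaling of all rate constants, so the through-flux is exactly linear in
    the scale.
    """
    tset = ss.instantiate_transitions(rules, space)
    occ = ss.machine_steady_state(tset, pools, dpsi, total, alpha=alpha)
    fl = tset.fluxes(np.maximum(occ, 0.0), dpsi, pools, alpha=alpha)
    names = [r.name for r in tset.rules]
    ri = names.index(rule_name)
    return float(fl[tset.rule_idx == ri].sum())


def _tune_enzyme(sec, eid: str, conc: dict[str, float], v: float,
                 ca_ref: float) -> float:
    """Set Vmax so the enzyme carries exactly ``v`` at the designed state;
    returns the resulting normalized capacity (Vmax over reference flux).

    The Km tables are fixed by the configuration; the cycle's control
    structure (KGDHC ceiling, redox relief, mass-action feedback of the
    near-equilibrium reactions) lives in those shapes, while calibration
    only scales the capacities.
    """
    p = tca.EnzymeParameters(enzyme_id=eid, vmax=1.0, km=dict(sec.km),
                             keq=sec.keq, ka_ca=sec.ka_ca)
    phi = tca.enzyme_rate(p, conc, ca_ref, ca_ref)
    if phi <= 0:
        raise ValueError(f"{eid}: designed state gives non-positive flux")
    sec.vmax = v / phi
    return sec.vmax / v


def design_reference(config: ModelConfig,
                     v_cycle: float = 0.115) -> tuple[ModelConfig, dict]:
    """Return a configuration whose parameters make the designed reference
    state an exact steady state, together with the designed fluxes."""
    cfg = copy.deepcopy(config)
    cal = cfg.calibration
    st = designed_state(cfg)
    v = v_cycle
    dpsi = st["dpsi"]
    u = dpsi / RT_OVER_F_MV
    h_m = ph_to_mm(st["ph_m"])
    h_c = ph_to_mm(cfg.clamps.ph_c)
    st["H_m"] = h_m

    # --- pathway fluxes from the cycle stoichiometry --------------------
    v_nadh = 4.0 * v                  # NADH oxidation rate (complex I)
    v_pairs_ciii = 5.0 * v            # electron pairs through complex III
    pumped = 46.0 * v                 # protons pumped per unit time
    reentry = pumped
    j_leak = cal.share_leak * reentry
    j_kh = cal.share_k * reentry
    j_nah = 0.002 * reentry           # sodium cycling kept marginal
    atp_bundle = reentry - j_leak - j_kh - j_nah
    n_a = cfg.transporters.n_a
    v_pyr = v
    # phosphate import feeds both the synthase and substrate-level
    # phosphorylation (v_pi = v_f1 + v); pyruvate uptake is proton-neutral,
    # so the bundle is (n_a + 1) v_f1 + v and the proton and charge books
    # close simultaneously
    v_f1 = (atp_bundle - v) / (n_a + 1.0)
    v_pi = v_f1 + v
    v_ant = v_f1 + v                  # SCS contributes one ATP per turn
    demand_cyt = v_ant / cfg.membrane.volume_ratio

    # --- respiratory-chain rate scales (linear in the uniform scale) ----
    pools = {
        "NADH": st["NADH"], "NAD": st["NAD"],
        "Q_n": st["Q_n"], "QH2_n": st["QH2_n"],
        "Q_p": st["Q_p"], "QH2_p": st["QH2_p"],
        "cytc_ox": st["cytc_ox"], "cytc_red": st["cytc_red"],
        "H_m": h_m, "H_c": h_c,
    }
    lumped = cfg.complex_i.variant == "lumped"
    ci_space = ss.enumerate_complex_i_states(lumped)
    phi_ci = _machine_flux_per_scale(
        ss.complex_i_rules(lumped, cfg.complex_i.energies, cfg.complex_i.kf,
                           rate_scale=1.0),
        ci_space, pools, dpsi, cfg.pools.ci_total, cfg.complex_i.alpha,
        "nadh_ox")
    if phi_ci <= 0:
        raise ValueError("complex I runs backward at the designed state")
    cfg.complex_i.rate_scale = v_nadh / phi_ci
    c3_space = ss.enumerate_complex_iii_states()
    phi_c3 = _machine_flux_per_scale(
        ss.complex_iii_rules(cfg.complex_iii.energies, cfg.complex_iii.kf,
                             rate_scale=1.0),
        c3_space, pools, dpsi, cfg.pools.ciii_total, cfg.complex_iii.alpha,
        "c1_to_cytc")
    if phi_c3 <= 0:
        raise ValueError("complex III runs backward at the designed state")
    cfg.complex_iii.rate_scale = 2.0 * v_pairs_ciii / phi_c3

    t = cfg.transporters
    # complex IV capacity from the designed electron-pair flux
    phi_c4 = tr.complex_iv_flux(st["cytc_red"], cfg.pools.cytc_total,
                                cfg.clamps.o2, dpsi, 1.0, t.km_o2, t.kappa_c4)
    t.v_c4 = v_pairs_ciii / phi_c4

    # quinone shuttling between the membrane faces
    t.k_qdiff = (2.0 * v_pairs_ciii) / (st["QH2_n"] - st["QH2_p"])

    # --- electrophysiology ----------------------------------------------
    t.dpsi_leak_ref = dpsi
    t.p_h = j_leak / tr.proton_leak_flux(h_m, h_c, dpsi, 1.0,
                                         t.lambda_leak, t.dpsi_leak_ref)
    t.p_k = j_kh / tr.ghk_flux(1, st["K_m"], cfg.clamps.k_c, dpsi, 1.0)
    t.v_kh = j_kh / tr.cation_proton_antiport_flux(
        st["K_m"], cfg.clamps.k_c, h_m, h_c, 1.0, t.km_kh_c, t.km_kh_h)
    t.p_na = j_nah / tr.ghk_flux(1, st["Na_m"], cfg.clamps.na_c, dpsi, 1.0)
    t.v_nah = j_nah / tr.cation_proton_antiport_flux(
        st["Na_m"], cfg.clamps.na_c, h_m, h_c, 1.0, t.km_kh_c, t.km_kh_h)
    syn = tr.SynthaseParams(vmax=1.0, n_a=n_a, dg0_kj=t.dg0_phos)
    phi_f1 = tr.atp_synthase_flux(dpsi, st["ph_m"], cfg.clamps.ph_c,
                                  st["ATP_m"], st["ADP_m"], st["Pi_m"], syn)
    if phi_f1 <= 0:
        raise ValueError("ATP synthase has no forward drive at the "
                         "designed state")
    t.v_f1 = v_f1 / phi_f1
    phi_ant = tr.ant_flux(st["ATP_m"], st["ADP_m"], st["ATP_c"], st["ADP_c"],
                          dpsi, 1.0, t.km_ant_m, t.km_ant_c)
    t.v_ant = v_ant / phi_ant
    t.v_pi = v_pi / tr.pi_carrier_flux(st["Pi_m"], cfg.clamps.pi_c, h_m, h_c,
                                       1.0, t.km_pi)
    t.v_pyr = v_pyr / tr.pyruvate_carrier_flux(st["Pyr_m"], cfg.clamps.pyr_c,
                                               1.0, t.km_pyr)
    cfg.load.k_load = demand_cyt / (st["ATP_c"]
                                    / (cfg.load.km_load + st["ATP_c"]))

    # calcium coupling: reference level is the designed-potential level
    cfg.calcium.reference = tca.calcium_concentration(
        dpsi, tca.CalciumCoupling(slope=cfg.calcium.slope,
                                  intercept=cfg.calcium.intercept,
                                  lower=cfg.calcium.lower,
                                  upper=cfg.calcium.upper))
    ca_ref = cfg.calcium.reference

    # --- TCA kinetics: prescribed reserves, exact flux ------------------
    conc = dict(st)
    reserves = {}
    for eid in tca.TCA_ENZYME_IDS:
        reserves[eid] = _tune_enzyme(cfg.enzymes[eid], eid, conc, v, ca_ref)

    # --- pool totals and initial state match the design ------------------
    cfg.pools.nad_total = st["NAD"] + st["NADH"]
    cfg.pools.coa_total = st["CoA"] + st["ACoA"] + st["SucCoA"]
    cfg.pools.adenine_m = st["ATP_m"] + st["ADP_m"]
    cfg.pools.adenine_c = st["ATP_c"] + st["ADP_c"]
    cfg.pools.cytc_total = st["cytc_red"] + st["cytc_ox"]
    init = dict(cfg.pools.initial)
    for key in ("Pyr_m", "ACoA", "CoA", "Cit", "IsoCit", "aKG", "SucCoA",
                "Suc", "Fum", "Mal", "OA", "NADH", "ATP_m", "Pi_m",
                "QH2_n", "Q_n", "QH2_p", "Q_p", "cytc_red", "K_m", "Na_m",
                "Cl_m", "ATP_c", "ph_m", "dpsi"):
        init[key] = st[key] if key != "ph_m" else st["ph_m"]
    cfg.pools.initial = init

    designed_fluxes = {
        "v_cycle": v, "v_nadh": v_nadh, "v_pairs_ciii": v_pairs_ciii,
        "pumped": pumped, "j_leak": j_leak, "j_kh": j_kh, "j_nah": j_nah,
        "v_f1": v_f1, "v_pi": v_pi, "v_pyr": v_pyr, "v_ant": v_ant,
        "demand_cyt": demand_cyt, "state": st, "reserves": reserves,
    }
    return cfg, designed_fluxes
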