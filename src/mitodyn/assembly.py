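"""Assembly of the complete ODE system and steady-state analysis.

The state vector concatenates, in a fixed documented order: the TCA-cycle
and nucleotide pools, the ubiquinone pools at the n- and p-sites, the
cytochrome c pair, matrix ions (H+, K+, Na+, Cl-), cytosolic adenine
nucleotides, the complex I microstate occupancies (96 lumped or 1536 full),
the 48 complex III occupancies, and the membrane potential.  All
concentrations are mM (matrix volume for matrix species); the membrane
potential is mV.

Conserved moieties (NAD(H), CoA esters, matrix and cytosolic adenine
nucleotides, cytochrome c, each complex's total occupancy, and the total
ubiquinone pool including complex-bound semiquinones) annihilate the
right-hand side analytically; an assembly-time audit verifies this on
random valid states.  Matrix pH is dynamic behind a linear buffering
capacity; cytosolic pH, ions, pyruvate, phosphate and oxygen are clamped.

Steady states are found by exact machine elimination: at fixed pools and
membrane potential the stationary occupancy of each respiratory complex
solves a small linear master equation, so a damped Newton iteration (in
log-concentration space, with one balance row per conserved moiety replaced
by its conservation residual) runs on the reduced system of pool, ion,
nucleotide and charge balances only; if it stalls, the reduced
quasi-steady-state ODE is relaxed with BDF and Newton retried.
Non-convergence is reported as data (a flagged result), which the scan
experiments use to detect collapse of the energy state at extreme loads or
inhibitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from . import statespace as ss
from . import tca
from . import transport as tr
from .config import ModelConfig
from .constants import LN10, RT_OVER_F_MV, mm_to_ph, ph_to_mm

__all__ = [
    "ModelSystem",
    "SteadyStateResult",
    "assemble",
    "integrate",
    "find_steady_state",
    "proton_stoichiometry_audit",
    "AssemblyError",
    "AuditError",
]


class AssemblyError(RuntimeError):
    pass


class AuditError(RuntimeError):
    pass


#: Metabolite / ion part of the layout, in order, before the machine blocks.
SCALAR_NAMES = (
    "Pyr_m", "ACoA", "CoA", "Cit", "IsoCit", "aKG", "SucCoA", "Suc", "Fum",
    "Mal", "OA", "NAD", "NADH", "ATP_m", "ADP_m", "Pi_m",
    "Q_n", "QH2_n", "Q_p", "QH2_p",
    "cytc_ox", "cytc_red",
    "H_m", "K_m", "Na_m", "Cl_m",
    "ATP_c", "ADP_c",
)


@dataclass
class SteadyStateResult:
    """A solved (or honestly failed) steady state."""

    state: np.ndarray
    residual: float
    converged: bool
    observables: dict[str, float] = field(default_factory=dict)
    message: str = ""


class ModelSystem:
    """Assembled ODE right-hand side over all state variables plus dpsi."""

    def __init__(self, config: ModelConfig):
        self.config = config
        lumped = config.complex_i.variant == "lumped"
        self.ci_space = ss.enumerate_complex_i_states(lumped)
        self.ci_tset = ss.instantiate_transitions(
            ss.complex_i_rules(lumped, config.complex_i.energies,
                               config.complex_i.kf,
                               config.complex_i.rate_scale),
            self.ci_space)
        self.ciii_space = ss.enumerate_complex_iii_states()
        self.ciii_tset = ss.instantiate_transitions(
            ss.complex_iii_rules(config.complex_iii.energies,
                                 config.complex_iii.kf,
                                 config.complex_iii.rate_scale),
            self.ciii_space)

        n_sc = len(SCALAR_NAMES)
        self.n_ci = self.ci_space.n_states
        self.n_ciii = self.ciii_space.n_states
        self.ci_slice = slice(n_sc, n_sc + self.n_ci)
        self.ciii_slice = slice(n_sc + self.n_ci, n_sc + self.n_ci + self.n_ciii)
        self.i_dpsi = n_sc + self.n_ci + self.n_ciii
        self.n_states = self.i_dpsi + 1
        self.idx = {name: i for i, name in enumerate(SCALAR_NAMES)}

        # per-enzyme reactant index arrays for fast gathering
        self._enzymes = {eid: tca.EnzymeParameters(
            enzyme_id=eid, vmax=sec.vmax, km=dict(sec.km), keq=sec.keq,
            ka_ca=sec.ka_ca, inhibition=sec.inhibition)
            for eid, sec in config.enzymes.items()}
        self._coupling = tca.CalciumCoupling(
            slope=config.calcium.slope, intercept=config.calcium.intercept,
            lower=config.calcium.lower, upper=config.calcium.upper,
            reference=config.calcium.reference)
        self._h_c = ph_to_mm(config.clamps.ph_c)
        self._syn = tr.SynthaseParams(vmax=config.transporters.v_f1,
                                      n_a=config.transporters.n_a,
                                      dg0_kj=config.transporters.dg0_phos)
        # indices of the machine pool vector within the global state
        self._machine_pool_idx = np.array([
            self.idx[n] if n in self.idx else -1
            for n in ss.POOL_NAMES
        ])  # H_c has no state index (clamped) -> -1
        self._load_multiplier = 1.0
        self.moieties, self.moiety_names = self._build_moieties()
        self.audit_conservation()

    # -- layout helpers ----------------------------------------------------

    def state_names(self) -> list[str]:
        names = list(SCALAR_NAMES)
        names += [f"CI_{i}" for i in range(self.n_ci)]
        names += [f"CIII_{i}" for i in range(self.n_ciii)]
        names.append("dpsi")
        return names

    @property
    def load_multiplier(self) -> float:
        return self._load_multiplier

    @load_multiplier.setter
    def load_multiplier(self, value: float) -> None:
        if value < 0:
            raise ValueError("load multiplier must be non-negative")
        self._load_multiplier = float(value)

    def set_inhibition(self, enzyme_id: str, fraction: float) -> None:
        """Set one enzyme's inhibition fraction against the baseline."""
        self._enzymes = tca.apply_inhibition(self._enzymes, enzyme_id, fraction)

    def initial_state(self) -> np.ndarray:
        cfg = self.config
        init = cfg.pools.initial
        y = np.zeros(self.n_states)
        for name in SCALAR_NAMES:
            if name in init:
                y[self.idx[name]] = init[name]
        y[self.idx["NAD"]] = cfg.pools.nad_total - init["NADH"]
        y[self.idx["ADP_m"]] = cfg.pools.adenine_m - init["ATP_m"]
        y[self.idx["ADP_c"]] = cfg.pools.adenine_c - init["ATP_c"]
        y[self.idx["cytc_ox"]] = cfg.pools.cytc_total - init["cytc_red"]
        y[self.idx["H_m"]] = ph_to_mm(init["ph_m"])
        dpsi = init["dpsi"]
        y[self.i_dpsi] = dpsi
        pools = self._machine_pools(y)
        y[self.ci_slice] = ss.machine_steady_state(
            self.ci_tset, pools, dpsi, cfg.pools.ci_total,
            alpha=cfg.complex_i.alpha)
        y[self.ciii_slice] = ss.machine_steady_state(
            self.ciii_tset, pools, dpsi, cfg.pools.ciii_total,
            alpha=cfg.complex_iii.alpha)
        np.clip(y[self.ci_slice], 0.0, None, out=y[self.ci_slice])
        np.clip(y[self.ciii_slice], 0.0, None, out=y[self.ciii_slice])
        return y

    def _machine_pools(self, y: np.ndarray) -> np.ndarray:
        vec = np.empty(len(ss.POOL_NAMES))
        for i, gi in enumerate(self._machine_pool_idx):
            vec[i] = y[gi] if gi >= 0 else self._h_c
        return vec

    # -- conserved moieties ------------------------------------------------

    def _build_moieties(self) -> tuple[np.ndarray, list[str]]:
        rows, names = [], []

        def row(pairs: Mapping[int, float]) -> np.ndarray:
            r = np.zeros(self.n_states)
            for i, c in pairs.items():
                r[i] = c
            return r

        ix = self.idx
        rows.append(row({ix["NAD"]: 1, ix["NADH"]: 1}))
        names.append("NAD(H)")
        rows.append(row({ix["CoA"]: 1, ix["ACoA"]: 1, ix["SucCoA"]: 1}))
        names.append("CoA esters")
        # the eight cycle skeletons interconvert 1:1 (no anaplerosis in the
        # model), so their total is a conserved moiety as well
        rows.append(row({ix[n]: 1 for n in
                         ("Cit", "IsoCit", "aKG", "SucCoA", "Suc", "Fum",
                          "Mal", "OA")}))
        names.append("TCA intermediates")
        rows.append(row({ix["ATP_m"]: 1, ix["ADP_m"]: 1}))
        names.append("matrix adenine")
        rows.append(row({ix["ATP_c"]: 1, ix["ADP_c"]: 1}))
        names.append("cytosolic adenine")
        rows.append(row({ix["cytc_ox"]: 1, ix["cytc_red"]: 1}))
        names.append("cytochrome c")
        r = np.zeros(self.n_states)
        r[self.ci_slice] = 1.0
        rows.append(r)
        names.append("complex I occupancy")
        r = np.zeros(self.n_states)
        r[self.ciii_slice] = 1.0
        rows.append(r)
        names.append("complex III occupancy")
        # total ubiquinone: free pools plus complex-bound semiquinones
        r = np.zeros(self.n_states)
        for n in ("Q_n", "QH2_n", "Q_p", "QH2_p"):
            r[ix[n]] = 1.0
        ci_sq = (self.ci_space.column("SQ") == 1).astype(float)
        r[self.ci_slice] = ci_sq
        c3_sq = ((self.ciii_space.column("SQp") == 1).astype(float)
                 + (self.ciii_space.column("SQn") == 1).astype(float))
        r[self.ciii_slice] = c3_sq
        rows.append(r)
        names.append("total ubiquinone")
        return np.vstack(rows), names

    def moiety_totals(self, y: np.ndarray) -> np.ndarray:
        return self.moieties @ y

    def audit_conservation(self, n_trials: int = 5, seed: int = 2012,
                           tol: float = 1e-9) -> None:
        """Verify the moiety rows annihilate the RHS on random valid states.

        The matrix proton row is excluded by construction (protons are open
        through the clamped cytosol).  Raises :class:`AssemblyError` naming
        the violated moiety.
        """
        rng = np.random.default_rng(seed)
        y0 = self.initial_state()
        scale = np.abs(y0) + 1e-6
        for _ in range(n_trials):
            y = y0 * np.exp(rng.normal(0, 0.2, self.n_states))
            y[self.i_dpsi] = y0[self.i_dpsi] + rng.normal(0, 15)
            dy = self.rhs(0.0, y)
            drift = self.moieties @ dy
            ref = np.abs(self.moieties) @ (np.abs(dy) + 1e-12)
            bad = np.abs(drift) > tol * (ref + 1e-12)
            if bad.any():
                name = self.moiety_names[int(np.argmax(bad))]
                raise AssemblyError(
                    f"moiety {name!r} not conserved by the assembled RHS "
                    f"(drift {drift[bad][0]:.3e})")

    # -- right-hand side ---------------------------------------------------

    def fluxes(self, y: np.ndarray) -> dict[str, float]:
        """All named fluxes and diagnostic quantities at state ``y``."""
        _, diag = self._evaluate(y, want_diagnostics=True)
        return diag

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy, _ = self._evaluate(y, want_diagnostics=False)
        return dy

    def _evaluate(self, y: np.ndarray, want_diagnostics: bool):
        cfg = self.config
        ix = self.idx
        yc = np.maximum(y, 0.0)  # rates evaluated on clipped concentrations
        dpsi = y[self.i_dpsi]
        yc[self.i_dpsi] = dpsi

        conc = {n: yc[ix[n]] for n in SCALAR_NAMES}
        h_m = max(conc["H_m"], 1e-9)
        ph_m = mm_to_ph(h_m)
        h_c = self._h_c
        ca = tca.calcium_concentration(dpsi, self._coupling)
        ca_ref = self._coupling.reference

        # TCA + PDH
        v_tca: dict[str, float] = {}
        for eid in tca.TCA_ENZYME_IDS:
            v_tca[eid] = tca.enzyme_rate(self._enzymes[eid], conc, ca, ca_ref)

        # respiratory-chain machines: occupancies enter the mass-action
        # fluxes linearly, so tiny negative integrator noise is passed
        # through unclipped (clipping would put a derivative kink exactly
        # at the operating point of the empty microstates)
        pools = self._machine_pools(yc)
        ci_occ = y[self.ci_slice]
        ciii_occ = y[self.ciii_slice]
        ci_flux = self.ci_tset.fluxes(ci_occ, dpsi, pools,
                                      alpha=cfg.complex_i.alpha)
        ciii_flux = self.ciii_tset.fluxes(ciii_occ, dpsi, pools,
                                          alpha=cfg.complex_iii.alpha)

        t_ = cfg.transporters
        v_c4 = tr.complex_iv_flux(conc["cytc_red"], cfg.pools.cytc_total,
                                  cfg.clamps.o2, dpsi, t_.v_c4, t_.km_o2,
                                  t_.kappa_c4)

        # transport
        j_h_leak = tr.proton_leak_flux(h_m, h_c, dpsi, t_.p_h,
                                       t_.lambda_leak, t_.dpsi_leak_ref)
        j_k = tr.ghk_flux(1, conc["K_m"], cfg.clamps.k_c, dpsi, t_.p_k)
        j_na = tr.ghk_flux(1, conc["Na_m"], cfg.clamps.na_c, dpsi, t_.p_na)
        j_cl = tr.ghk_flux(-1, conc["Cl_m"], cfg.clamps.cl_c, dpsi, t_.p_cl)
        v_kh = tr.cation_proton_antiport_flux(
            max(conc["K_m"], 1e-9), cfg.clamps.k_c, h_m, h_c, t_.v_kh,
            t_.km_kh_c, t_.km_kh_h)
        v_nah = tr.cation_proton_antiport_flux(
            max(conc["Na_m"], 1e-9), cfg.clamps.na_c, h_m, h_c, t_.v_nah,
            t_.km_kh_c, t_.km_kh_h)
        v_ant = tr.ant_flux(conc["ATP_m"], conc["ADP_m"], conc["ATP_c"],
                            conc["ADP_c"], dpsi, t_.v_ant, t_.km_ant_m,
                            t_.km_ant_c)
        v_f1 = tr.atp_synthase_flux(dpsi, ph_m, cfg.clamps.ph_c,
                                    conc["ATP_m"], conc["ADP_m"],
                                    conc["Pi_m"], self._syn)
        v_pi = tr.pi_carrier_flux(conc["Pi_m"], cfg.clamps.pi_c, h_m, h_c,
                                  t_.v_pi, t_.km_pi)
        v_pyr = tr.pyruvate_carrier_flux(conc["Pyr_m"], cfg.clamps.pyr_c,
                                         t_.v_pyr, t_.km_pyr)
        v_load = tr.atp_load_flux(conc["ATP_c"], self._load_multiplier,
                                  cfg.load.k_load, cfg.load.km_load)
        v_qh = t_.k_qdiff * (conc["QH2_n"] - conc["QH2_p"])
        v_q = t_.k_qdiff * (conc["Q_p"] - conc["Q_n"])

        # -- derivative assembly ------------------------------------------
        dy = np.zeros(self.n_states)

        for eid, v in v_tca.items():
            rxn = tca.REACTIONS[eid]
            for sp in rxn["sub"]:
                dy[ix[sp]] -= v
            for sp in rxn["prod"]:
                dy[ix[sp]] += v

        dy[self.ci_slice] += self.ci_tset.occupancy_derivative(ci_flux)
        dy[self.ciii_slice] += self.ciii_tset.occupancy_derivative(ciii_flux)
        prod_ci = self.ci_tset.pool_production(ci_flux)
        prod_c3 = self.ciii_tset.pool_production(ciii_flux)
        machine_h_m = 0.0
        for i, gi in enumerate(self._machine_pool_idx):
            p = prod_ci[i] + prod_c3[i]
            if ss.POOL_NAMES[i] == "H_m":
                machine_h_m = p
            elif gi >= 0:
                dy[gi] += p

        dy[ix["cytc_red"]] -= 2.0 * v_c4
        dy[ix["cytc_ox"]] += 2.0 * v_c4

        dy[ix["ATP_m"]] += v_f1 - v_ant
        dy[ix["ADP_m"]] += -v_f1 + v_ant
        dy[ix["Pi_m"]] += v_pi - v_f1
        rv = cfg.membrane.volume_ratio
        dy[ix["ATP_c"]] += v_ant / rv - v_load
        dy[ix["ADP_c"]] += -v_ant / rv + v_load
        dy[ix["Pyr_m"]] += v_pyr
        dy[ix["K_m"]] += j_k - v_kh
        dy[ix["Na_m"]] += j_na - v_nah
        dy[ix["Cl_m"]] += j_cl
        dy[ix["QH2_n"]] += -v_qh
        dy[ix["QH2_p"]] += v_qh
        dy[ix["Q_p"]] += -v_q
        dy[ix["Q_n"]] += v_q

        tca_h = sum(tca.REACTIONS[eid]["h_m"] * v for eid, v in v_tca.items())
        j_h_net = (j_h_leak + v_kh + v_nah + t_.n_a * v_f1 + v_pi
                   + machine_h_m + tca_h - 4.0 * v_c4)
        dy[ix["H_m"]] = LN10 * h_m / cfg.buffering.beta_h * j_h_net

        charge_out = (float(self.ci_tset.z @ ci_flux)
                      + float(self.ciii_tset.z @ ciii_flux)
                      + 4.0 * v_c4
                      - v_ant - t_.n_a * v_f1
                      - j_h_leak - j_k - j_na + j_cl)
        dy[self.i_dpsi] = -charge_out / cfg.membrane.capacitance

        if not want_diagnostics:
            return dy, None

        pumped = (float(self.ci_tset.pumped @ ci_flux)
                  + float(self.ciii_tset.pumped @ ciii_flux)
                  + 2.0 * v_c4)
        reentry_atp = t_.n_a * v_f1 + v_pi
        reentry_total = j_h_leak + v_kh + v_nah + reentry_atp
        nadh = conc["NADH"]
        nad = conc["NAD"]
        diag = {
            "dpsi": dpsi,
            "ph_m": ph_m,
            "calcium": ca,
            "nadh": nadh,
            "nadh_ratio": nadh / nad if nad > 0 else np.inf,
            "atp_c": conc["ATP_c"],
            "akg": conc["aKG"],
            "cytc_red_fraction": conc["cytc_red"] / cfg.pools.cytc_total,
            "qh2_q_total": (conc["QH2_n"] + conc["QH2_p"])
            / max(conc["Q_n"] + conc["Q_p"], 1e-12),
            "qh2_q_p": conc["QH2_p"] / max(conc["Q_p"], 1e-12),
            "qh2_q_n": conc["QH2_n"] / max(conc["Q_n"], 1e-12),
            "v_c4": v_c4,
            "o2_consumption": 0.5 * v_c4,
            "v_ant": v_ant,
            "v_f1": v_f1,
            "v_scs": v_tca["SCS"],
            "atp_production": v_f1 + v_tca["SCS"],
            "v_load_cyt": v_load,
            "v_load_matrix": v_load * rv,
            "j_h_leak": j_h_leak,
            "v_kh": v_kh,
            "v_nah": v_nah,
            "v_pi": v_pi,
            "v_pyr": v_pyr,
            "j_k": j_k,
            "j_na": j_na,
            "j_cl": j_cl,
            "protons_pumped": pumped,
            "proton_reentry": reentry_total,
            "share_leak": j_h_leak / reentry_total if reentry_total else np.nan,
            "share_k": v_kh / reentry_total if reentry_total else np.nan,
            "share_na": v_nah / reentry_total if reentry_total else np.nan,
            "share_atp": reentry_atp / reentry_total if reentry_total else np.nan,
            "charge_imbalance": charge_out,
            "load_multiplier": self._load_multiplier,
        }
        for eid, v in v_tca.items():
            diag[f"v_{eid}"] = v
        ci_marg = ss.complex_occupancy_summaries(self.ci_space, ci_occ)
        c3_marg = ss.complex_occupancy_summaries(self.ciii_space, ciii_occ)
        for k, v in {**ci_marg, **c3_marg}.items():
            diag[f"occ_{k}"] = v
        return dy, diag

    def observables(self, y: np.ndarray) -> dict[str, float]:
        """Observables recomputed from a state vector (never cached)."""
        return self.fluxes(y)


def assemble(config: ModelConfig) -> ModelSystem:
    """Build a :class:`ModelSystem` from a validated configuration."""
    return ModelSystem(config)


# ---------------------------------------------------------------------------
# Integration and steady-state location
# ---------------------------------------------------------------------------


def integrate(system: ModelSystem, y0: np.ndarray, t_end: float,
              rtol: float = 1e-8, atol: float | np.ndarray | None = None,
              dense: bool = False):
    """Stiff integration to ``t_end`` (BDF).

    Raises a diagnostic error naming the fastest-changing state variable if
    the integrator fails.
    """
    if t_end == 0.0:
        class _Zero:
            t = np.array([0.0])
            y = y0.reshape(-1, 1)
            success = True
        return _Zero()
    if atol is None:
        atol = np.full(system.n_states, 1e-8)
        atol[system.i_dpsi] = 1e-5
    sol = solve_ivp(system.rhs, (0.0, t_end), y0, method="BDF",
                    rtol=rtol, atol=atol, dense_output=dense)
    if not sol.success:
        yl = sol.y[:, -1]
        dy = system.rhs(0.0, yl)
        worst = int(np.argmax(np.abs(dy) / (np.abs(yl) + 1e-9)))
        raise RuntimeError(
            f"integration failed at t={sol.t[-1]:.3g}s; fastest-changing "
            f"state: {system.state_names()[worst]} (dy/dt={dy[worst]:.3e})")
    return sol


def _residual_weights(system: ModelSystem, y: np.ndarray) -> np.ndarray:
    w = np.maximum(np.abs(y), 1e-3)
    ci_floor = 2e-2 * max(system.config.pools.ci_total, 1e-9)
    c3_floor = 2e-2 * max(system.config.pools.ciii_total, 1e-9)
    w[system.ci_slice] = np.maximum(np.abs(y[system.ci_slice]), ci_floor)
    w[system.ciii_slice] = np.maximum(np.abs(y[system.ciii_slice]), c3_floor)
    w[system.i_dpsi] = 100.0
    return w


def _fd_jacobian(fun, y: np.ndarray, f0: np.ndarray) -> np.ndarray:
    n = len(y)
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-7 * max(abs(y[j]), 1e-6)
        yp = y.copy()
        yp[j] += h
        J[:, j] = (fun(yp) - f0) / h
    return J


def _scaled_residual(system: ModelSystem, f: np.ndarray,
                     y: np.ndarray) -> float:
    return float(np.max(np.abs(f) / _residual_weights(system, y)))


def _embed(system: ModelSystem, x: np.ndarray) -> np.ndarray:
    """Full state from reduced scalars, machines at their internal steady
    state given the pools and membrane potential (exact at steady state)."""
    y = np.zeros(system.n_states)
    n_sc = len(SCALAR_NAMES)
    y[:n_sc] = np.maximum(x[:n_sc], 0.0)
    dpsi = x[-1]
    y[system.i_dpsi] = dpsi
    pools = system._machine_pools(y)
    cfg = system.config
    occ_ci = ss.machine_steady_state(system.ci_tset, pools, dpsi,
                                     cfg.pools.ci_total,
                                     alpha=cfg.complex_i.alpha)
    occ_c3 = ss.machine_steady_state(system.ciii_tset, pools, dpsi,
                                     cfg.pools.ciii_total,
                                     alpha=cfg.complex_iii.alpha)
    y[system.ci_slice] = np.maximum(occ_ci, 0.0)
    y[system.ciii_slice] = np.maximum(occ_c3, 0.0)
    return y


def _reduced_indices(system: ModelSystem) -> np.ndarray:
    return np.concatenate([np.arange(len(SCALAR_NAMES)), [system.i_dpsi]])


def _reduced_moieties(system: ModelSystem):
    """Conservation rows of the reduced problem.  The per-complex occupancy
    totals hold by construction inside the machine elimination; the total
    ubiquinone row needs the machine-bound semiquinone marginals, evaluated
    on the embedded state."""
    ix = system.idx
    rows = [
        ({"NAD": 1, "NADH": 1}, None),
        ({"CoA": 1, "ACoA": 1, "SucCoA": 1}, None),
        ({"Cit": 1, "IsoCit": 1, "aKG": 1, "SucCoA": 1, "Suc": 1,
          "Fum": 1, "Mal": 1, "OA": 1}, None),
        ({"ATP_m": 1, "ADP_m": 1}, None),
        ({"ATP_c": 1, "ADP_c": 1}, None),
        ({"cytc_ox": 1, "cytc_red": 1}, None),
        ({"Q_n": 1, "QH2_n": 1, "Q_p": 1, "QH2_p": 1}, "bound_sq"),
    ]
    return rows


def _bound_sq(system: ModelSystem, y_full: np.ndarray) -> float:
    ci_sq = (system.ci_space.column("SQ") == 1)
    c3_sq = ((system.ciii_space.column("SQp") == 1)
             | (system.ciii_space.column("SQn") == 1)).astype(float) \
        + ((system.ciii_space.column("SQp") == 1)
           & (system.ciii_space.column("SQn") == 1)).astype(float)
    # SQp and SQn each hold one quinone: count both when both bound
    c3_count = ((system.ciii_space.column("SQp") == 1).astype(float)
                + (system.ciii_space.column("SQn") == 1).astype(float))
    return float(y_full[system.ci_slice] @ ci_sq.astype(float)
                 + y_full[system.ciii_slice] @ c3_count)


def find_steady_state(system: ModelSystem, guess: np.ndarray | None = None,
                      load_multiplier: float | None = None,
                      pre_time: float = 1.0, tol: float = 1e-8,
                      max_iter: int = 60) -> SteadyStateResult:
    """Locate a steady state of the assembled model.

    The microstate blocks of complexes I and III are eliminated exactly:
    at fixed pools and membrane potential their steady state solves a
    linear master equation, so a damped Newton iteration runs on the
    reduced system of metabolite, ion, nucleotide and membrane-potential
    balances only, with one balance row per conserved moiety replaced by
    its conservation residual (totals from the supplied guess).  This
    avoids the extreme stiffness of the coupled system entirely.  The
    scaled residual is ``max_i |f_i| / max(|y_i|, floor_i)`` over the full
    state vector, a per-second relative rate of change.  Failure to
    converge returns a flagged result, never raises.
    """
    if load_multiplier is not None:
        system.load_multiplier = load_multiplier
    y0 = system.initial_state() if guess is None else guess.copy()
    if pre_time > 0:
        try:
            sol = integrate(system, y0, pre_time, rtol=1e-6)
            y0 = np.asarray(sol.y[:, -1]).copy()
        except RuntimeError:
            pass
    red = _reduced_indices(system)
    n_sc = len(SCALAR_NAMES)
    x = y0[red].copy()
    ix = system.idx
    moieties = _reduced_moieties(system)
    totals = []
    y_init = _embed(system, x)
    for coeffs, extra in moieties:
        t = sum(c * y0[ix[n]] for n, c in coeffs.items())
        if extra == "bound_sq":
            # take the bound-quinone content of the original guess
            ci_sq = (system.ci_space.column("SQ") == 1).astype(float)
            c3_count = ((system.ciii_space.column("SQp") == 1).astype(float)
                        + (system.ciii_space.column("SQn") == 1).astype(float))
            t += float(y0[system.ci_slice] @ ci_sq
                       + y0[system.ciii_slice] @ c3_count)
        totals.append(t)
    # row replacement choices: the moiety member largest in the guess
    rep_rows: list[int] = []
    for coeffs, _ in moieties:
        cands = sorted(coeffs, key=lambda n: -abs(y0[ix[n]]))
        pick = next((ix[n] for n in cands if ix[n] not in rep_rows),
                    ix[cands[0]])
        rep_rows.append(pick)

    def residual(xv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        y = _embed(system, xv)
        f_full = system.rhs(0.0, y)
        f = f_full[red].copy()
        for k, (coeffs, extra) in enumerate(moieties):
            c = sum(cc * y[ix[n]] for n, cc in coeffs.items()) - totals[k]
            if extra == "bound_sq":
                c += _bound_sq(system, y)
            f[rep_rows[k]] = c
        return f, y

    def weights(xv: np.ndarray) -> np.ndarray:
        w = np.maximum(np.abs(xv), 1e-3)
        w[-1] = 100.0
        return w

    def newton(x0: np.ndarray):
        """Damped Newton in log-concentration space with row scaling."""
        floor = 1e-12
        x = x0.copy()
        x[:n_sc] = np.maximum(x[:n_sc], 0.0)
        n = len(x)

        def to_z(xv):
            z = np.empty(n)
            z[:n_sc] = np.log(np.maximum(xv[:n_sc], floor))
            z[-1] = xv[-1] / 100.0
            return z

        def from_z(z):
            xv = np.empty(n)
            xv[:n_sc] = np.exp(np.clip(z[:n_sc], -60.0, 10.0))
            xv[-1] = z[-1] * 100.0
            return xv

        def row_w(xv):
            w = np.maximum(np.abs(xv), 1e-3)
            w[-1] = 100.0
            return w

        z = to_z(x)
        f, y = residual(x)
        w = row_w(x)
        res = float(np.max(np.abs(f) / w))
        res2 = float(np.linalg.norm(f / w))
        best = (res, x.copy(), y)
        for _ in range(max_iter):
            if res < tol:
                break
            J = np.empty((n, n))
            for j in range(n):
                h = 1e-6 * max(abs(z[j]), 1.0)
                zp = z.copy()
                zp[j] += h
                J[:, j] = (residual(from_z(zp))[0] - f) / h
            Jh = J / w[:, None]
            fh = f / w
            U, S, Vt = np.linalg.svd(Jh, full_matrices=False)
            keep = S > 1e-13 * S[0]
            Sinv = np.where(keep, 1.0 / np.maximum(S, 1e-300), 0.0)
            dz = Vt.T @ (Sinv * (U.T @ -fh))
            # trust region in log space: no component moves more than e^2
            mz = float(np.max(np.abs(dz)))
            lam = min(1.0, 2.0 / mz) if mz > 0 else 1.0
            improved = False
            for _ls in range(16):
                z_new = z + lam * dz
                x_new = from_z(z_new)
                f_new, y_new = residual(x_new)
                if np.all(np.isfinite(f_new)):
                    r2 = float(np.linalg.norm(f_new / w))
                    if r2 < res2 * (1.0 - 1e-4 * lam):
                        z, x, f, y = z_new, x_new, f_new, y_new
                        improved = True
                        break
                lam *= 0.5
            if not improved:
                break
            w = row_w(x)
            res = float(np.max(np.abs(f) / w))
            res2 = float(np.linalg.norm(f / w))
            if res < best[0]:
                best = (res, x.copy(), y)
        if res > best[0]:
            res, x, y = best
        return res, x, y

    def reduced_rhs(t, xv):
        return system.rhs(0.0, _embed(system, xv))[red]

    # relax along the reduced (machine-eliminated) dynamics: the microstate
    # blocks are slaved to the pools, so the stiff transitions drop out and
    # BDF cruises to the attractor
    atol = np.full(len(x), 1e-10)
    atol[-1] = 1e-6
    res, y = np.inf, _embed(system, x)
    for horizon in (5.0e2, 5.0e3):
        try:
            sol = solve_ivp(reduced_rhs, (0.0, horizon), x, method="BDF",
                            rtol=1e-5, atol=atol)
        except Exception:
            break
        if sol.success:
            x = np.asarray(sol.y[:, -1])
            x[:n_sc] = np.maximum(x[:n_sc], 0.0)
        res, x, y = newton(x)
        if res < tol:
            break
        if not sol.success:
            break
    converged = res < tol
    # full-state residual on the reconstructed state
    f_full = system.rhs(0.0, y)
    res_full = _scaled_residual(system, f_full, y)
    ok = converged and res_full < 1e-6
    return SteadyStateResult(
        state=y, residual=res_full, converged=ok,
        observables=system.observables(y),
        message="" if ok else "steady-state refinement did not converge")


# ---------------------------------------------------------------------------
# Stoichiometry audit
# ---------------------------------------------------------------------------

#: Event multiplicities along one full oxidation path, per 2 electrons.
_CI_PATH_PER_NADH = {
    "nadh_ox": 1, "fmn2_to_*": 1, "fmn1_to_*": 1, "chain": 2,
    "q_bind_reduce": 1, "sq_reduce_release": 1,
}
_CIII_PATH_PER_2E = {
    "qh2p_ox": 2, "sqp_to_bl": 2, "fes_to_c1": 2, "c1_to_cytc": 2,
    "bl_to_bh": 2, "qn_bind": 1, "sqn_reduce": 1,
}


def _ci_pumped_per_nadh(system: ModelSystem) -> int:
    total = 0
    rules = {r.name: r for r in system.ci_tset.rules}
    chain = (ss.CI_LUMPED_CHAIN if system.config.complex_i.variant == "lumped"
             else ss.CI_FULL_CHAIN)
    first = chain[0]
    total += rules["nadh_ox"].protons_pumped
    total += rules[f"fmn2_to_{first}"].protons_pumped
    total += rules[f"fmn1_to_{first}"].protons_pumped
    for donor, acceptor in zip(chain[:-1], chain[1:]):
        name = f"{donor.lower()}_to_{acceptor.lower()}"
        total += 2 * rules[name].protons_pumped  # both electrons traverse
    total += rules["q_bind_reduce"].protons_pumped
    total += rules["sq_reduce_release"].protons_pumped
    return total


def _ciii_pumped_per_2e(system: ModelSystem) -> int:
    rules = {r.name: r for r in system.ciii_tset.rules}
    total = 0
    for name, mult in _CIII_PATH_PER_2E.items():
        total += mult * rules[name].protons_pumped
    return total


def proton_stoichiometry_audit(system: ModelSystem) -> dict[str, int]:
    """Protons pumped per substrate along the canonical oxidation paths.

    Traces one NADH through CI -> CIII -> CIV and one succinate through
    CII -> CIII -> CIV, counting the ``protons_pumped`` tags of every event
    with its electron-bookkeeping multiplicity, and verifies the external
    quinone stoichiometry closes along each path.
    """
    # quinone closure of the CIII q-cycle path: 2 QH2_p in, 2 Q_p out,
    # 1 Q_n in, 1 QH2_n out -> net one ubiquinol oxidized per 2 e-
    rules = {r.name: r for r in system.ciii_tset.rules}
    net: dict[str, float] = {}
    for name, mult in _CIII_PATH_PER_2E.items():
        r = rules[name]
        for pool, nu in r.pools_forward:
            net[pool] = net.get(pool, 0.0) - mult * nu
        for pool, nu in r.pools_reverse:
            net[pool] = net.get(pool, 0.0) + mult * nu
    if not (net.get("QH2_p", 0) == -2 and net.get("Q_p", 0) == 2
            and net.get("Q_n", 0) == -1 and net.get("QH2_n", 0) == 1):
        raise AuditError(f"complex III q-cycle path does not close: {net}")

    ci = _ci_pumped_per_nadh(system)
    ciii = _ciii_pumped_per_2e(system)
    civ = 2  # per electron pair, from the complex IV stoichiometry
    cii = 0  # succinate dehydrogenase pumps no protons
    return {
        "complex_i": ci,
        "complex_ii": cii,
        "complex_iii": ciii,
        "complex_iv": civ,
        "nadh_path": ci + ciii + civ,
        "succinate_path": cii + ciii + civ,
    }
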