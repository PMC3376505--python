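"""Inner-membrane electrophysiology: ion leaks, carriers, ATP synthase,
complex IV, the cytosolic ATP load, and the membrane-potential ODE.

Sign conventions (see :mod:`mitodyn.constants`): ``dpsi`` is matrix minus
cytosol in mV (negative when energized); transport fluxes are positive into
the matrix; ``charge_out`` coefficients count positive elementary charges
leaving the matrix per flux unit, and the membrane potential obeys

    d(dpsi)/dt = -(1/C) * sum_i q_i * J_i,

so outward pumping (q > 0) drives the potential negative.

Passive ion permeation uses the Goldman-Hodgkin-Katz flux equation

    J_in = P * z*u * (c_out - c_in * exp(z*u)) / (exp(z*u) - 1),

with ``u = F*dpsi/RT``; the u -> 0 limit is the linear form
``P * (c_out - c_in)`` and the flux vanishes at the Nernst potential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .constants import FARADAY_KJ_PER_MOL_V, LN10, RT_KJ, RT_OVER_F_MV

__all__ = [
    "ghk_flux",
    "electrodiffusion_flux",
    "cation_proton_antiport_flux",
    "ant_flux",
    "atp_synthase_flux",
    "synthase_reversal_dpsi",
    "complex_iv_flux",
    "pi_carrier_flux",
    "pyruvate_carrier_flux",
    "atp_load_flux",
    "membrane_potential_derivative",
]


def ghk_flux(z: int, c_in: float, c_out: float, dpsi_mv: float,
             permeability: float) -> float:
    """GHK electrodiffusion flux into the matrix (mM/s).

    ``permeability`` has units 1/s (flux per mM of driving concentration).
    Continuous at ``dpsi = 0`` through the linear limit.
    """
    if c_in < 0 or c_out < 0:
        raise ValueError("non-positive concentration in GHK flux")
    zu = z * dpsi_mv / RT_OVER_F_MV
    if abs(zu) < 1.0e-6:
        # first-order expansion around zu = 0
        return permeability * ((c_out - c_in) - 0.5 * zu * (c_out + c_in))
    ezu = np.exp(zu)
    return permeability * zu * (c_out - c_in * ezu) / (ezu - 1.0)


#: Alias naming the GHK electrodiffusion operation by its physical role.
electrodiffusion_flux = ghk_flux


def proton_leak_flux(h_m: float, h_c: float, dpsi_mv: float,
                     permeability: float, lambda_mv: float = 14.0,
                     dpsi_ref_mv: float = -140.0) -> float:
    """Non-ohmic inner-membrane proton leak (mM/s into the matrix).

    The GHK electrodiffusion flux is amplified by ``exp(-(dpsi - dpsi_ref)
    / lambda)``: the leak conductance grows e-fold per ``lambda_mv`` of
    hyperpolarization beyond the reference potential and shuts down on
    depolarization, reproducing the strongly non-ohmic proton conductance
    of the inner membrane.  The factor is unity at the reference potential,
    so calibration at the reference state is unaffected.
    """
    base = ghk_flux(1, h_m, h_c, dpsi_mv, permeability)
    return base * np.exp(-(dpsi_mv - dpsi_ref_mv) / lambda_mv)


def cation_proton_antiport_flux(c_in: float, c_out: float, h_in: float,
                                h_out: float, vmax: float,
                                km_c: float = 30.0,
                                km_h: float = 2.0e-4) -> float:
    """Electroneutral 1:1 cation/H+ exchange; positive = cation efflux.

    Driven by the ratio ``(c_in * h_out) / (c_out * h_in)``; zero at
    equilibrium ratio 1, so the isolated antiporter relaxes the matrix/
    cytosol cation ratio to ``h_in / h_out``.
    """
    if min(c_in, c_out, h_in, h_out) <= 0:
        raise ValueError("antiport requires positive concentrations")
    num = c_in * h_out - c_out * h_in
    den = (km_c + c_in + c_out) * (km_h + h_in + h_out)
    return vmax * num / den


def ant_flux(atp_m: float, adp_m: float, atp_c: float, adp_c: float,
             dpsi_mv: float, vmax: float, km_m: float = 1.0,
             km_c: float = 0.2, alpha: float = 0.5) -> float:
    """Adenine nucleotide translocase: ATP4- out / ADP3- in exchange rate.

    Positive values export matrix ATP.  The exchange carries net charge -1
    outward, so an inside-negative potential biases it toward export; the
    zero crossing sits at ``(atp_c * adp_m)/(atp_m * adp_c) = exp(-u)``.
    """
    u = dpsi_mv / RT_OVER_F_MV
    f = np.exp(-alpha * u)
    r = np.exp((1.0 - alpha) * u)
    num = atp_m * adp_c * f - atp_c * adp_m * r
    den = (km_m + atp_m + adp_m) * (km_c + atp_c + adp_c)
    return vmax * num / den


@dataclass
class SynthaseParams:
    vmax: float = 2.0          # mM/s scale of the sinh rate law
    n_a: float = 3.0           # protons translocated per ATP by F0F1
    dg0_kj: float = 31.9       # standard Gibbs energy of ATP synthesis, kJ/mol


def _phosphorylation_dg(atp_m: float, adp_m: float, pi_m: float,
                        dg0_kj: float) -> float:
    """Gibbs energy of ADP + Pi -> ATP in the matrix (kJ/mol, mM inputs)."""
    atp = max(atp_m, 1e-12)
    adp = max(adp_m, 1e-12)
    pi = max(pi_m, 1e-12)
    # concentrations mM -> M introduces the factor 1e3
    return dg0_kj + RT_KJ * np.log(atp / (adp * pi) * 1.0e3)


def atp_synthase_flux(dpsi_mv: float, ph_m: float, ph_c: float, atp_m: float,
                      adp_m: float, pi_m: float,
                      params: SynthaseParams) -> float:
    """Reversible F0F1-ATPase rate (mM/s, positive = ATP synthesis).

    Driven by ``-(dG_phos + n_A * F * dp)`` with the proton-motive force
    ``dp = dpsi - Z * dpH`` (Z = RT/F * ln 10, dpH = pH_m - pH_c).  The rate
    is ``vmax * sinh(x)`` in the scaled driving force, which keeps the flux
    reversible and smooth through the thermodynamic reversal point while
    providing the steep response of a multi-proton reaction.
    """
    z_mv = RT_OVER_F_MV * LN10
    dp_mv = dpsi_mv - z_mv * (ph_m - ph_c)
    dg_phos = _phosphorylation_dg(atp_m, adp_m, pi_m, params.dg0_kj)
    dg_syn = dg_phos + params.n_a * FARADAY_KJ_PER_MOL_V * (dp_mv * 1.0e-3)
    x = np.clip(-dg_syn / (2.0 * RT_KJ), -25.0, 25.0)
    return params.vmax * np.sinh(x)


def synthase_reversal_dpsi(ph_m: float, ph_c: float, atp_m: float,
                           adp_m: float, pi_m: float,
                           params: SynthaseParams) -> float:
    """Membrane potential (mV) at which the synthase flux changes sign:
    ``dpsi_rev = -dG_phos/(n_A * F) + Z * dpH``."""
    z_mv = RT_OVER_F_MV * LN10
    dg_phos = _phosphorylation_dg(atp_m, adp_m, pi_m, params.dg0_kj)
    return -dg_phos / (params.n_a * FARADAY_KJ_PER_MOL_V) * 1.0e3 \
        + z_mv * (ph_m - ph_c)


def complex_iv_flux(cytc_red: float, cytc_total: float, o2: float,
                    dpsi_mv: float, vmax: float, km_o2: float = 1.0e-3,
                    kappa: float = 0.35) -> float:
    """Cytochrome c oxidase electron-pair flux (mM/s of 2 e- transfers).

    Irreversible and second order in the reduced cytochrome c fraction (two
    cytochromes per O-O bond half-reduced), saturable in oxygen, with an
    exponential attenuation of the electrogenic steps as the membrane
    hyperpolarizes.  Per electron pair: 2 cyt c re-oxidized, 1/2 O2 consumed,
    2 protons pumped plus 2 matrix protons consumed chemically (4 charges).
    """
    if cytc_red < 0 or o2 < 0:
        raise ValueError("negative concentration in complex IV flux")
    if cytc_total <= 0:
        return 0.0
    fred = cytc_red / cytc_total
    u = dpsi_mv / RT_OVER_F_MV
    return vmax * fred * fred * o2 / (km_o2 + o2) * np.exp(kappa * u)


def pi_carrier_flux(pi_m: float, pi_c: float, h_m: float, h_c: float,
                    vmax: float, km: float = 2.0) -> float:
    """Electroneutral Pi-/H+ symport into the matrix (mM/s); equilibrium at
    ``pi_m / pi_c = h_c / h_m``."""
    num = pi_c * h_c - pi_m * h_m
    den = (km + pi_c + pi_m) * 1.0e-4  # proton scale folded into vmax units
    return vmax * num / den


def pyruvate_carrier_flux(pyr_m: float, pyr_c: float, vmax: float,
                          km: float = 0.3) -> float:
    """Saturable pyruvate uptake into the matrix (mM/s).

    Modelled as facilitated diffusion with no net proton cost: the carrier
    symports one H+ per pyruvate anion, but that proton is stoichiometrically
    returned when the CO2 produced by pyruvate oxidation (not tracked as a
    state) hydrates and leaves the matrix, so the net gradient debit of
    steady-state pyruvate oxidation is zero.
    """
    num = pyr_c - pyr_m
    den = km + pyr_c + pyr_m
    return vmax * num / den


def atp_load_flux(atp_c: float, load_multiplier: float, k_load: float,
                  km_load: float = 0.35) -> float:
    """Cytosolic ATP hydrolysis rate (cytosolic mM/s).

    Saturable in ATP and linear in the load multiplier; multiplier 1 is the
    reference energetic demand.
    """
    if load_multiplier < 0:
        raise ValueError("load multiplier must be non-negative")
    if atp_c <= 0:
        return 0.0
    return load_multiplier * k_load * atp_c / (km_load + atp_c)


def membrane_potential_derivative(charge_fluxes: Mapping[str, tuple[float, float]]
                                  | np.ndarray,
                                  capacitance: float,
                                  charges: np.ndarray | None = None) -> float:
    """d(dpsi)/dt in mV/s from charge-tagged fluxes.

    ``charge_fluxes`` is either a mapping ``name -> (q, J)`` with ``q`` the
    positive charge moved out of the matrix per flux unit, or a flux array
    accompanied by a matching ``charges`` array.  Untagged fluxes (mapping
    values that are not (q, J) pairs) raise a configuration error.
    """
    if capacitance <= 0:
        raise ValueError("capacitance must be positive")
    if isinstance(charge_fluxes, np.ndarray):
        if charges is None:
            raise ValueError("flux array requires a matching charges array")
        total = float(np.dot(charges, charge_fluxes))
    else:
        total = 0.0
        for name, qj in charge_fluxes.items():
            try:
                q, j = qj
            except TypeError as exc:
                raise ValueError(f"flux {name!r} is not charge-tagged") from exc
            total += q * j
    return -total / capacitance
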