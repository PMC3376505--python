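"""Rate laws for pyruvate dehydrogenase and the TCA-cycle enzymes.

All nine reactions (PDH plus the eight cycle enzymes) use a reversible
Michaelis-Menten rate law with a Haldane-constrained reverse term,

    v = (1 - i) * Vmax * f_Ca * (prod S/Km_S) * (1 - Gamma/Keq') / D,

where ``Gamma`` is the mass-action ratio, ``Keq'`` the apparent equilibrium
constant (CO2 and water folded in), and ``D`` the standard reversible
denominator ``prod(1 + S/Km_S) + prod(1 + P/Km_P) - 1``.  ``i`` is the
enzyme's inhibition fraction and ``f_Ca`` a hyperbolic calcium-activation
multiplier, normalized to 1 at the reference calcium level, applied to the
three calcium-sensitive dehydrogenases (PDH, IDH, KGDHC).

Mitochondrial free calcium is modelled as a clamped linear function of the
membrane potential (hyperpolarization promotes uptake), which stands in for
explicit uniporter dynamics.

Succinate dehydrogenase (complex II) is a single reversible reaction
reducing the n-site ubiquinone pool with no proton pumping.  The four
NADH-producing dehydrogenases release one scalar matrix proton each
(NAD+ -> NADH + H+), which closes the matrix proton balance against the
respiratory chain's uptake steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "TCA_ENZYME_IDS",
    "REACTIONS",
    "EnzymeParameters",
    "CalciumCoupling",
    "calcium_concentration",
    "enzyme_rate",
    "apply_inhibition",
]

#: Canonical enzyme order (PDH first, then the cycle in carbon-flow order).
TCA_ENZYME_IDS = ("PDH", "CS", "AC", "IDH", "KGDHC", "SCS", "SDH", "FUM", "MDH")

#: Reaction stoichiometry over named metabolite pools: substrates consumed,
#: products produced, and scalar matrix protons released per event.
#: CO2 release (PDH, IDH, KGDHC) is folded into the apparent Keq.
REACTIONS: dict[str, dict] = {
    "PDH": {"sub": ("Pyr_m", "CoA", "NAD"), "prod": ("ACoA", "NADH"), "h_m": 1},
    "CS": {"sub": ("ACoA", "OA"), "prod": ("Cit", "CoA"), "h_m": 0},
    "AC": {"sub": ("Cit",), "prod": ("IsoCit",), "h_m": 0},
    "IDH": {"sub": ("IsoCit", "NAD"), "prod": ("aKG", "NADH"), "h_m": 1},
    "KGDHC": {"sub": ("aKG", "CoA", "NAD"), "prod": ("SucCoA", "NADH"), "h_m": 1},
    "SCS": {"sub": ("SucCoA", "ADP_m", "Pi_m"), "prod": ("Suc", "CoA", "ATP_m"),
            "h_m": 0},
    "SDH": {"sub": ("Suc", "Q_n"), "prod": ("Fum", "QH2_n"), "h_m": 0},
    "FUM": {"sub": ("Fum",), "prod": ("Mal",), "h_m": 0},
    "MDH": {"sub": ("Mal", "NAD"), "prod": ("OA", "NADH"), "h_m": 1},
}

#: Enzymes whose activity is stimulated by matrix calcium.
CA_ACTIVATED = ("PDH", "IDH", "KGDHC")


@dataclass
class EnzymeParameters:
    """Kinetic constants of one reaction: Vmax (mM/s), Km per reactant (mM),
    apparent Keq, optional calcium-activation constant, inhibition fraction."""

    enzyme_id: str
    vmax: float
    km: dict[str, float]
    keq: float
    ka_ca: float | None = None
    inhibition: float = 0.0

    def __post_init__(self) -> None:
        if self.enzyme_id not in REACTIONS:
            raise ValueError(f"unknown enzyme {self.enzyme_id!r}")
        if self.vmax < 0:
            raise ValueError(f"{self.enzyme_id}: negative Vmax")
        if not 0.0 <= self.inhibition <= 1.0:
            raise ValueError(f"{self.enzyme_id}: inhibition outside [0, 1]")
        rxn = REACTIONS[self.enzyme_id]
        for species in rxn["sub"] + rxn["prod"]:
            if species not in self.km:
                raise KeyError(f"{self.enzyme_id}: missing Km for {species}")
            if self.km[species] <= 0:
                raise ValueError(f"{self.enzyme_id}: non-positive Km[{species}]")


@dataclass
class CalciumCoupling:
    """Matrix free calcium as a clamped linear function of membrane potential."""

    slope: float = -4.0e-6    # mM per mV (more negative potential -> more Ca)
    intercept: float = -2.0e-4  # mM
    lower: float = 1.0e-5     # mM
    upper: float = 2.0e-3     # mM
    reference: float = 4.0e-4  # mM, calcium at the reference state


def calcium_concentration(dpsi_mv: float, coupling: CalciumCoupling) -> float:
    """Clamped linear map from membrane potential to matrix calcium (mM)."""
    ca = coupling.intercept + coupling.slope * dpsi_mv
    return float(min(max(ca, coupling.lower), coupling.upper))


def _ca_factor(params: EnzymeParameters, ca: float, ca_ref: float) -> float:
    if params.enzyme_id not in CA_ACTIVATED or params.ka_ca is None:
        return 1.0
    return (1.0 + ca / params.ka_ca) / (1.0 + ca_ref / params.ka_ca)


def enzyme_rate(params: EnzymeParameters, pools: Mapping[str, float],
                ca: float = 0.0, ca_ref: float = 0.0) -> float:
    """Net reaction rate (mM/s, positive in the forward direction).

    For the NAD-linked dehydrogenases, NAD and NADH compete for a single
    nucleotide binding site — the denominator carries one term
    ``(1 + NAD/Km_NAD + NADH/Km_NADH)`` instead of separate substrate and
    product saturation factors — which is what gives the cycle its strong
    response to the matrix redox state.
    """
    rxn = REACTIONS[params.enzyme_id]
    nucleotide = "NAD" in rxn["sub"]
    s_red, p_red = 1.0, 1.0
    s_sat, p_sat = 1.0, 1.0
    gamma_num = 1.0
    for sp in rxn["sub"]:
        c = pools[sp]
        if c < 0:
            raise ValueError(f"negative concentration for {sp}")
        s_red *= c / params.km[sp]
        if not (nucleotide and sp == "NAD"):
            s_sat *= 1.0 + c / params.km[sp]
    for sp in rxn["prod"]:
        c = pools[sp]
        if c < 0:
            raise ValueError(f"negative concentration for {sp}")
        p_red *= c / params.km[sp]
        if not (nucleotide and sp == "NADH"):
            p_sat *= 1.0 + c / params.km[sp]
        gamma_num *= c
    if nucleotide:
        site = 1.0 + pools["NAD"] / params.km["NAD"] \
            + pools["NADH"] / params.km["NADH"]
        denom = s_sat * site + p_sat - 1.0
    else:
        denom = s_sat + p_sat - 1.0
    # (prod S/Km) * (1 - Gamma/Keq) written without forming Gamma itself so
    # zero substrate concentrations stay well defined
    km_s = np.prod([params.km[sp] for sp in rxn["sub"]])
    drive = s_red - gamma_num / (params.keq * km_s)
    fca = _ca_factor(params, ca, ca_ref)
    return (1.0 - params.inhibition) * params.vmax * fca * drive / denom


def apply_inhibition(enzymes: Mapping[str, EnzymeParameters], enzyme_id: str,
                     fraction: float) -> dict[str, EnzymeParameters]:
    """Return a copy of the enzyme table with one inhibition fraction set.

    The fraction is always interpreted against the uninhibited baseline
    (idempotent: re-applying the same fraction is a no-op; applying 0.3 then
    0.6 equals applying 0.6 once).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("inhibition fraction outside [0, 1]")
    if enzyme_id not in enzymes:
        raise KeyError(f"unknown enzyme {enzyme_id!r}")
    out = dict(enzymes)
    out[enzyme_id] = replace(enzymes[enzyme_id], inhibition=fraction)
    return out
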