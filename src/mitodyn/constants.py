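"""Physical constants and unit conventions.

Units used throughout the package: concentrations in mM, electrical
potentials in mV, time in seconds, fluxes in mM/s referred to the matrix
volume unless stated otherwise.

Sign conventions:

* ``dpsi`` is the inner-membrane potential, matrix minus cytosol, in mV.
  An energized mitochondrion has ``dpsi`` around -150 mV (negative inside).
* ``z`` (``charge_moved``) on a transition is the number of positive
  elementary charges moved *out* of the matrix per forward event.
* Ion and metabolite transport fluxes are positive *into* the matrix.
"""

#: Faraday constant over gas constant times temperature, expressed as the
#: thermal voltage RT/F in mV at 310 K (37 C).
RT_OVER_F_MV = 26.712

#: RT in kJ/mol at 310 K, for free-energy bookkeeping of the ATP synthase.
RT_KJ = 2.5775

#: Faraday constant, kJ / (mol * V); multiply by volts to get kJ/mol.
FARADAY_KJ_PER_MOL_V = 96.485

#: ln(10), used for pH <-> proton concentration conversions.
LN10 = 2.302585092994046

#: Reference concentration for mass-action pool factors (mM).  Redox pool
#: concentrations enter transition rates as (c / C_REF)**nu so that rate
#: constants stay in per-second units and equilibrium constants derived from
#: midpoint potentials (quoted at pH 7) remain consistent across complexes.
C_REF_MM = 1.0

#: Reference proton concentration, 1e-4 mM = pH 7, matching the pH at which
#: the midpoint potentials of the proton-carrying couples are quoted.
H_REF_MM = 1.0e-4


def ph_to_mm(ph: float) -> float:
    """Convert a pH value to a proton concentration in mM."""
    return 10.0 ** (-ph) * 1.0e3


def mm_to_ph(h_mm: float) -> float:
    """Convert a proton concentration in mM to pH."""
    import math

    return -math.log10(h_mm * 1.0e-3)
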