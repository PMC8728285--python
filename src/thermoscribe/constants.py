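"""Physical constants and default aqueous conditions.

All energies are in kJ/mol, concentrations in M, temperatures in K and
membrane potentials in V throughout the package. The formation-energy
conventions follow Alberty's transformed-thermodynamics framework: the
proton's standard chemical formation energy is fixed at zero and the
magnesium ion's at -455.3 kJ/mol, so that pseudoisomer formation
energies of Mg-bound species are directly comparable across compounds.
"""

from __future__ import annotations

#: Gas constant, kJ/(mol*K).
R = 8.314462e-3

#: Standard chemical formation energy of the proton, kJ/mol (convention).
DGF_PROTON = 0.0

#: Standard chemical formation energy of Mg2+, kJ/mol (convention).
DGF_MG = -455.3

#: Faraday constant at full precision, kC/mol (1 kC*V = 1 kJ).
FARADAY = 96.485

#: Faraday constant rounded for display, kC/mol.
FARADAY_DISPLAY = 96.5

# Extended Debye-Hueckel parameter alpha(T) = A1*T - A2*T^2 + A3*T^3 in
# kJ/mol/M^0.5 (RT already folded in), a cubic fit to Clarke & Glew (1980)
# as tabulated by Alberty, "Thermodynamics of Biochemical Reactions" (2003).
# At 298.15 K alpha evaluates to ~2.915 kJ/mol/M^0.5.
DEBYE_HUECKEL_A1 = 9.20483e-3
DEBYE_HUECKEL_A2 = 1.284668e-5
DEBYE_HUECKEL_A3 = 4.95199e-8

#: Extended Debye-Hueckel denominator constant B, 1/sqrt(M).
DEBYE_HUECKEL_B = 1.6

#: Default intracellular-like conditions.
DEFAULT_P_H = 7.0
DEFAULT_P_MG = 3.0
DEFAULT_IONIC_STRENGTH = 0.25
DEFAULT_TEMPERATURE = 298.15


def debye_hueckel_alpha(temperature: float) -> float:
    """Temperature-dependent extended Debye-Hueckel coefficient, kJ/mol/M^0.5."""
    t = temperature
    return DEBYE_HUECKEL_A1 * t - DEBYE_HUECKEL_A2 * t**2 + DEBYE_HUECKEL_A3 * t**3
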