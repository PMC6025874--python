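"""Physical constants and unit conversions.

Internal units: length nm, time ps, mass amu, stress MPa, energy kcal/mol,
entropy kcal mol^-1 K^-1.  CODATA 2018 values.
"""

import math

#: Boltzmann constant, J K^-1 (exact, SI definition)
KB_J = 1.380649e-23
#: Reduced Planck constant, J s
HBAR_J_S = 1.054571817e-34
#: Avogadro constant, mol^-1 (exact)
AVOGADRO = 6.02214076e23
#: Atomic mass unit, kg
AMU_KG = 1.66053906660e-27
#: Thermochemical calorie, J
CAL_J = 4.184
#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL_MOL_K = KB_J * AVOGADRO / (1000.0 * CAL_J)
#: Euler's number (the `e` of the Schlitter formula -- NOT the elementary charge)
E_EULER = math.e
#: 1 kJ mol^-1 nm^-3 expressed in MPa
KJ_MOL_NM3_TO_MPA = 1.0e3 / AVOGADRO / 1.0e-27 / 1.0e6  # = 1.6605...
#: nm^2 in m^2
NM2_M2 = 1.0e-18

#: Standard atomic masses, amu (elements that occur in nucleic acids/proteins
#: and in the coarse fixtures).
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
    "MG": 24.305,
    "K": 39.098,
    "MN": 54.938,
    "FE": 55.845,
    "ZN": 65.38,
}


def mass_of(element: str) -> float:
    """Atomic mass (amu) for an element symbol; raises KeyError if unknown."""
    return ATOMIC_MASSES[element.strip().upper()]


def kbt_kcal_mol(temperature: float) -> float:
    """k_B*T in kcal/mol at ``temperature`` (K)."""
    return KB_KCAL_MOL_K * temperature
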