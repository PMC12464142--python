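"""Physical constants, unit conversions and per-element data.

All internal energies are in hartree, coordinates in Å, frequencies in
cm⁻¹ and temperatures in kelvin.  Constants come from :mod:`scipy.constants`
(CODATA); the hartree↔kcal/mol↔kJ/mol factors therefore agree with the
conventional 627.5095 / 2625.4996 values.
"""

from __future__ import annotations

import scipy.constants as _sc

# fundamental constants (SI)
KB = _sc.k                      # J/K
H_PLANCK = _sc.h                # J s
C_LIGHT = _sc.c                 # m/s
N_AVOGADRO = _sc.N_A            # 1/mol
R_GAS = _sc.R                   # J/mol/K
AMU = _sc.atomic_mass           # kg

HARTREE_J = _sc.physical_constants["Hartree energy"][0]      # J
HARTREE_TO_JMOL = HARTREE_J * N_AVOGADRO
HARTREE_TO_KJMOL = HARTREE_TO_JMOL / 1e3                     # ≈ 2625.4996
HARTREE_TO_KCALMOL = HARTREE_TO_KJMOL / 4.184                # ≈ 627.5095
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL
KJMOL_TO_HARTREE = 1.0 / HARTREE_TO_KJMOL

# Boltzmann constant in hartree/K
KB_HARTREE = KB / HARTREE_J

# wavenumber (cm⁻¹) → hartree:  E = h c ν̃
CM1_TO_HARTREE = H_PLANCK * C_LIGHT * 100.0 / HARTREE_J

ATM_PA = _sc.atm                # 101325 Pa
BOHR_A = _sc.physical_constants["Bohr radius"][0] * 1e10     # Å

# atomic masses (u), most-abundant-isotope-weighted standard weights
ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Ne": 20.180, "Ar": 39.948,
    "S": 32.06, "P": 30.974, "Cl": 35.45,
}

# covalent radii (Å), Cordero et al. consensus values
COVALENT_RADII = {
    "H": 0.31, "He": 0.28,
    "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Ne": 0.58, "Ar": 1.06,
    "S": 1.05, "P": 1.07, "Cl": 1.02,
}

KNOWN_ELEMENTS = frozenset(ATOMIC_MASSES)


def hartree_to_kcal(x):
    """hartree → kcal/mol."""
    return x * HARTREE_TO_KCALMOL


def kcal_to_hartree(x):
    """kcal/mol → hartree."""
    return x * KCALMOL_TO_HARTREE


def hartree_to_kj(x):
    """hartree → kJ/mol."""
    return x * HARTREE_TO_KJMOL


def kj_to_hartree(x):
    """kJ/mol → hartree."""
    return x * KJMOL_TO_HARTREE
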