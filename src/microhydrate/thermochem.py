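"""Rigid-rotor / harmonic-oscillator ideal-gas thermochemistry.

Given a geometry, atomic masses, an electronic energy and a set of harmonic
wavenumbers, computes the standard statistical-mechanics partition-function
contributions (translational ideal gas at pressure P, classical rigid rotor
with symmetry number σ, quantum harmonic oscillators with the zero-point
energy separated out) and assembles H(T), S(T) and G(T) = H − T·S.

Conventions
-----------
* energies in hartree, wavenumbers in cm⁻¹, temperatures in K, pressure in atm;
* enthalpy includes the ideal-gas pV term: H = E_elec + ZPE + E_thermal + RT;
* low-frequency modes are treated fully harmonically (no quasi-RRHO damping);
* imaginary modes (negative wavenumbers) are an error unless explicitly dropped;
* default symmetry number σ = 1 (hydrogen-bonded clusters are asymmetric).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AMU, ATM_PA, ATOMIC_MASSES, CM1_TO_HARTREE, H_PLANCK, HARTREE_J, KB,
    KB_HARTREE,
)
from .io_structures import Structure

__all__ = [
    "FrequencySet",
    "ThermoRecord",
    "zero_point_energy",
    "rotational_constants",
    "rrho_thermo",
    "thermo_scan",
]


class FrequencyError(ValueError):
    """Invalid vibrational frequency input (imaginary mode, wrong count)."""


@dataclass
class FrequencySet:
    """Harmonic wavenumbers (cm⁻¹) with an optional global scale factor."""

    frequencies: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self):
        self.frequencies = np.atleast_1d(
            np.asarray(self.frequencies, dtype=float)
        )

    def validated(self, drop_imaginary: bool = False) -> "FrequencySet":
        """Return a copy with only real (positive) modes, or raise."""
        freqs = self.frequencies
        if np.any(freqs <= 0):
            if not drop_imaginary:
                raise FrequencyError(
                    f"{int(np.sum(freqs <= 0))} imaginary/zero frequencies present"
                )
            warnings.warn(
                f"dropping {int(np.sum(freqs <= 0))} imaginary/zero frequencies"
            )
            freqs = freqs[freqs > 0]
        return FrequencySet(freqs, self.scale_factor)

    @property
    def scaled(self) -> np.ndarray:
        return self.frequencies * self.scale_factor

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass
class ThermoRecord:
    """H, S, G and components for one structure at one (T, P)."""

    T: float            # K
    P: float            # atm
    E_elec: float       # hartree
    ZPE: float          # hartree
    H: float            # hartree
    S: float            # hartree/K
    G: float            # hartree
    sigma: int = 1
    label: str = ""
    phase: str = "gas"
    components: dict = field(default_factory=dict)


def zero_point_energy(f: FrequencySet, drop_imaginary: bool = False) -> float:
    """ZPE = ½ Σ h c ν̃ᵢ (scaled), in hartree; 0 for an atom (no modes)."""
    f = f.validated(drop_imaginary)
    if len(f) == 0:
        return 0.0
    return 0.5 * float(np.sum(f.scaled)) * CM1_TO_HARTREE


def _masses(s: Structure, masses=None) -> np.ndarray:
    if masses is not None:
        return np.asarray(masses, dtype=float)
    return np.array([ATOMIC_MASSES[el] for el in s.elements])


def rotational_constants(s: Structure, masses=None):
    """Principal rotational constants in GHz and a linearity flag.

    Returns ``(constants, kind)`` where *kind* is ``"atom"`` (no constants),
    ``"linear"`` (two equal constants) or ``"nonlinear"`` (A ≥ B ≥ C).
    """
    m = _masses(s, masses)
    if s.n_atoms == 1:
        return np.array([]), "atom"
    com = (s.coords * m[:, None]).sum(axis=0) / m.sum()
    x = (s.coords - com) * 1e-10                      # m
    mk = m * AMU
    inertia = np.zeros((3, 3))
    r2 = (x ** 2).sum(axis=1)
    inertia += np.diag([(mk * (r2 - x[:, i] ** 2)).sum() for i in range(3)])
    for i in range(3):
        for j in range(i + 1, 3):
            off = -(mk * x[:, i] * x[:, j]).sum()
            inertia[i, j] = inertia[j, i] = off
    moments = np.sort(np.linalg.eigvalsh(inertia))    # kg m², ascending
    tol = moments[-1] * 1e-8
    if moments[0] <= tol:                             # linear: I_a ≈ 0
        consts = H_PLANCK / (8 * math.pi ** 2 * moments[1:]) / 1e9
        return consts, "linear"
    consts = H_PLANCK / (8 * math.pi ** 2 * moments) / 1e9
    return np.sort(consts)[::-1], "nonlinear"         # A ≥ B ≥ C, GHz


def _vibrational_terms(freqs_cm1: np.ndarray, T: float):
    """Thermal vibrational energy (excl. ZPE) and entropy, hartree(/K)."""
    if len(freqs_cm1) == 0:
        return 0.0, 0.0
    theta = freqs_cm1 * CM1_TO_HARTREE / KB_HARTREE   # K
    x = theta / T
    # guard against overflow for very stiff modes
    expm1 = np.expm1(np.minimum(x, 500.0))
    e_therm = KB_HARTREE * np.sum(theta / expm1)
    s_vib = KB_HARTREE * np.sum(x / expm1 - np.log1p(-np.exp(-np.minimum(x, 500.0))))
    return float(e_therm), float(s_vib)


def rrho_thermo(s: Structure, f: FrequencySet, T: float = 298.15,
                P: float = 1.0, sigma: int = 1, masses=None,
                drop_imaginary: bool = False) -> ThermoRecord:
    """Full RRHO thermochemistry of one structure at (T, P).

    The frequency count must equal 3N−6 (nonlinear), 3N−5 (linear) or 0
    (single atom).  Requires ``s.energy_elec``.
    """
    if s.energy_elec is None:
        raise ValueError(f"structure {s.label!r} has no electronic energy")
    if T <= 0 or P <= 0 or sigma < 1:
        raise ValueError("require T > 0, P > 0, sigma >= 1")
    f = f.validated(drop_imaginary)
    consts_ghz, kind = rotational_constants(s, masses)
    expected = {"atom": 0, "linear": 3 * s.n_atoms - 5,
                "nonlinear": 3 * s.n_atoms - 6}[kind]
    if len(f) != expected:
        raise FrequencyError(
            f"{s.label or 'structure'}: {len(f)} modes given, "
            f"{expected} expected for a {kind} species with {s.n_atoms} atoms"
        )

    kT = KB_HARTREE * T
    m_total = _masses(s, masses).sum() * AMU
    p_pa = P * ATM_PA

    # translation (ideal gas, Sackur–Tetrode)
    q_trans = (2 * math.pi * m_total * KB * T / H_PLANCK ** 2) ** 1.5 \
        * (KB * T / p_pa)
    s_trans = KB_HARTREE * (math.log(q_trans) + 2.5)
    e_trans = 1.5 * kT

    # rotation (classical rigid rotor)
    if kind == "atom":
        s_rot, e_rot = 0.0, 0.0
    else:
        theta_rot = consts_ghz * 1e9 * H_PLANCK / KB   # K
        if kind == "linear":
            q_rot = T / (sigma * theta_rot[0])
            s_rot = KB_HARTREE * (math.log(q_rot) + 1.0)
            e_rot = kT
        else:
            q_rot = math.sqrt(math.pi) / sigma \
                * math.sqrt(T ** 3 / np.prod(theta_rot))
            s_rot = KB_HARTREE * (math.log(q_rot) + 1.5)
            e_rot = 1.5 * kT

    zpe = 0.5 * float(np.sum(f.scaled)) * CM1_TO_HARTREE if len(f) else 0.0
    e_vib, s_vib = _vibrational_terms(f.scaled, T)

    s_total = s_trans + s_rot + s_vib
    enthalpy = s.energy_elec + zpe + e_trans + e_rot + e_vib + kT
    gibbs = enthalpy - T * s_total
    return ThermoRecord(
        T=T, P=P, E_elec=s.energy_elec, ZPE=zpe, H=enthalpy, S=s_total,
        G=gibbs, sigma=sigma, label=s.label, phase=s.phase,
        components={
            "S_trans": s_trans, "S_rot": s_rot, "S_vib": s_vib,
            "E_trans": e_trans, "E_rot": e_rot, "E_vib_thermal": e_vib,
            "kind": kind,
        },
    )


def thermo_scan(s: Structure, f: FrequencySet, T_grid, P: float = 1.0,
                sigma: int = 1, masses=None,
                drop_imaginary: bool = False) -> list[ThermoRecord]:
    """RRHO records over a strictly increasing temperature grid."""
    T_grid = np.asarray(T_grid, dtype=float)
    if np.any(T_grid <= 0) or np.any(np.diff(T_grid) <= 0):
        raise ValueError("T grid must be strictly increasing and positive")
    return [rrho_thermo(s, f, T=t, P=P, sigma=sigma, masses=masses,
                        drop_imaginary=drop_imaginary) for t in T_grid]
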