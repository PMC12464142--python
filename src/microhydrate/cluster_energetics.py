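"""Binding, incremental and relative energies of IMZ(H₂O)_n ladders.

Binding energy of the n-cluster:   ΔE_n = E_n − E(IMZ) − n·E(H₂O)
Incremental (stepwise) energy:     ΔE_n = E_n − E_{n−1} − E(H₂O)

with E_0 := E(IMZ), so the incremental energies telescope exactly to the
binding energy.  The same relations apply verbatim to enthalpies — the
``quantity`` tag only records which was supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    HARTREE_TO_KCALMOL, HARTREE_TO_KJMOL, KCALMOL_TO_HARTREE,
)

__all__ = [
    "EnergyLadder",
    "binding_energy",
    "incremental_energy",
    "relative_energies",
    "binding_profile",
    "incremental_profile",
]

_UNIT_FACTORS = {
    ("hartree", "kcal/mol"): HARTREE_TO_KCALMOL,
    ("hartree", "kJ/mol"): HARTREE_TO_KJMOL,
    ("kcal/mol", "hartree"): KCALMOL_TO_HARTREE,
    ("kcal/mol", "kJ/mol"): 4.184,
    ("kJ/mol", "hartree"): 1.0 / HARTREE_TO_KJMOL,
    ("kJ/mol", "kcal/mol"): 1.0 / 4.184,
}


def convert_units(x, src: str, dst: str):
    """Convert between hartree, kcal/mol and kJ/mol."""
    if src == dst:
        return x
    try:
        return x * _UNIT_FACTORS[(src, dst)]
    except KeyError:
        raise ValueError(f"no conversion {src!r} → {dst!r}")


@dataclass
class EnergyLadder:
    """Cluster-size-indexed total energies plus the two monomer references."""

    n_values: list[int]
    E_n: dict[int, float] = field(default_factory=dict)
    E_monomer_water: float = 0.0
    E_imidazole: float = 0.0
    quantity: str = "electronic"      # or "enthalpy"
    units: str = "hartree"

    def __post_init__(self):
        if len(set(self.n_values)) != len(self.n_values):
            raise ValueError("duplicate cluster sizes")
        self.n_values = sorted(self.n_values)
        missing = [n for n in self.n_values if n not in self.E_n]
        if missing:
            raise ValueError(f"sizes {missing} lack energies")

    def energy(self, n: int) -> float:
        """E_n, with E_0 defined as E(IMZ)."""
        if n == 0:
            return self.E_imidazole
        if n not in self.E_n:
            raise KeyError(f"no energy for cluster size n={n}")
        return self.E_n[n]


def binding_energy(ladder: EnergyLadder, n: int) -> float:
    """ΔE_n = E_n − E(IMZ) − n·E(H₂O); negative for a bound cluster."""
    return ladder.energy(n) - ladder.E_imidazole - n * ladder.E_monomer_water


def incremental_energy(ladder: EnergyLadder, n: int) -> float:
    """ΔE_n = E_n − E_{n−1} − E(H₂O), the cost of adding the n-th water.

    Identically equal to binding(n) − binding(n−1); n = 1 uses E_0 = E(IMZ).
    """
    if n < 1:
        raise ValueError("incremental energy defined for n >= 1")
    return ladder.energy(n) - ladder.energy(n - 1) - ladder.E_monomer_water


def binding_profile(ladder: EnergyLadder) -> dict[int, float]:
    return {n: binding_energy(ladder, n) for n in ladder.n_values}


def incremental_profile(ladder: EnergyLadder) -> dict[int, float]:
    """Incremental energies for every size whose predecessor is available."""
    out = {}
    for n in ladder.n_values:
        if n == 1 or (n - 1) in ladder.E_n:
            out[n] = incremental_energy(ladder, n)
    return out


def relative_energies(members, units: str | None = None,
                      src_units: str = "hartree") -> np.ndarray:
    """Offsets from the minimum, order preserved (min maps to 0).

    With ``units`` set, offsets are converted from ``src_units``.
    """
    e = np.asarray(members, dtype=float)
    if e.size == 0:
        raise ValueError("no members")
    rel = e - e.min()
    if units is not None:
        rel = convert_units(rel, src_units, units)
    return rel
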