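"""Boltzmann-weighted conformer ensembles of IMZ(H₂O)_n structures.

Populations of the located structures of one cluster size follow
wᵢ ∝ exp(−(Gᵢ − G_min)/kT).  Weighting uses the Gibbs free energy at the
evaluation temperature (an electronic-energy variant is available through
the ``energies`` argument since the weights only ever see a 1-D array).
T = 0 is handled as the limit: all probability on the minimum, degenerate
minima (within 1e-10 hartree) split equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB_HARTREE
from .io_structures import Structure
from .thermochem import ThermoRecord

DEGENERACY_TOL = 1e-10      # hartree
POPULATION_THRESHOLD = 0.05

__all__ = [
    "ClusterEnsemble",
    "boltzmann_weights",
    "population_vs_temperature",
    "ensemble_average",
]


def boltzmann_weights(G_values, T: float) -> np.ndarray:
    """Normalized Boltzmann probabilities from free energies (hartree).

    Shifts by the minimum before exponentiating for numerical stability.
    ``T == 0`` returns the zero-temperature limit (equal split among
    degenerate minima).
    """
    g = np.asarray(G_values, dtype=float)
    if g.size == 0:
        raise ValueError("empty free-energy input")
    if T < 0:
        raise ValueError("temperature must be non-negative")
    if T == 0:
        w = (g <= g.min() + DEGENERACY_TOL).astype(float)
        return w / w.sum()
    x = np.exp(-(g - g.min()) / (KB_HARTREE * T))
    return x / x.sum()


def ensemble_average(values, weights) -> float:
    """Σ wᵢ xᵢ with normalized weights (the ensemble ⟨H⟩/⟨G⟩ estimator)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights differ in length")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights are not normalized")
    return float(np.dot(v, w))


@dataclass
class ClusterEnsemble:
    """All located structures of one cluster size with thermochemistry."""

    n: int
    members: list[tuple[Structure, ThermoRecord]]
    T_ref: float = 298.15
    weights: np.ndarray = field(default=None)

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        phases = {s.phase for s, _ in self.members}
        if len(phases) > 1:
            raise ValueError(f"mixed phase tags in ensemble: {phases}")
        temps = {round(t.T, 9) for _, t in self.members}
        if len(temps) > 1:
            raise ValueError("members evaluated at different temperatures")
        if self.weights is None:
            self.weights = boltzmann_weights(
                [t.G for _, t in self.members], self.T_ref
            )
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12 or np.any(self.weights < 0):
            raise ValueError("weights must be a probability vector")

    @property
    def phase(self) -> str:
        return self.members[0][0].phase

    @property
    def labels(self) -> list[str]:
        return [s.label for s, _ in self.members]

    @property
    def G_values(self) -> np.ndarray:
        return np.array([t.G for _, t in self.members])

    @property
    def H_values(self) -> np.ndarray:
        return np.array([t.H for _, t in self.members])

    def avg_H(self) -> float:
        """Boltzmann-weighted ⟨H⟩ (hartree)."""
        return ensemble_average(self.H_values, self.weights)

    def avg_G(self, partition_function: bool = False) -> float:
        """⟨G⟩ as the weighted average; optionally −kT ln Σ exp(−Gᵢ/kT).

        The weighted average is the default estimator; the partition-function
        form (always ≤ the average, by the Gibbs inequality) is provided for
        comparison.
        """
        if partition_function:
            g = self.G_values
            kt = KB_HARTREE * self.T_ref
            gmin = g.min()
            return float(gmin - kt * np.log(np.sum(np.exp(-(g - gmin) / kt))))
        return ensemble_average(self.G_values, self.weights)


def population_vs_temperature(ensemble: ClusterEnsemble, T_grid,
                              threshold: float = POPULATION_THRESHOLD,
                              g_of_T=None):
    """Per-member population curves over a temperature grid.

    ``g_of_T`` may map a temperature to the members' free energies
    (hartree); by default the members' fixed G values are used at every
    temperature (relative free energies taken as temperature-independent).

    Returns ``(curves, reported)``: *curves* is an (n_T × n_member) array,
    *reported* the member indices whose population exceeds *threshold* at
    any grid point (the conventional 5 % reporting cut by default).
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if np.any(T_grid < 0):
        raise ValueError("temperatures must be non-negative")
    g_fixed = ensemble.G_values
    curves = np.empty((len(T_grid), len(ensemble.members)))
    for i, t in enumerate(T_grid):
        g = np.asarray(g_of_T(t)) if g_of_T is not None else g_fixed
        curves[i] = boltzmann_weights(g, t)
    reported = [j for j in range(curves.shape[1])
                if np.any(curves[:, j] > threshold)]
    return curves, reported
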