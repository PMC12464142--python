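"""Cluster-continuum hydration enthalpy and free energy of imidazole.

The hydration quantities are reaction thermodynamics of

    IMZ(gas) + (H₂O)_n(aq)  →  IMZ(H₂O)_n(aq)

so that, per cluster size n,

    ΔH_solv(n) = H[IMZ(H₂O)_n]_water − H[(H₂O)_n]_water − H[IMZ]_gas
    ΔG_solv(n) = G[IMZ(H₂O)_n]_water − G[(H₂O)_n]_water − G[IMZ]_gas

with the solvated-species H/G being Boltzmann-weighted ensemble averages.
The profiles converge in n; the headline estimates are plain averages over
a stable window ("variation" = max − min over the window), by default
n = 5–7 for the enthalpy and n = 3–7 for the free energy.  Outputs are in
kJ/mol (the customary hydration unit), inputs in hartree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .constants import HARTREE_TO_KJMOL

__all__ = [
    "SpeciesThermo",
    "HydrationProfile",
    "hydration_deltas",
    "build_profile",
    "convergence_profile",
    "stable_range_average",
    "suggest_stable_range",
    "temperature_scan",
]

DEFAULT_RANGE_H = (5, 7)
DEFAULT_RANGE_G = (3, 7)
PLATEAU_TOL_KJ = 2.5


@dataclass
class SpeciesThermo:
    """Ensemble-averaged ⟨H⟩/⟨G⟩ (hartree) of one species at one T."""

    H: float
    G: float
    T: float
    phase: str
    n: int = 0


def hydration_deltas(imz_water: SpeciesThermo, water_n: SpeciesThermo,
                     imz_gas: SpeciesThermo) -> tuple[float, float]:
    """(ΔH, ΔG) of the hydration reaction at one n, in kJ/mol.

    Requires matching temperatures and the conventional phase tags
    (solvated complex and water cluster, gas-phase solute).
    """
    if imz_water.phase != "solvent" or water_n.phase != "solvent":
        raise ValueError("complex and water cluster must be phase='solvent'")
    if imz_gas.phase != "gas":
        raise ValueError("isolated imidazole must be phase='gas'")
    temps = {round(x.T, 6) for x in (imz_water, water_n, imz_gas)}
    if len(temps) > 1:
        raise ValueError(f"temperature mismatch across species: {sorted(temps)}")
    dh = (imz_water.H - water_n.H - imz_gas.H) * HARTREE_TO_KJMOL
    dg = (imz_water.G - water_n.G - imz_gas.G) * HARTREE_TO_KJMOL
    return dh, dg


@dataclass
class HydrationProfile:
    """ΔH_solv(n) and ΔG_solv(n) (kJ/mol) at one temperature."""

    n_values: list[int]
    dH: np.ndarray
    dG: np.ndarray
    T: float
    stable_range_H: tuple[int, int] = DEFAULT_RANGE_H
    stable_range_G: tuple[int, int] = DEFAULT_RANGE_G

    def __post_init__(self):
        self.dH = np.asarray(self.dH, dtype=float)
        self.dG = np.asarray(self.dG, dtype=float)
        order = np.argsort(self.n_values)
        self.n_values = [int(self.n_values[i]) for i in order]
        self.dH = self.dH[order]
        self.dG = self.dG[order]

    def _window(self, values, lo: int, hi: int) -> np.ndarray:
        idx = [i for i, n in enumerate(self.n_values) if lo <= n <= hi]
        if not idx:
            raise ValueError(f"range n={lo}..{hi} outside available sizes")
        return values[idx]

    def estimates(self) -> tuple[float, float]:
        """(ΔH_hyd, ΔG_hyd): stable-range averages, kJ/mol."""
        return stable_range_average(self, self.stable_range_H,
                                    self.stable_range_G)


def clamp_range(rng: tuple[int, int], n_values) -> tuple[int, int]:
    """Clip an inclusive n-window to the available sizes."""
    n_max = max(n_values)
    lo, hi = min(rng[0], n_max), min(rng[1], n_max)
    return (min(lo, hi), hi)


def build_profile(per_n: dict[int, tuple[float, float]], T: float,
                  **kw) -> HydrationProfile:
    """Profile from a {n: (ΔH, ΔG) kJ/mol} mapping.

    The default stable windows are clipped to the available sizes.
    """
    ns = sorted(per_n)
    kw.setdefault("stable_range_H", clamp_range(DEFAULT_RANGE_H, ns))
    kw.setdefault("stable_range_G", clamp_range(DEFAULT_RANGE_G, ns))
    return HydrationProfile(ns, [per_n[n][0] for n in ns],
                            [per_n[n][1] for n in ns], T, **kw)


def _variation(values: np.ndarray) -> float:
    if values.size == 0:
        raise ValueError("empty window")
    return float(values.max() - values.min())


def convergence_profile(profile: HydrationProfile,
                        windows=((5, 7), (3, 7))) -> dict:
    """Overall and per-window max−min variation of ΔH and ΔG (kJ/mol)."""
    if len(profile.n_values) < 2:
        raise ValueError("need at least two sizes to assess convergence")
    out = {
        "dH_overall": _variation(profile.dH),
        "dG_overall": _variation(profile.dG),
    }
    for lo, hi in windows:
        try:
            out[f"dH_{lo}_{hi}"] = _variation(profile._window(profile.dH, lo, hi))
            out[f"dG_{lo}_{hi}"] = _variation(profile._window(profile.dG, lo, hi))
        except ValueError:
            pass
    return out


def stable_range_average(profile: HydrationProfile,
                         range_H: tuple[int, int] = DEFAULT_RANGE_H,
                         range_G: tuple[int, int] = DEFAULT_RANGE_G
                         ) -> tuple[float, float]:
    """Arithmetic means of ΔH over range_H and ΔG over range_G (inclusive)."""
    dh = float(profile._window(profile.dH, *range_H).mean())
    dg = float(profile._window(profile.dG, *range_G).mean())
    return dh, dg


def suggest_stable_range(n_values, values,
                         tol: float = PLATEAU_TOL_KJ) -> tuple[int, int]:
    """Largest trailing window whose max−min variation stays below *tol*.

    Grows the window backwards from the largest n; a single trailing point
    is returned if even the last two sizes differ by more than *tol*.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty profile")
    start = len(values) - 1
    for i in range(len(values) - 2, -1, -1):
        if _variation(values[i:]) <= tol:
            start = i
        else:
            break
    return int(n_values[start]), int(n_values[-1])


def temperature_scan(profiles: list[HydrationProfile]) -> dict:
    """Hydration estimates across a temperature grid.

    Returns the per-T (ΔH_hyd, ΔG_hyd) arrays, the linear-fit slope and
    intercept of ΔG_hyd(T) (slope ≈ −ΔS_hyd), and — if ΔG_hyd changes sign
    on the grid — the bracketing temperatures of the crossing.
    """
    if not profiles:
        raise ValueError("no profiles")
    profiles = sorted(profiles, key=lambda p: p.T)
    T = np.array([p.T for p in profiles])
    est = np.array([p.estimates() for p in profiles])
    dh, dg = est[:, 0], est[:, 1]
    fit = _stats.linregress(T, dg)
    crossing = None
    sign = np.sign(dg)
    for i in range(len(T) - 1):
        if sign[i] != sign[i + 1] and sign[i] != 0:
            crossing = (float(T[i]), float(T[i + 1]))
            break
    out = {
        "T": T, "dH": dh, "dG": dg,
        "dG_slope": float(fit.slope),            # kJ/mol/K ≈ −ΔS_hyd
        "dG_intercept": float(fit.intercept),    # kJ/mol ≈ ΔH_hyd
        "dG_r2": float(fit.rvalue ** 2),
        "dG_sign_change": crossing,
    }
    if crossing is not None:
        t0, t1 = crossing
        g0 = dg[np.where(T == t0)[0][0]]
        g1 = dg[np.where(T == t1)[0][0]]
        out["dG_zero_T"] = float(t0 - g0 * (t1 - t0) / (g1 - g0))
    return out
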