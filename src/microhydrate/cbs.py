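"""Two-point complete-basis-set (CBS) extrapolation.

The SCF and correlation parts of the energy converge differently with the
basis-set cardinal number X (aug-cc-pVXZ: D→2, T→3, Q→4, 5→5) and are
extrapolated separately from two single-point energies at cardinals N < M:

SCF (exponential form):

    E_SCF(∞) = [E_SCF(M)·e^(−α√N) − E_SCF(N)·e^(−α√M)] / [e^(−α√N) − e^(−α√M)]

correlation (inverse-power form):

    E_corr(∞) = [E_corr(N)·N^β − E_corr(M)·M^β] / (N^β − M^β)

The default parameters α = 5.79 and β = 3.05 are tied to the
(N, M) = (3, 4) pair, i.e. the aug-cc-pVTZ/aug-cc-pVQZ combination; other
pairs require explicitly supplied parameters.  Both formulas are affine in
the energies, so extrapolating a·E + b gives a·E(∞) + b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CbsInput", "extrapolate_scf", "extrapolate_corr", "cbs_total",
           "cardinal_number", "ALPHA_DEFAULT", "BETA_DEFAULT"]

ALPHA_DEFAULT = 5.79
BETA_DEFAULT = 3.05

_CARDINALS = {"d": 2, "t": 3, "q": 4, "5": 5, "6": 6}


def cardinal_number(basis) -> int:
    """Map a correlation-consistent basis name (or int) to its cardinal.

    Accepts e.g. ``aug-cc-pVTZ``, ``cc-pvqz``, ``aVTZ``, ``TZ`` or a plain
    integer ≥ 2.
    """
    if isinstance(basis, int):
        if basis < 2:
            raise ValueError("cardinal number must be >= 2")
        return basis
    name = str(basis).lower().replace("-", "").replace("_", "")
    for prefix in ("augccpv", "ccpv", "av", "v", ""):
        if name.startswith(prefix) and name.endswith("z"):
            core = name[len(prefix):-1]
            if core in _CARDINALS:
                return _CARDINALS[core]
    raise ValueError(f"unrecognized basis set {basis!r}")


@dataclass
class CbsInput:
    """Energies (hartree) at two cardinals plus extrapolation parameters."""

    E_scf_N: float
    E_scf_M: float
    E_corr_N: float
    E_corr_M: float
    N: int = 3
    M: int = 4
    alpha: float = ALPHA_DEFAULT
    beta: float = BETA_DEFAULT

    def __post_init__(self):
        self.N = cardinal_number(self.N)
        self.M = cardinal_number(self.M)
        if self.M <= self.N:
            raise ValueError(f"require M > N, got N={self.N} M={self.M}")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if (self.N, self.M) != (3, 4) and (self.alpha, self.beta) == (
                ALPHA_DEFAULT, BETA_DEFAULT):
            raise ValueError(
                "default alpha/beta are calibrated for (N, M) = (3, 4); "
                "supply alpha and beta explicitly for other pairs"
            )


def extrapolate_scf(c: CbsInput) -> float:
    """SCF CBS limit via the two-point exponential formula."""
    wn = math.exp(-c.alpha * math.sqrt(c.N))
    wm = math.exp(-c.alpha * math.sqrt(c.M))
    return (c.E_scf_M * wn - c.E_scf_N * wm) / (wn - wm)


def extrapolate_corr(c: CbsInput) -> float:
    """Correlation CBS limit via the two-point inverse-power formula."""
    pn = c.N ** c.beta
    pm = c.M ** c.beta
    return (c.E_corr_N * pn - c.E_corr_M * pm) / (pn - pm)


def cbs_total(c: CbsInput) -> float:
    """E(∞) = E_SCF(∞) + E_corr(∞)."""
    return extrapolate_scf(c) + extrapolate_corr(c)
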