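"""Cluster geometry I/O, fragment perception and imidazole atom roles.

Structures are plain element/coordinate records read from (multi-record)
XYZ files.  The comment line may carry ``key=value`` tokens — ``label``,
``energy`` (hartree) and ``phase`` (``gas``/``solvent``) are recognised,
anything else is ignored — so files remain valid plain XYZ.

Fragments are connected components of a covalent bond graph (bond iff the
interatomic distance is below ``scale`` × the sum of covalent radii).  A
fragment with formula H2O is a water molecule; C3H4N2 is imidazole, whose
ring nitrogens are then distinguished as N1 (bears the ring H, hydrogen-bond
donor) and N3 (pyridine-type lone pair, acceptor).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .constants import COVALENT_RADII, KNOWN_ELEMENTS

DEFAULT_BOND_SCALE = 1.2

__all__ = [
    "Structure",
    "FragmentAssignment",
    "ImidazoleRoles",
    "XYZParseError",
    "RoleError",
    "read_xyz",
    "write_xyz",
    "perceive_fragments",
    "label_imidazole",
]


class XYZParseError(ValueError):
    """Raised for malformed XYZ input; message names record and line."""


class RoleError(ValueError):
    """Raised when imidazole donor/acceptor roles cannot be assigned."""


@dataclass
class Structure:
    """One molecular geometry with optional electronic energy and phase tag."""

    elements: list[str]
    coords: np.ndarray                  # (N, 3) Å
    label: str = ""
    energy_elec: float | None = None    # hartree
    phase: str = "gas"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError(
                f"{len(self.elements)} elements but {len(self.coords)} coordinates"
            )
        if self.energy_elec is not None and not np.isfinite(self.energy_elec):
            raise ValueError("electronic energy must be finite when present")
        if self.phase not in ("gas", "solvent"):
            raise ValueError(f"unknown phase tag {self.phase!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def size_n(self) -> int:
        """Number of water molecules (perceived on demand)."""
        frags = perceive_fragments(self)
        return sum(1 for f in frags.fragment_formulas if f == "H2O")

    def with_energy(self, energy: float) -> "Structure":
        return replace(self, coords=self.coords.copy(), energy_elec=float(energy))


@dataclass
class FragmentAssignment:
    """Partition of the atoms into covalently bonded fragments."""

    fragment_ids: np.ndarray            # int per atom, contiguous from 0
    fragment_formulas: list[str]        # Hill formula per fragment
    bonds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_formulas)

    @property
    def imidazole_fragment(self) -> int | None:
        try:
            return self.fragment_formulas.index("C3H4N2")
        except ValueError:
            return None

    def atoms_of(self, fragment: int) -> np.ndarray:
        return np.nonzero(self.fragment_ids == fragment)[0]


@dataclass
class ImidazoleRoles:
    """Indices of the chemically distinct imidazole atoms and the ring plane."""

    N1: int
    N3: int
    C2: int
    C4: int
    C5: int
    H_N1: int
    ring_plane_normal: np.ndarray       # unit 3-vector
    ring_centroid: np.ndarray


def _hill_formula(symbols) -> str:
    counts = Counter(symbols)
    parts = []
    for el in ["C", "H"] + sorted(set(counts) - {"C", "H"}):
        if el in counts:
            n = counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
    if "C" not in counts:  # Hill: no carbon → fully alphabetical
        parts = [
            el + (str(counts[el]) if counts[el] > 1 else "")
            for el in sorted(counts)
        ]
    return "".join(parts)


def read_xyz(path) -> list[Structure]:
    """Parse a (multi-record) XYZ file into a list of :class:`Structure`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    structures: list[Structure] = []
    i = 0
    record = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        record += 1
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"record {record}, line {i + 1}: expected atom count, got {lines[i]!r}"
            )
        if natoms < 0 or i + 2 + natoms > len(lines):
            raise XYZParseError(
                f"record {record}: truncated (needs {natoms} atom lines)"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        label, energy, phase = f"record{record}", None, "gas"
        for tok in comment.split():
            if "=" not in tok:
                continue
            key, _, val = tok.partition("=")
            if key == "label":
                label = val
            elif key == "energy":
                try:
                    energy = float(val)
                except ValueError:
                    raise XYZParseError(
                        f"record {record}, line {i + 2}: bad energy {val!r}"
                    )
            elif key == "phase":
                if val not in ("gas", "solvent"):
                    raise XYZParseError(
                        f"record {record}, line {i + 2}: bad phase {val!r}"
                    )
                phase = val
        elements, coords = [], []
        for j in range(natoms):
            ln = i + 2 + j
            fields = lines[ln].split()
            if len(fields) < 4:
                raise XYZParseError(
                    f"record {record}, line {ln + 1}: expected 'El x y z'"
                )
            el = fields[0]
            if el not in KNOWN_ELEMENTS:
                raise XYZParseError(
                    f"record {record}, line {ln + 1}: unknown element {el!r}"
                )
            try:
                xyz = [float(v) for v in fields[1:4]]
            except ValueError:
                raise XYZParseError(
                    f"record {record}, line {ln + 1}: non-numeric coordinate"
                )
            elements.append(el)
            coords.append(xyz)
        structures.append(
            Structure(elements, np.array(coords).reshape(-1, 3), label=label,
                      energy_elec=energy, phase=phase)
        )
        i += 2 + natoms
    return structures


def write_xyz(structures, path) -> None:
    """Write structures as multi-record XYZ (inverse of :func:`read_xyz`)."""
    with open(path, "w") as fh:
        for s in structures:
            tokens = [f"label={s.label or 'unnamed'}"]
            if s.energy_elec is not None:
                tokens.append(f"energy={s.energy_elec!r}")
            tokens.append(f"phase={s.phase}")
            fh.write(f"{s.n_atoms}\n{' '.join(tokens)}\n")
            for el, (x, y, z) in zip(s.elements, s.coords):
                fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


def bond_graph(s: Structure, scale: float = DEFAULT_BOND_SCALE) -> nx.Graph:
    """Covalent bond graph: edge iff d(i,j) ≤ scale·(r_i + r_j)."""
    if scale <= 0:
        raise ValueError("bond scale must be positive")
    g = nx.Graph()
    g.add_nodes_from(range(s.n_atoms))
    if s.n_atoms < 2:
        return g
    radii = np.array([COVALENT_RADII[el] for el in s.elements])
    dmat = squareform(pdist(s.coords))
    cutoff = scale * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero(np.triu(dmat <= cutoff, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def perceive_fragments(s: Structure, scale: float = DEFAULT_BOND_SCALE) -> FragmentAssignment:
    """Partition atoms into connected fragments of the bond graph.

    Fragment ids are contiguous from 0, ordered by each fragment's lowest
    atom index, so the result is deterministic and permutation-consistent.
    """
    g = bond_graph(s, scale)
    comps = sorted((sorted(c) for c in nx.connected_components(g)),
                   key=lambda c: c[0])
    ids = np.empty(s.n_atoms, dtype=int)
    formulas = []
    for k, comp in enumerate(comps):
        ids[comp] = k
        formulas.append(_hill_formula(s.elements[a] for a in comp))
    return FragmentAssignment(ids, formulas, bonds=list(g.edges))


def _best_fit_plane_normal(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    n = vt[-1]
    return n / np.linalg.norm(n)


def label_imidazole(s: Structure, f: FragmentAssignment | None = None,
                    scale: float = DEFAULT_BOND_SCALE) -> ImidazoleRoles:
    """Assign N1/N3/C2/C4/C5 roles within the imidazole fragment.

    N1 is the ring nitrogen bearing exactly one hydrogen (the donor site);
    N3 is the bare ring nitrogen (the acceptor site); C2 bridges the two
    nitrogens.  Raises :class:`RoleError` for imidazolide/imidazolium-like
    protonation states (zero or two NH).
    """
    if f is None:
        f = perceive_fragments(s, scale)
    frag = f.imidazole_fragment
    if frag is None:
        raise RoleError("no C3H4N2 fragment found")
    atoms = set(f.atoms_of(frag).tolist())
    g = bond_graph(s, scale)
    nitrogens = [a for a in atoms if s.elements[a] == "N"]
    carbons = [a for a in atoms if s.elements[a] == "C"]
    n_with_h = {
        a: [b for b in g.neighbors(a) if s.elements[b] == "H"] for a in nitrogens
    }
    donors = [a for a in nitrogens if len(n_with_h[a]) == 1]
    bare = [a for a in nitrogens if len(n_with_h[a]) == 0]
    if len(donors) != 1 or len(bare) != 1:
        raise RoleError(
            f"expected exactly one NH and one bare ring nitrogen, "
            f"found {len(donors)} NH / {len(bare)} bare"
        )
    n1, n3 = donors[0], bare[0]
    c2 = [c for c in carbons if g.has_edge(c, n1) and g.has_edge(c, n3)]
    if len(c2) != 1:
        raise RoleError("no unique C2 bridging N1 and N3")
    c2 = c2[0]
    c5 = [c for c in carbons if c != c2 and g.has_edge(c, n1)]
    c4 = [c for c in carbons if c != c2 and g.has_edge(c, n3)]
    if len(c4) != 1 or len(c5) != 1:
        raise RoleError("ring connectivity is not imidazole-like")
    ring = np.array([n1, c2, n3, c4[0], c5[0]])
    pts = s.coords[ring]
    return ImidazoleRoles(
        N1=n1, N3=n3, C2=c2, C4=c4[0], C5=c5[0],
        H_N1=n_with_h[n1][0],
        ring_plane_normal=_best_fit_plane_normal(pts),
        ring_centroid=pts.mean(axis=0),
    )
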