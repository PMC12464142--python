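"""Geometric detection and typing of imidazole–water non-covalent contacts.

A donor–H···acceptor triple counts as a contact when the H···acceptor
distance is below the cutoff (2.6 Å for O/N acceptors, 3.0 Å for the ring
centroid) and the D–H···A angle is at least 120° — standard crystallographic
practice.  Contacts are typed by the chemical identity of donor and
acceptor:

* ``OH...N3``  — water donating into the imidazole acceptor nitrogen,
* ``N1H...O``  — the imidazole N1–H donating to a water oxygen,
* ``CH...O``   — weak ring C–H donation to a water oxygen,
* ``OH...pi``  — water O–H pointing at the aromatic ring face (centroid
  acceptor),
* ``OH...O``   — water–water hydrogen bonds.

Only inter-fragment triples are considered.  The out-of-plane angle of an
N3-ward donor water (angle between the N3→O vector and the ring plane;
0° = in-plane) quantifies the experimentally observed non-planar approach.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io_structures import (
    DEFAULT_BOND_SCALE, FragmentAssignment, ImidazoleRoles, Structure,
    bond_graph, perceive_fragments,
)

__all__ = [
    "ContactCriteria",
    "Contact",
    "ContactReport",
    "detect_contacts",
    "out_of_plane_angle",
    "census_summary",
]


@dataclass
class ContactCriteria:
    """Distance/angle cutoffs for geometric hydrogen-bond assignment."""

    d_HA_max: float = 2.6          # Å, O/N acceptors
    d_Hpi_max: float = 3.0         # Å, H···ring-centroid
    angle_DHA_min: float = 120.0   # degrees
    pi_centroid: bool = True

    def __post_init__(self):
        if self.d_HA_max <= 0 or self.d_Hpi_max <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 < self.angle_DHA_min <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")


@dataclass
class Contact:
    donor: int                     # heavy donor atom index
    hydrogen: int
    acceptor: int | None           # atom index, None for the ring centroid
    kind: str
    d_HA: float                    # Å
    angle_DHA: float               # degrees


@dataclass
class ContactReport:
    contacts: list[Contact]
    census: Counter = field(default_factory=Counter)
    out_of_plane: dict[int, float] = field(default_factory=dict)  # O index → deg

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def out_of_plane_angle(roles: ImidazoleRoles, oxygen_coord: np.ndarray,
                       coords_N3: np.ndarray | None = None,
                       structure: Structure | None = None) -> float:
    """Angle (deg, 0–90) between the N3→O vector and the ring plane."""
    if coords_N3 is None:
        if structure is None:
            raise ValueError("need the N3 coordinate or the structure")
        coords_N3 = structure.coords[roles.N3]
    v = np.asarray(oxygen_coord, dtype=float) - coords_N3
    v = v / np.linalg.norm(v)
    return float(np.degrees(np.arcsin(abs(np.dot(v, roles.ring_plane_normal)))))


def detect_contacts(s: Structure, roles: ImidazoleRoles | None = None,
                    f: FragmentAssignment | None = None,
                    criteria: ContactCriteria | None = None,
                    bond_scale: float = DEFAULT_BOND_SCALE) -> ContactReport:
    """Enumerate and type all inter-fragment D–H···A contacts.

    ``roles`` may be None for water-only systems (no imidazole typing).
    """
    criteria = criteria or ContactCriteria()
    if f is None:
        f = perceive_fragments(s, bond_scale)
    g = bond_graph(s, bond_scale)
    frag = f.fragment_ids

    # donors: every H bonded to N or O; plus ring C–H of imidazole
    dh_pairs = []
    for h in range(s.n_atoms):
        if s.elements[h] != "H":
            continue
        for d in g.neighbors(h):
            if s.elements[d] in ("N", "O", "C"):
                dh_pairs.append((d, h))

    acceptors = [a for a in range(s.n_atoms) if s.elements[a] == "O"]
    if roles is not None:
        acceptors.append(roles.N3)
    ring_carbons = set()
    if roles is not None:
        ring_carbons = {roles.C2, roles.C4, roles.C5}

    contacts: list[Contact] = []
    census: Counter = Counter()
    out_of_plane: dict[int, float] = {}

    for d, h in dh_pairs:
        el_d = s.elements[d]
        for a in acceptors:
            if a == d or frag[a] == frag[d]:
                continue
            d_ha = float(np.linalg.norm(s.coords[h] - s.coords[a]))
            if d_ha > criteria.d_HA_max:
                continue
            ang = _angle_deg(s.coords[d], s.coords[h], s.coords[a])
            if ang < criteria.angle_DHA_min:
                continue
            kind = None
            if roles is not None and a == roles.N3 and el_d == "O":
                kind = "OH...N3"
                census["N3_accepted"] += 1
                out_of_plane[d] = out_of_plane_angle(
                    roles, s.coords[d], coords_N3=s.coords[roles.N3])
            elif roles is not None and d == roles.N1 and s.elements[a] == "O":
                kind = "N1H...O"
                census["N1H_donated"] += 1
            elif el_d == "C" and s.elements[a] == "O":
                if roles is not None and d not in ring_carbons:
                    continue
                kind = "CH...O"
                census["CH_O"] += 1
            elif el_d == "O" and s.elements[a] == "O":
                kind = "OH...O"
                census["OH_O"] += 1
            elif el_d == "N" and s.elements[a] == "O":
                kind = "NH...O"
                census["NH_O"] += 1
            elif el_d == "O" and s.elements[a] == "N":
                kind = "OH...N"
                census["OH_N"] += 1
            if kind:
                contacts.append(Contact(d, h, a, kind, d_ha, ang))

    # water O–H into the aromatic ring face; hydrogens already engaged in a
    # conventional sigma H-bond are not re-counted toward the centroid
    if roles is not None and criteria.pi_centroid:
        engaged = {c.hydrogen for c in contacts}
        cen = roles.ring_centroid
        imz_frag = frag[roles.N1]
        for d, h in dh_pairs:
            if s.elements[d] != "O" or frag[d] == imz_frag or h in engaged:
                continue
            d_ha = float(np.linalg.norm(s.coords[h] - cen))
            if d_ha > criteria.d_Hpi_max:
                continue
            ang = _angle_deg(s.coords[d], s.coords[h], cen)
            if ang < criteria.angle_DHA_min:
                continue
            contacts.append(Contact(d, h, None, "OH...pi", d_ha, ang))
            census["OH_pi"] += 1

    return ContactReport(contacts, census, out_of_plane)


def census_summary(reports: list[ContactReport]) -> dict:
    """Distribution and modal value of each census count over an ensemble."""
    if not reports:
        raise ValueError("no reports")
    keys = sorted({k for r in reports for k in r.census})
    out = {}
    for k in keys:
        counts = [r.census.get(k, 0) for r in reports]
        dist = Counter(counts)
        modal = max(dist.items(), key=lambda kv: (kv[1], kv[0]))[0]
        out[k] = {"distribution": dict(sorted(dist.items())), "modal": modal,
                  "mean": float(np.mean(counts))}
    return out
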