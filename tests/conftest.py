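"""Shared fixtures: hand-built reference geometries and synthetic studies."""

import numpy as np
import pytest

from microhydrate import synthetic_data as sd
from microhydrate.io_structures import Structure


@pytest.fixture
def water():
    return sd.water_structure()


@pytest.fixture
def imidazole():
    return sd.imidazole_structure()


@pytest.fixture
def water_dimer():
    """Linear O–H···O hydrogen bond, O···O 2.9 Å, D–H···A angle 180°.

    The acceptor's hydrogens point away from the donor (out of plane) so the
    fixture contains exactly one donor–H···acceptor triple by construction.
    """
    oh, half = 0.9572, np.radians(104.52 / 2)
    donor = np.array([
        [0.0, 0.0, 0.0],
        [oh, 0.0, 0.0],                                   # aimed at acceptor O
        [oh * np.cos(np.radians(104.52)),
         oh * np.sin(np.radians(104.52)), 0.0],
    ])
    o_a = np.array([2.9, 0.0, 0.0])
    acceptor = np.array([
        o_a,
        o_a + [oh * np.cos(half), 0.0, oh * np.sin(half)],
        o_a + [oh * np.cos(half), 0.0, -oh * np.sin(half)],
    ])
    return Structure(["O", "H", "H", "O", "H", "H"],
                     np.vstack([donor, acceptor]), label="W2_linear")


def place_water_donating_to(point, direction, d_HN=1.9):
    """A water with one O–H aimed at *point* from *direction* (unit vector),
    H at distance d_HN from the point."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    h_pos = point + direction * d_HN
    o_pos = point + direction * (d_HN + 0.9572)
    # second H roughly perpendicular
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(direction, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    h2 = o_pos + 0.9572 * (-direction * np.cos(np.radians(75.48))
                           + perp * np.sin(np.radians(75.48)))
    return np.array([o_pos, h_pos, h2]), ["O", "H", "H"]


@pytest.fixture
def water_on_n3(imidazole):
    """One water donating into N3 at H···N 1.9 Å, nearly collinear."""
    n3 = imidazole.coords[2]
    ring_out = n3 / np.linalg.norm(n3)         # radially outward, in plane
    w_coords, w_els = place_water_donating_to(n3, ring_out, 1.9)
    return Structure(imidazole.elements + w_els,
                     np.vstack([imidazole.coords, w_coords]),
                     label="IMZW1_n3")


@pytest.fixture
def imidazolium(imidazole):
    """Both ring nitrogens protonated (role assignment must fail)."""
    n3 = imidazole.coords[2]
    h_extra = n3 * (1 + 1.01 / np.linalg.norm(n3))
    return Structure(imidazole.elements + ["H"],
                     np.vstack([imidazole.coords, [h_extra]]),
                     label="IMZH+")


@pytest.fixture(scope="session")
def study_small():
    """Three-size synthetic study on a small sampler budget."""
    return sd.generate_study(n_max=3, seed=11, sampler_iterations=4,
                             pool_size=2)


@pytest.fixture(scope="session")
def study_full():
    """Eight-size study (full stable ranges) on a reduced sampler budget."""
    return sd.generate_study(n_max=8, seed=7, sampler_iterations=3,
                             pool_size=1)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=rng).as_matrix()
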