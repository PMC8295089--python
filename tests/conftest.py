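import numpy as np
import pytest

from eemcc import FrameSet, build_topology

WATER_OH = 0.9572
WATER_ANGLE = 104.52  # degrees


@pytest.fixture
def water_topology():
    return build_topology(
        elements=["O", "H", "H"],
        bonds=[(0, 1), (0, 2)],
        molecules_spec=[{"atoms": [0, 1, 2], "species": "water",
                         "sigma": 2.0}],
    )


@pytest.fixture
def water_coords():
    """One water molecule, C2 axis along +y, oxygen at the origin."""
    half = np.radians(WATER_ANGLE / 2.0)
    return np.array([
        [0.0, 0.0, 0.0],
        [WATER_OH * np.sin(half), WATER_OH * np.cos(half), 0.0],
        [-WATER_OH * np.sin(half), WATER_OH * np.cos(half), 0.0],
    ])


@pytest.fixture
def water_frames(water_coords):
    coords = water_coords[None] + 10.0   # away from the box edge
    forces = np.zeros_like(coords)
    return FrameSet(coords, forces, box=np.full((1, 3), 30.0))


@pytest.fixture
def butane_topology():
    """n-butane: 4 united atoms, one flexible dihedral (the central bond)."""
    elements = ["C", "H", "H", "H",      # C0 + 3H
                "C", "H", "H",           # C1 + 2H
                "C", "H", "H",           # C2 + 2H
                "C", "H", "H", "H"]      # C3 + 3H
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4),
             (4, 5), (4, 6), (4, 7),
             (7, 8), (7, 9), (7, 10),
             (10, 11), (10, 12), (10, 13)]
    return build_topology(elements, bonds,
                          [{"atoms": list(range(14)), "species": "solute"}])


@pytest.fixture
def butane_coords():
    """Rough anti-conformation butane geometry (Å)."""
    c = np.array([[0.0, 0.0, 0.0], [1.53, 0.0, 0.0],
                  [2.3, 1.33, 0.0], [3.83, 1.33, 0.0]])
    x = np.zeros((14, 3))
    x[0], x[4], x[7], x[10] = c
    # hydrogens: simple offsets off the carbon skeleton plane
    x[1] = c[0] + [-0.6, -0.6, 0.6]
    x[2] = c[0] + [-0.6, -0.3, -0.8]
    x[3] = c[0] + [0.2, -0.9, 0.4]
    x[5] = c[1] + [0.4, -0.6, 0.7]
    x[6] = c[1] + [0.4, -0.6, -0.7]
    x[8] = c[2] + [-0.4, 0.6, 0.7]
    x[9] = c[2] + [-0.4, 0.6, -0.7]
    x[11] = c[3] + [0.6, 0.6, 0.6]
    x[12] = c[3] + [0.6, 0.3, -0.8]
    x[13] = c[3] + [-0.2, 2.2 - 1.33, 0.4]
    return x


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
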