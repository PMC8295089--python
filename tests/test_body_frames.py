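"""Molecule/UA reference frames, generalized forces, halving rules."""

import numpy as np
import pytest

from conftest import random_rotation
from eemcc import (FrameSet, GeometryError, HALVING_FACTORS, build_topology,
                   molecule_frame, molecule_generalized_forces,
                   net_force_torque, ua_axes, ua_generalized_forces,
                   united_atom_dof)


def frames_from(coords, forces=None, box=50.0):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    forces = np.zeros_like(coords) if forces is None else \
        np.asarray(forces, dtype=float).reshape(coords.shape)
    return FrameSet(coords + box / 2.0, forces, np.full((len(coords), 3), box))


def test_water_c2_axis_is_principal(water_topology, water_coords):
    frames = frames_from(water_coords)
    body = molecule_frame(frames, water_topology, 0)
    # the C2 axis (y) must appear among the principal axes
    overlaps = np.abs(body.axes[0] @ np.array([0.0, 1.0, 0.0]))
    assert overlaps.max() == pytest.approx(1.0, abs=1e-10)
    # axes orthonormal and right-handed
    np.testing.assert_allclose(body.axes[0] @ body.axes[0].T, np.eye(3),
                               atol=1e-10)
    assert np.linalg.det(body.axes[0]) == pytest.approx(1.0, abs=1e-10)
    assert np.all(np.diff(body.moments[0]) >= -1e-12)


def test_molecule_frame_equivariance(butane_topology, butane_coords, rng):
    frames = frames_from(butane_coords)
    body = molecule_frame(frames, butane_topology, 0)
    q = random_rotation(rng)
    rotated = frames_from(butane_coords @ q.T)
    body_r = molecule_frame(rotated, butane_topology, 0)
    np.testing.assert_allclose(body_r.moments, body.moments, rtol=1e-9)
    # rotated axes equal the rotation of the original axes up to the fixed
    # sign convention
    for k in range(3):
        dot = abs(body_r.axes[0, k] @ (q @ body.axes[0, k]))
        assert dot == pytest.approx(1.0, abs=1e-9)


def test_planar_ring_out_of_plane_moment_largest():
    # planar hexagon in the xy plane: largest moment about z
    ang = np.radians(np.arange(6) * 60.0)
    coords = np.stack([1.4 * np.cos(ang), 1.4 * np.sin(ang),
                       np.zeros(6)], axis=1)
    topo = build_topology(["C"] * 6, [(i, (i + 1) % 6) for i in range(6)])
    body = molecule_frame(frames_from(coords), topo, 0)
    # ascending moments: the last axis is out of plane
    assert abs(body.axes[0, 2] @ [0, 0, 1.0]) == pytest.approx(1.0, abs=1e-9)
    assert body.moments[0, 2] == pytest.approx(2 * body.moments[0, 0], rel=1e-9)


def test_collinear_molecule_rejected():
    coords = np.array([[0.0, 0, 0], [1.2, 0, 0], [2.4, 0, 0]])
    topo = build_topology(["C", "C", "C"], [(0, 1), (1, 2)])
    with pytest.raises(GeometryError, match="collinear"):
        molecule_frame(frames_from(coords), topo, 0)


@pytest.mark.parametrize("n_h,expected", [(3, (3, 3)), (2, (3, 3)),
                                          (1, (3, 2)), (0, (3, 0))])
def test_united_atom_dof_rules(n_h, expected):
    # a lone carbon with n_h hydrogens (plus a neighbour C to keep the
    # hydrogen rule satisfied for the zero-H case)
    elements = ["C"] + ["H"] * n_h + ["C"] + ["H"] * 3
    bonds = [(0, i) for i in range(1, n_h + 1)]
    nc = n_h + 1
    bonds += [(0, nc)] + [(nc, nc + 1 + i) for i in range(3)]
    topo = build_topology(elements, bonds)
    assert united_atom_dof(topo, 0)[0] == expected


def test_uniform_field_gives_zero_torque_about_com(water_topology,
                                                   water_coords):
    # a uniform acceleration field (F_a = m_a g) acts through the COM
    g = np.array([0.3, -0.2, 0.1])
    masses = water_topology.masses
    force = masses[:, None] * g[None, :]
    frames = frames_from(water_coords, force)
    gfs = molecule_generalized_forces(frames, water_topology, 0)
    np.testing.assert_allclose(gfs.torque[0], 0.0, atol=1e-12)
    # net body-frame force keeps the lab-frame magnitude, halved
    assert np.linalg.norm(gfs.force[0]) == pytest.approx(
        0.5 * masses.sum() * np.linalg.norm(g))


def test_force_couple_gives_pure_torque():
    coords = np.array([[-1.0, 0, 0], [1.0, 0, 0], [0.0, 0.5, 0]])
    forces = np.array([[0, -2.0, 0], [0, 2.0, 0], [0, 0, 0]])
    topo = build_topology(["C", "C", "O"], [(0, 2), (1, 2)])
    frames = frames_from(coords, forces)
    body = molecule_frame(frames, topo, 0)
    f, t = net_force_torque(frames.coordinates[:, :3], frames.forces[:, :3],
                            body)
    np.testing.assert_allclose(f[0], 0.0, atol=1e-12)
    assert np.linalg.norm(t[0]) == pytest.approx(4.0)  # 2 × |r×F| = 2×2


def test_torque_matches_lab_frame_cross_product(butane_topology,
                                                butane_coords, rng):
    forces = rng.standard_normal((14, 3))
    frames = frames_from(butane_coords, forces)
    body = molecule_frame(frames, butane_topology, 0)
    _, t_body = net_force_torque(frames.coordinates, frames.forces, body)
    # brute-force oracle: Σ r×F in the lab, then rotate
    rel = frames.coordinates[0] - body.origin[0]
    t_lab = np.cross(rel, forces).sum(axis=0)
    np.testing.assert_allclose(t_body[0], body.axes[0] @ t_lab, atol=1e-10)


def test_ua_axis_along_single_heavy_bond(butane_topology, butane_coords):
    frames = frames_from(butane_coords)
    bodies = ua_axes(frames, butane_topology, 0)
    # terminal CH3 (heavy atom 0, single heavy neighbour 4): axis1 ∥ C–C
    bond = butane_coords[4] - butane_coords[0]
    bond /= np.linalg.norm(bond)
    assert abs(bodies[0].axes[0, 0] @ bond) == pytest.approx(1.0, abs=1e-10)


def test_ua_bisector_axis_for_midchain(butane_topology, butane_coords):
    frames = frames_from(butane_coords)
    bodies = ua_axes(frames, butane_topology, 0)
    # mid-chain CH2 (heavy atom 4, neighbours 0 and 7)
    b1 = butane_coords[0] - butane_coords[4]
    b2 = butane_coords[7] - butane_coords[4]
    bis = b1 / np.linalg.norm(b1) + b2 / np.linalg.norm(b2)
    bis /= np.linalg.norm(bis)
    assert abs(bodies[1].axes[0, 0] @ bis) == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(bodies[1].axes[0] @ bodies[1].axes[0].T,
                               np.eye(3), atol=1e-10)


def test_ua_axes_equivariance(butane_topology, butane_coords, rng):
    q = random_rotation(rng)
    base = ua_axes(frames_from(butane_coords), butane_topology, 0)
    rot = ua_axes(frames_from(butane_coords @ q.T), butane_topology, 0)
    for b, r in zip(base, rot):
        # bond-derived frames rotate with the molecule (axis1 exactly;
        # axis2/3 also, because they derive from the bonds)
        np.testing.assert_allclose(r.axes[0, 0], q @ b.axes[0, 0],
                                   atol=1e-10)


def test_halving_flags_follow_the_mean_field_rule(butane_topology,
                                                  butane_coords):
    assert HALVING_FACTORS == {("M", "trans"): 0.5, ("M", "rot"): 0.5,
                               ("UA", "trans"): 1.0, ("UA", "rot"): 0.5}
    frames = frames_from(butane_coords)
    mol = molecule_generalized_forces(frames, butane_topology, 0)
    assert mol.halving == {"force": 0.5, "torque": 0.5}
    for ua in ua_generalized_forces(frames, butane_topology, 0):
        assert ua.halving == {"force": 1.0, "torque": 0.5}


def test_ua_torque_dimensions_match_dof(butane_topology, butane_coords):
    frames = frames_from(butane_coords)
    uas = ua_generalized_forces(frames, butane_topology, 0)
    dof = united_atom_dof(butane_topology, 0)
    for ua, (_, n_rot) in zip(uas, dof):
        assert ua.torque.shape[1] == n_rot
        assert ua.moments.shape[1] == n_rot
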