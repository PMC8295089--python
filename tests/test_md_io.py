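"""Topology/trajectory/energy I/O: dialects, derivation rules, round trips."""

import numpy as np
import pytest

from eemcc import (FrameSet, TopologyError, TrajectoryError, build_topology,
                   load_energy_series, load_topology, read_frames,
                   write_frames, write_topology)
from eemcc.md_io import detect_flexible_dihedrals, iter_frame_blocks


@pytest.mark.parametrize("elements,bonds,n_mol,n_ua,n_dih", [
    # water: one molecule, one united atom, no flexible dihedrals
    (["O", "H", "H"], [(0, 1), (0, 2)], 1, 1, 0),
    # methane: one UA containing all five atoms
    (["C", "H", "H", "H", "H"], [(0, 1), (0, 2), (0, 3), (0, 4)], 1, 1, 0),
])
def test_united_atom_derivation(elements, bonds, n_mol, n_ua, n_dih):
    topo = build_topology(elements, bonds)
    assert len(topo.molecules) == n_mol
    mol = topo.molecules[0]
    assert len(mol.united_atoms) == n_ua
    assert len(mol.flexible_dihedrals) == n_dih
    # the UA partition covers every atom exactly once
    covered = sorted(a for ua in mol.united_atoms for a in ua.atoms)
    assert covered == sorted(mol.atom_indices)


def test_octanol_heavy_chain_has_nine_united_atoms():
    # heavy-atom skeleton C8–O with explicit hydrogens on each carbon
    elements, bonds = [], []
    heavy = []
    for i in range(8):
        heavy.append(len(elements))
        elements.append("C")
        if i > 0:
            bonds.append((heavy[i - 1], heavy[i]))
        n_h = 3 if i in (0,) else 2
        for _ in range(n_h):
            elements.append("H")
            bonds.append((heavy[i], len(elements) - 1))
    o = len(elements)
    elements += ["O", "H"]
    bonds += [(heavy[-1], o), (o, o + 1)]
    topo = build_topology(elements, bonds)
    assert len(topo.molecules[0].united_atoms) == 9


def test_flexible_dihedral_rules_skip_terminal_and_ring_bonds():
    # benzene ring with a two-carbon tail: only the ring–tail and tail
    # C–C bonds are candidates; the bond to the terminal CH3 is excluded,
    # all ring bonds are excluded
    elements = ["C"] * 8 + ["H"] * 0
    bonds = [(i, (i + 1) % 6) for i in range(6)]  # ring 0..5
    bonds += [(0, 6), (6, 7)]                     # tail C6–C7
    quads = detect_flexible_dihedrals(
        [a for a in build_topology(elements, bonds).atoms], list(range(8)))
    # only bond 0–6 is non-ring with both ends non-terminal
    assert len(quads) == 1
    assert quads[0][1:3] in {(0, 6), (6, 0)}


def test_butane_single_flexible_dihedral(butane_topology):
    mol = butane_topology.molecules[0]
    assert len(mol.flexible_dihedrals) == 1
    a, b, c, d = mol.flexible_dihedrals[0]
    assert (b, c) == (4, 7)  # central C–C bond


def test_hydrogen_bonded_to_two_heavies_is_an_error():
    with pytest.raises(TopologyError, match="hydrogen"):
        build_topology(["C", "H", "C"], [(0, 1), (1, 2)])


def test_topology_yaml_round_trip(tmp_path, butane_topology):
    path = tmp_path / "topo.yaml"
    write_topology(butane_topology, path)
    back = load_topology(path)
    assert [a.element for a in back.atoms] == \
        [a.element for a in butane_topology.atoms]
    assert [a.mass for a in back.atoms] == \
        [a.mass for a in butane_topology.atoms]
    assert [m.atom_indices for m in back.molecules] == \
        [m.atom_indices for m in butane_topology.molecules]
    assert back.molecules[0].flexible_dihedrals == \
        butane_topology.molecules[0].flexible_dihedrals


def test_frames_round_trip_bitwise(tmp_path, rng):
    frames = FrameSet(rng.standard_normal((3, 5, 3)),
                      rng.standard_normal((3, 5, 3)),
                      box=np.full((3, 3), 17.25), temperature=310.0)
    path = tmp_path / "frames.txt"
    write_frames(frames, path)
    back = read_frames(path)
    assert back.n_frames == 3
    assert np.array_equal(back.coordinates, frames.coordinates)
    assert np.array_equal(back.forces, frames.forces)
    assert np.array_equal(back.box, frames.box)
    assert back.temperature == 310.0


def test_frame_block_streaming_matches_whole_read(tmp_path, rng):
    frames = FrameSet(rng.standard_normal((7, 2, 3)),
                      rng.standard_normal((7, 2, 3)),
                      box=np.full((7, 3), 9.0))
    path = tmp_path / "frames.txt"
    write_frames(frames, path)
    blocks = list(iter_frame_blocks(path, block_size=3))
    assert [b.n_frames for b in blocks] == [3, 3, 1]
    assert np.array_equal(np.concatenate([b.coordinates for b in blocks]),
                          frames.coordinates)


def test_forces_are_mandatory(tmp_path):
    with pytest.raises(TrajectoryError, match="truncated|forces"):
        path = tmp_path / "broken.txt"
        path.write_text("1 1\n10 10 10\n0.0 0.0 0.0\n")  # no force line
        read_frames(path)


def test_atom_count_mismatch(tmp_path, water_topology):
    path = tmp_path / "frames.txt"
    frames = FrameSet(np.zeros((1, 2, 3)), np.zeros((1, 2, 3)),
                      np.full((1, 3), 10.0))
    write_frames(frames, path)
    with pytest.raises(TrajectoryError, match="atoms"):
        read_frames(path, water_topology)


def test_netcdf_round_trip_with_forces(tmp_path, rng):
    from scipy.io import netcdf_file

    coords = rng.standard_normal((4, 3, 3)).astype(np.float32)
    forces = rng.standard_normal((4, 3, 3)).astype(np.float32)
    path = tmp_path / "traj.nc"
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("frame", None)
        nc.createDimension("atom", 3)
        nc.createDimension("spatial", 3)
        nc.createDimension("cell_spatial", 3)
        v = nc.createVariable("coordinates", "f", ("frame", "atom", "spatial"))
        v[:] = coords
        v = nc.createVariable("forces", "f", ("frame", "atom", "spatial"))
        v[:] = forces
        v = nc.createVariable("cell_lengths", "d", ("frame", "cell_spatial"))
        v[:] = np.full((4, 3), 20.0)
    back = read_frames(path, format_name="netcdf")
    assert back.n_frames == 4
    np.testing.assert_allclose(back.coordinates, coords, rtol=1e-6)
    np.testing.assert_allclose(back.forces, forces, rtol=1e-6)


def test_netcdf_without_forces_is_an_error(tmp_path):
    from scipy.io import netcdf_file

    path = tmp_path / "nof.nc"
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("frame", None)
        nc.createDimension("atom", 2)
        nc.createDimension("spatial", 3)
        v = nc.createVariable("coordinates", "f", ("frame", "atom", "spatial"))
        v[:] = np.zeros((1, 2, 3), dtype=np.float32)
    with pytest.raises(TrajectoryError, match="forces required"):
        read_frames(path, format_name="netcdf")


def test_prmtop_minimal_reader(tmp_path):
    text = """%VERSION  VERSION_STAMP = V0001.000
%FLAG TITLE
%FORMAT(20a4)
WAT
%FLAG POINTERS
%FORMAT(10I8)
       3       2       2       0       0       0       0       0       0       0
%FLAG ATOMIC_NUMBER
%FORMAT(10I8)
       8       1       1
%FLAG MASS
%FORMAT(5E16.8)
  1.59990000E+01  1.00800000E+00  1.00800000E+00
%FLAG RESIDUE_LABEL
%FORMAT(20a4)
WAT
%FLAG RESIDUE_POINTER
%FORMAT(10I8)
       1
%FLAG BONDS_INC_HYDROGEN
%FORMAT(10I8)
       0       3       1       0       6       1
"""
    path = tmp_path / "wat.prmtop"
    path.write_text(text)
    topo = load_topology(path, "prmtop")
    assert topo.n_atoms == 3
    assert [a.element for a in topo.atoms] == ["O", "H", "H"]
    assert topo.molecules[0].species == "water"
    assert topo.molecules[0].sigma == 2.0
    assert len(topo.molecules[0].united_atoms) == 1


def test_energy_series_table_and_mdout(tmp_path):
    table = tmp_path / "energy.txt"
    table.write_text("".join(f"{i} 5.0\n" for i in range(10)))
    series = load_energy_series(table, "wat")
    assert series.mean == pytest.approx(5.0)
    assert len(series.values) == 10

    mdout = tmp_path / "box.mdout"
    mdout.write_text("\n".join(
        f" NSTEP = {i}\n Etot   =   {-9500.5 - i:.4f}  EKtot = 100.0"
        for i in range(4)))
    series = load_energy_series(mdout, "X(aq)")
    assert len(series.values) == 4
    assert series.values[0] == pytest.approx(-9500.5)


def test_energy_series_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_energy_series(tmp_path / "absent.txt", "x")
    bad = tmp_path / "bad.txt"
    bad.write_text("0 not_a_number\n")
    with pytest.raises(TrajectoryError, match="non-numeric"):
        load_energy_series(bad, "x")
    empty = tmp_path / "empty.txt"
    empty.write_text("# just a comment\n")
    with pytest.raises(TrajectoryError, match="empty"):
        load_energy_series(empty, "x")
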