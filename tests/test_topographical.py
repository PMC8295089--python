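"""Positional, orientational and conformational entropy terms."""

import math

import numpy as np
import pytest

from eemcc import (assign_conformers, conformational_entropy, dihedral_angles,
                   dihedral_chain, orientational_entropy, positional_entropy,
                   positional_transfer_entropy)
from eemcc.constants import R_J


# --- positional ------------------------------------------------------------

def test_positional_entropy_basics():
    assert positional_entropy(100.0, 100.0) == 0.0
    s = positional_entropy(200.0, 50.0)
    assert s == pytest.approx(R_J * math.log(4.0))
    # scale invariance: only the ratio matters
    assert positional_entropy(400.0, 100.0) == pytest.approx(s)
    with pytest.raises(ValueError):
        positional_entropy(-1.0, 5.0)


def test_positional_transfer_is_volume_ratio():
    v_wat = 34.0**3 / 1300.0
    v_oct = 34.0**3 / 150.0
    ds = positional_transfer_entropy(v_wat, v_oct)
    assert ds == pytest.approx(R_J * math.log(150.0 / 1300.0))
    # antisymmetry
    assert positional_transfer_entropy(v_oct, v_wat) == pytest.approx(-ds)


# --- orientational ---------------------------------------------------------

def test_orientational_zero_coordination_clamps_to_zero():
    assert orientational_entropy({0: 1.0}, sigma=1.0) == 0.0


def test_orientational_single_neighbour():
    s = orientational_entropy({1: 1.0}, sigma=1.0)
    assert s == pytest.approx(R_J * math.log(math.sqrt(math.pi)))


def test_orientational_water_quarter_factor():
    # Nc = 4, σ = 2, water: Ω = ¼·√(64π)/2 = √π
    s = orientational_entropy({4: 1.0}, sigma=2.0, is_water=True)
    assert s == pytest.approx(R_J * math.log(
        max(1.0, 0.25 * math.sqrt(4**3 * math.pi) / 2.0)))
    # without the water factor the same distribution has more orientations
    s_plain = orientational_entropy({4: 1.0}, sigma=2.0, is_water=False)
    assert s_plain > s


def test_orientational_nondecreasing_in_nc():
    values = [orientational_entropy({nc: 1.0}, sigma=1.0)
              for nc in range(0, 15)]
    assert all(b >= a for a, b in zip(values, values[1:]))


def test_orientational_validates_distribution():
    with pytest.raises(ValueError, match="sums"):
        orientational_entropy({4: 0.7}, sigma=1.0)
    with pytest.raises(ValueError, match="symmetry"):
        orientational_entropy({4: 1.0}, sigma=0.5)


# --- dihedral angles -------------------------------------------------------

def test_dihedral_angle_known_geometries():
    box = np.full((1, 3), 100.0)

    def angle_of(p3):
        coords = np.array([[[1.0, 0, 0], [0.0, 0, 0], [0.0, 1.0, 0], p3]])
        return dihedral_angles(coords, box, (0, 1, 2, 3))[0]

    assert angle_of([-1.0, 1.0, 0.0]) == pytest.approx(180.0)   # trans
    assert angle_of([1.0, 1.0, 0.0]) == pytest.approx(0.0, abs=1e-10)  # cis
    assert angle_of([0.0, 1.0, 1.0]) % 360 == pytest.approx(90.0)


# --- conformer assignment --------------------------------------------------

def test_single_mode_gives_one_conformer(rng):
    angles = (180.0 + 8.0 * rng.standard_normal(2000)) % 360.0
    states = assign_conformers(angles)
    assert states.n_conformers == 1
    assert conformational_entropy([states]) == 0.0


def test_three_equal_wells_recovered(rng):
    angles, truth = dihedral_chain([[1 / 3, 1 / 3, 1 / 3]], n_frames=6000,
                                   seed=5)
    states = assign_conformers(angles[:, 0])
    assert states.n_conformers == 3
    np.testing.assert_allclose(states.probabilities, 1 / 3, atol=0.03)


def test_two_well_populations_within_binomial_error():
    n = 4000
    angles, truth = dihedral_chain([[0.9, 0.1]], n_frames=n, seed=9)
    states = assign_conformers(angles[:, 0])
    assert states.n_conformers == 2
    p_hat = np.sort(states.probabilities)[-1]
    # 4σ binomial band around the generating probability
    assert abs(p_hat - 0.9) < 4.0 * math.sqrt(0.9 * 0.1 / n)


def test_too_few_frames_marks_dihedral_rigid():
    with pytest.warns(UserWarning, match="rigid"):
        states = assign_conformers(np.full(10, 60.0))
    assert states.n_conformers == 1


# --- conformational entropy ------------------------------------------------

def test_single_dihedral_reduces_to_shannon(rng):
    angles, _ = dihedral_chain([[0.5, 0.5]], n_frames=8000, seed=3)
    states = assign_conformers(angles[:, 0])
    s = conformational_entropy([states])
    assert s == pytest.approx(states.shannon_entropy, rel=1e-9)
    assert s == pytest.approx(R_J * math.log(2.0), rel=0.02)


def test_correlated_pair_not_double_counted():
    angles, truth = dihedral_chain([[0.5, 0.5], [0.5, 0.5]], n_frames=8000,
                                   seed=4, correlated=True)
    states = [assign_conformers(angles[:, d]) for d in range(2)]
    s = conformational_entropy(states)
    assert truth.joint_entropy == pytest.approx(R_J * math.log(2.0))
    assert s == pytest.approx(R_J * math.log(2.0), rel=0.02)


def test_exact_correlated_matrix_eigenstructure():
    # hand construction: two perfectly correlated two-state dihedrals;
    # the 4×4 correlation matrix has eigenvalues {1, 1, 0, 0}, which
    # renormalise to {½, ½} → S = k_B ln 2 exactly
    from eemcc.topographical import DihedralStateSeries

    labels = np.array([0, 1] * 500)
    s1 = DihedralStateSeries(labels=labels, n_conformers=2,
                             boundaries=np.array([0.0, 180.0]))
    s2 = DihedralStateSeries(labels=labels.copy(), n_conformers=2,
                             boundaries=np.array([0.0, 180.0]))
    assert conformational_entropy([s1, s2]) == pytest.approx(
        R_J * math.log(2.0), rel=1e-12)


def test_independent_pair_bounded_by_sum_of_shannons():
    angles, truth = dihedral_chain([[0.5, 0.5], [0.5, 0.5]], n_frames=8000,
                                   seed=6, correlated=False)
    states = [assign_conformers(angles[:, d]) for d in range(2)]
    s = conformational_entropy(states)
    assert s <= sum(st.shannon_entropy for st in states) + 1e-9
    assert s > 0


def test_deterministic_series_gives_zero():
    from eemcc.topographical import DihedralStateSeries

    states = DihedralStateSeries(labels=np.zeros(100, dtype=int),
                                 n_conformers=1,
                                 boundaries=np.array([0.0]))
    assert conformational_entropy([states]) == 0.0


def test_order_permutation_invariance(rng):
    angles, _ = dihedral_chain([[0.6, 0.4], [0.3, 0.7]], n_frames=4000,
                               seed=8)
    perm = rng.permutation(4000)
    s1 = conformational_entropy(
        [assign_conformers(angles[:, d]) for d in range(2)])
    s2 = conformational_entropy(
        [assign_conformers(angles[perm, d]) for d in range(2)])
    assert s1 == pytest.approx(s2, rel=1e-12)
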