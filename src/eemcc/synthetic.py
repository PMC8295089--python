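"""Synthetic systems with exactly known entropies and energies.

Every stage of the entropy pipeline gets a download-free oracle:

* :func:`harmonic_liquid` — point molecules tethered to lattice sites by
  independent springs, sampled from the exact Boltzmann distribution (no
  integrator, hence no timestep bias).  Forces satisfy F = −∇U exactly and
  the analytic frequencies and QHO entropies are returned alongside.
* :func:`dihedral_chain` — multi-well dihedral angle series with known
  conformer populations, independent or perfectly correlated.
* :func:`toy_shell_geometry` — fixed centre-of-mass configurations whose
  first shells are hand-checkable, plus a naive reference evaluation of the
  RAD blocking inequality.
* :func:`composite_solution` — four harmonic boxes mimicking the
  solute-in-water / solute-in-octanol / pure-water / pure-octanol transfer
  cycle with a prescribed ΔH and an analytically known ΔS, hence exact ΔG
  and logP for end-to-end recovery tests.

These fixtures validate estimators, not force fields; they make no attempt
to mimic real water or octanol structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (J_TO_KCAL, KB_KCAL, OMEGA_SQ_TO_SI, TWO_PI)
from .md_io import EnergySeries, FrameSet, MolecularTopology, build_topology
from .vibrational import ModeSpectrum, qho_entropy

__all__ = [
    "HarmonicOracle",
    "DihedralTruth",
    "CompositeOracle",
    "CompositeBundle",
    "harmonic_frequency",
    "harmonic_liquid",
    "dihedral_chain",
    "toy_shell_geometry",
    "brute_force_rad",
    "composite_solution",
]


def _lattice(n: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """First n sites of a cubic lattice and the enclosing box lengths."""
    side = math.ceil(n ** (1.0 / 3.0))
    grid = np.array([(i, j, k) for i in range(side)
                     for j in range(side) for k in range(side)][:n],
                    dtype=float)
    sites = (grid + 0.5) * spacing
    box = np.full(3, side * spacing)
    return sites, box


def harmonic_frequency(spring: float, mass: float) -> float:
    """Exact oscillator frequency (s⁻¹) for a spring (kcal mol⁻¹ Å⁻²) and
    mass (amu): ν = (1/2π)√(k/m)."""
    return math.sqrt(spring / mass * OMEGA_SQ_TO_SI) / TWO_PI


@dataclass
class HarmonicOracle:
    """Closed-form truth for a harmonic liquid."""

    springs: np.ndarray          # per molecule, kcal/mol/Å²
    masses: np.ndarray           # per molecule, amu
    temperature: float
    mean_energy: float           # kcal/mol, equipartition + offset

    def frequencies(self, molecule: int, halved: bool = False) -> np.ndarray:
        """The three exact mode frequencies of one molecule (s⁻¹).

        ``halved=True`` gives the expectation of the estimator after the
        mean-field halving of molecule-level forces (ν/2)."""
        nu = harmonic_frequency(self.springs[molecule], self.masses[molecule])
        return np.full(3, 0.5 * nu if halved else nu)

    def entropy(self, molecule: int, halved: bool = False) -> float:
        """Exact QHO entropy of one molecule's three modes, J/K/mol."""
        spec = ModeSpectrum(self.frequencies(molecule, halved=halved))
        return qho_entropy(spec, self.temperature)


def harmonic_liquid(n_molecules: int, spring, n_frames: int, seed: int,
                    mass: float = 18.0, temperature: float = 298.0,
                    spacing: float = 3.1, species: str = "water",
                    energy_offset: float = 0.0,
                    ar1_correlation: float = 0.0,
                    ) -> tuple[MolecularTopology, FrameSet, EnergySeries,
                               HarmonicOracle]:
    """Point molecules on a lattice, each tethered by an isotropic spring.

    Positions are exact Boltzmann samples (Gaussian, σ² = k_BT/k per
    coordinate); forces are −k·displacement; the energy series is the
    sampled potential plus the constant equipartition kinetic term.
    ``spring`` may be a scalar or a per-molecule array.
    ``ar1_correlation`` ∈ [0, 1) adds frame-to-frame AR(1) memory without
    changing the marginal distribution (for robustness tests).
    """
    rng = np.random.default_rng(seed)
    springs = np.broadcast_to(np.asarray(spring, dtype=float),
                              (n_molecules,)).copy()
    if np.any(springs <= 0):
        raise ValueError("spring constants must be positive")
    sites, box = _lattice(n_molecules, spacing)
    sigma = np.sqrt(KB_KCAL * temperature / springs)  # per molecule
    disp = rng.standard_normal((n_frames, n_molecules, 3)) \
        * sigma[None, :, None]
    if ar1_correlation:
        rho = float(ar1_correlation)
        if not 0.0 <= rho < 1.0:
            raise ValueError("ar1_correlation must be in [0, 1)")
        scale = math.sqrt(1.0 - rho * rho)
        for f in range(1, n_frames):
            disp[f] = rho * disp[f - 1] + scale * disp[f]
    coords = sites[None, :, :] + disp
    forces = -springs[None, :, None] * disp
    potential = 0.5 * (springs[None, :, None] * disp**2).sum(axis=(1, 2))
    kinetic = 0.5 * 3 * n_molecules * KB_KCAL * temperature
    energy = EnergySeries(potential + kinetic + energy_offset,
                          label=species)
    topology = build_topology(
        elements=["X"] * n_molecules,
        bonds=[],
        molecules_spec=[{"atoms": [i], "species": species,
                         "sigma": 2.0 if species == "water" else 1.0}
                        for i in range(n_molecules)],
        masses=[mass] * n_molecules,
    )
    frames = FrameSet(coordinates=coords, forces=forces,
                      box=np.tile(box, (n_frames, 1)),
                      temperature=temperature)
    oracle = HarmonicOracle(
        springs=springs, masses=np.full(n_molecules, mass),
        temperature=temperature,
        mean_energy=3 * n_molecules * KB_KCAL * temperature + energy_offset)
    return topology, frames, energy, oracle


# ---------------------------------------------------------------------------
# dihedral series
# ---------------------------------------------------------------------------

@dataclass
class DihedralTruth:
    """Generating truth for a synthetic dihedral series."""

    states: np.ndarray            # (n_frames, n_dihedrals) well labels
    probabilities: list[np.ndarray]
    centers: list[np.ndarray]     # well centres, degrees
    correlated: bool

    def shannon_entropy(self, dihedral: int) -> float:
        """Marginal Shannon entropy of the generating distribution, J/K/mol."""
        from .constants import R_J
        p = self.probabilities[dihedral]
        p = p[p > 0]
        return float(-R_J * np.sum(p * np.log(p)))

    @property
    def joint_entropy(self) -> float:
        """Exact joint conformational entropy of the construction, J/K/mol."""
        if self.correlated:
            return self.shannon_entropy(0)
        return sum(self.shannon_entropy(i)
                   for i in range(len(self.probabilities)))


_DEFAULT_CENTERS = np.array([60.0, 180.0, 300.0])


def dihedral_chain(probabilities, n_frames: int, seed: int,
                   centers=None, noise_deg: float = 12.0,
                   correlated: bool = False,
                   ) -> tuple[np.ndarray, DihedralTruth]:
    """Angle series (degrees, (n_frames, n_dihedrals)) with known wells.

    Each dihedral draws a well per frame from its probability vector and
    adds wrapped Gaussian noise about the well centre.  With
    ``correlated=True`` every dihedral copies the first one's well choice
    (all probability vectors must then have equal length), so the exact
    joint entropy is that of a single dihedral.
    """
    rng = np.random.default_rng(seed)
    probs = [np.asarray(p, dtype=float) for p in probabilities]
    for p in probs:
        if not math.isclose(p.sum(), 1.0, abs_tol=1e-9) or np.any(p < 0):
            raise ValueError(f"probabilities {p} are not a distribution")
    if centers is None:
        centers = [_DEFAULT_CENTERS[:len(p)].copy() for p in probs]
    centers = [np.asarray(c, dtype=float) for c in centers]
    if correlated and len({len(p) for p in probs}) != 1:
        raise ValueError("correlated mode needs equal conformer counts")
    n_dih = len(probs)
    states = np.empty((n_frames, n_dih), dtype=int)
    states[:, 0] = rng.choice(len(probs[0]), size=n_frames, p=probs[0])
    for d in range(1, n_dih):
        if correlated:
            states[:, d] = states[:, 0]
        else:
            states[:, d] = rng.choice(len(probs[d]), size=n_frames, p=probs[d])
    angles = np.empty((n_frames, n_dih))
    for d in range(n_dih):
        angles[:, d] = (centers[d][states[:, d]]
                        + noise_deg * rng.standard_normal(n_frames)) % 360.0
    return angles, DihedralTruth(states=states, probabilities=probs,
                                 centers=centers, correlated=correlated)


# ---------------------------------------------------------------------------
# toy shell geometries
# ---------------------------------------------------------------------------

def brute_force_rad(coms: np.ndarray, center: int,
                    box: np.ndarray) -> frozenset[int]:
    """Naive reference evaluation of the RAD blocking inequality.

    Candidates are walked in ascending distance (pure Python, no pre-cut,
    no vectorisation); each is tested against every already-accepted closer
    neighbour with 1/r_j² < (1/r_k²)·cos θ_jik.
    """
    coms = np.asarray(coms, dtype=float)
    box = np.asarray(box, dtype=float)
    cands = []
    for j in range(coms.shape[0]):
        if j == center:
            continue
        d = coms[j] - coms[center]
        d = d - box * np.round(d / box)
        cands.append((float(np.dot(d, d)), j, d))
    cands.sort(key=lambda t: (t[0], t[1]))
    accepted: list[tuple[float, int, np.ndarray]] = []
    for r2j, j, dj in cands:
        blocked = False
        for r2k, _, dk in accepted:
            cos_jik = float(np.dot(dj, dk)) / math.sqrt(r2j * r2k)
            if 1.0 / r2j < (1.0 / r2k) * cos_jik:
                blocked = True
                break
        if not blocked:
            accepted.append((r2j, j, dj))
    return frozenset(j for _, j, _ in accepted)


def toy_shell_geometry(name: str, seed: int = 2024
                       ) -> tuple[np.ndarray, np.ndarray, int, frozenset[int]]:
    """Named COM configuration: (coms, box, center_index, expected shell).

    The expected shell is the brute-force evaluation of the blocking
    inequality; for the deterministic geometries it equals the
    hand-derived answer (collinear blocking → 1; square → 4;
    octahedron with a far seventh → 6).
    """
    box = np.full(3, 40.0)
    c = np.full(3, 20.0)
    if name == "collinear3":
        coms = np.array([c, c + [2.5, 0, 0], c + [5.0, 0, 0]])
    elif name == "square4":
        coms = np.array([c, c + [3.0, 0, 0], c + [-3.0, 0, 0],
                         c + [0, 3.0, 0], c + [0, -3.0, 0]])
    elif name == "octahedron6_plus1":
        coms = np.array([c,
                         c + [3.0, 0, 0], c + [-3.0, 0, 0],
                         c + [0, 3.0, 0], c + [0, -3.0, 0],
                         c + [0, 0, 3.0], c + [0, 0, -3.0],
                         c + [6.0, 0, 0]])
    elif name == "random_seeded":
        rng = np.random.default_rng(seed)
        box = np.full(3, 12.0)
        coms = rng.uniform(0.0, 12.0, size=(20, 3))
    else:
        raise ValueError(f"unknown toy geometry '{name}'")
    return coms, box, 0, brute_force_rad(coms, 0, box)


# ---------------------------------------------------------------------------
# four-box composite
# ---------------------------------------------------------------------------

@dataclass
class CompositeOracle:
    """Exact transfer thermodynamics implied by the construction."""

    delta_h: float          # kcal/mol
    delta_s: float          # J/K/mol (estimator expectation, incl. halving)
    temperature: float

    @property
    def t_delta_s(self) -> float:
        return self.temperature * self.delta_s * J_TO_KCAL

    @property
    def delta_g(self) -> float:
        return self.delta_h - self.t_delta_s

    @property
    def log_p(self) -> float:
        return -self.delta_g / (math.log(10.0) * KB_KCAL * self.temperature)


@dataclass
class CompositeBundle:
    """Four synthetic boxes (X(aq), X(oct), wat, oct) plus their oracle."""

    systems: dict = field(default_factory=dict)  # label -> (topo, frames, energy)
    oracle: CompositeOracle | None = None


def composite_solution(seed: int, n_frames: int, n_solvent: int = 24,
                       solvent_spring: float = 10.0,
                       solute_spring_aq: float = 25.0,
                       solute_spring_oct: float = 25.0,
                       delta_h: float = -1.3643,
                       solute_mass: float = 50.0,
                       solvent_mass: float = 18.0,
                       temperature: float = 298.0,
                       spacing: float = 3.1) -> CompositeBundle:
    """Four harmonic boxes realising a prescribed water→octanol transfer.

    Both solvents share identical parameters (their shell and vibrational
    terms cancel in expectation); the solute spring may differ between the
    two solutions, fixing ΔS, and the X(oct) energy series carries a
    constant offset equal to the prescribed ΔH.  The oracle entropy is the
    expectation of the pipeline's estimator, i.e. the QHO entropy at the
    mean-field-halved frequencies.
    """
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    def make(label, solvent_species, with_solute, solute_spring, offset, sd):
        n = n_solvent + (1 if with_solute else 0)
        springs = np.full(n, solvent_spring)
        masses = [solvent_mass] * n
        species = [solvent_species] * n
        if with_solute:
            # the solute takes the lattice site nearest the box centre
            sites, _ = _lattice(n, spacing)
            mid = int(np.argmin(((sites - sites.mean(axis=0))**2).sum(axis=1)))
            springs[mid] = solute_spring
            masses[mid] = solute_mass
            species[mid] = "solute"
        topo, frames, energy, oracle = harmonic_liquid(
            n_molecules=n, spring=springs, n_frames=n_frames, seed=sd,
            mass=solvent_mass, temperature=temperature, spacing=spacing,
            species=solvent_species, energy_offset=offset)
        # harmonic_liquid assigns one mass/species for all; patch the solute
        if with_solute:
            topo = build_topology(
                elements=["X"] * n, bonds=[],
                molecules_spec=[{"atoms": [i], "species": species[i],
                                 "sigma": 2.0 if species[i] == "water" else 1.0}
                                for i in range(n)],
                masses=masses)
            oracle.masses = np.asarray(masses, dtype=float)
        energy.label = label
        return label, topo, frames, energy, oracle

    bundle = CompositeBundle()
    specs = [
        ("X(aq)", "water", True, solute_spring_aq, 0.0, child[0]),
        ("X(oct)", "octanol", True, solute_spring_oct, delta_h, child[1]),
        ("wat", "water", False, None, 0.0, child[2]),
        ("oct", "octanol", False, None, 0.0, child[3]),
    ]
    for label, solvent_species, with_solute, k_s, off, sd in specs:
        label, topo, frames, energy, _ = make(
            label, solvent_species, with_solute, k_s, off, sd)
        bundle.systems[label] = (topo, frames, energy)

    def solute_entropy(k: float) -> float:
        nu = 0.5 * harmonic_frequency(k, solute_mass)   # mean-field halving
        return qho_entropy(ModeSpectrum(np.full(3, nu)), temperature)

    delta_s = solute_entropy(solute_spring_oct) - solute_entropy(solute_spring_aq)
    bundle.oracle = CompositeOracle(delta_h=delta_h, delta_s=delta_s,
                                    temperature=temperature)
    return bundle
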