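# Methods

This note records the model assumptions, the numerical conventions the
package fixes where the theory leaves freedom, what the synthetic fixtures
do and do not establish, and known limitations.

## Model and assumptions

Free energy is taken as G = H − TS per simulation box.  H is the arithmetic
mean of the per-frame total energy; the pressure–volume term is neglected
(it nearly cancels in a transfer between condensed phases at ambient
pressure).  S is the multiscale cell-correlation decomposition: covalently
bonded units are treated as correlated within their parent's reference
frame, while non-bonded units vibrate in a mean-field cell of their
neighbours.  The mean-field approximation is implemented by halving all
force/torque series before covariance accumulation, **except** the
united-atom forces, whose correlations are already represented at the
molecule level.  For the same reason the six lowest-frequency modes of the
UA translational covariance are removed — they reproduce rigid-body
translation and rotation of the whole molecule.

Entropy components are computed per species and per level/motion/minima
slot.  Water is treated only at the molecule level (one united atom);
the package generalises this rule: any molecule with a single united atom
has no UA-level terms.  Monatomic model particles are additionally given
zero rotational degrees of freedom at the molecule level; collinear
polyatomic molecules are rejected rather than approximated.

In solutions, only first-shell solvent molecules contribute: they are less
numerous (hence convergeable) and carry nearly all the solute-induced
change.  The pure-liquid counterpart uses the same mean coordination
number N_c of bulk molecules, pooled over all molecules for statistics.
N_c enters the assembly as the *mean* over frames (a real number) for
consistency with the orientational term, which uses the full p(N_c).

## Units and constants

Internal units are Å, amu, kcal mol⁻¹, K (k_B = 0.0019872041 kcal/mol/K).
Entropies are reported in J K⁻¹ mol⁻¹ (R = 8.314462618) and converted with
the thermochemical calorie (4184 J/kcal) where free energies are
assembled.  The frequency conversion uses the identity amu·N_A = 1 g/mol,
so a covariance eigenvalue in internal units maps to ω² in s⁻² by the
exact factor 4.184×10²⁶.

## Numerical conventions

* **Covariances** are central (mean-subtracted) population second moments,
  accumulated single-pass (sum and outer-product sum).  Nonzero mean
  forces at equilibrium are finite-sampling artifacts; subtracting them
  removes a rank-one bias.  Weighting is applied per sample: forces by
  1/√(unit mass), torques by 1/√(per-frame body-axis moment of inertia).
* **Eigenvalue floors**: eigenvalues below −10⁻⁸·trace/N are an error
  (not a covariance); those in (−10⁻⁸, +10⁻¹²)·trace/N are clipped to
  exactly zero and contribute no entropy — the QHO expression diverges as
  ν→0 and such modes arise only from exact constraints or degenerate
  synthetic inputs.
* **Molecule axes**: principal axes of inertia about the COM, ordered by
  ascending moment.  Sign convention: each of the first two axes is
  flipped so its largest-magnitude component is positive; the third axis
  is their cross product (right-handed).  Frame-to-frame continuity then
  flips signs to match the previous frame, preventing spurious covariance
  from axis flips near moment degeneracies.  Exactly degenerate moments
  (symmetric tops) can still mix eigenvectors within the degenerate
  subspace; the fixtures avoid exact degeneracy and real molecules break
  it thermally.
* **UA axes**: origin at the heavy atom.  With ≥2 heavy neighbours, axis 1
  is the bisector of the two lowest-index bond vectors and axis 2 lies in
  their plane; with one, axis 1 is that bond and axis 2 is built from the
  least-aligned Cartesian axis; with none, the molecule frame is used.
  A UA keeps as many torque components as rotational degrees of freedom
  (3 with ≥2 H, 2 with 1 H, 0 with none); the dropped axis is the one
  with the smallest mean inertia (for a linear UA, the near-bond axis,
  whose inertia vanishes), ties broken by axis index.
* **RAD shells**: candidates sorted by ascending minimum-image COM
  distance, ties broken by molecule index; candidate j is blocked by an
  accepted closer k when 1/r_ij² < (1/r_ik²)·cos θ_jik.  A speed pre-cut
  at twice the first minimum of a coarse COM g(r) is applied only when a
  convincing first minimum exists (an upturn below half the first peak);
  otherwise the cut falls back to half the shortest box edge.  Tests
  assert cut and no-cut shells agree on liquid-like fixtures.
* **Molecule unwrapping** uses the minimum image relative to the first
  atom; a molecule reaching 45% of a box edge is rejected as ambiguous.
  This is adequate for solvents and drug-sized solutes in ≳30 Å boxes.
* **Conformers**: periodic histogram of 72 × 5° bins, 3-bin circular
  moving-average smoothing, maxima above 1% occupancy, boundaries at the
  deepest bin between adjacent maxima.  The smoothing and floor make
  "maxima of the distribution" deterministic on finite samples.  Fewer
  than 50 frames → the dihedral is marked rigid (zero contribution).
* **Conformer correlation matrix**: diagonal = marginal probabilities;
  off-diagonal between different dihedrals = symmetrised joint
  co-occurrence; zero between conformers of one dihedral.  Eigenvalues
  are clipped at zero and renormalised to unit sum.  Normative behaviour:
  a single dihedral reduces exactly to its Shannon entropy, and a
  perfectly correlated pair yields k_B ln 2, not 2 k_B ln 2.  Rigid
  dihedrals are excluded from the matrix.
* **Flexible dihedrals** are auto-detected as one representative
  heavy-atom 4-tuple per rotatable bond (both ends non-terminal in the
  heavy-atom graph, bond not in a ring), with lowest-index neighbours as
  the outer atoms; the topology file can override the list.  One tuple
  per bond is used because the conformer count is a property of the
  torsion, not of the 4-tuple choice.
* **V°** is set to the solution box volume per solute.  It cancels in all
  reported differences (equal box volumes) and is logged for
  transparency.
* **Solution-box solvent sampling**: the solute's shell is evaluated every
  frame and gates which solvent molecules feed the covariance accumulators
  at that frame; the shell members' own coordination statistics are
  sampled on a stride (default 50) since p(N_c) converges orders of
  magnitude faster than covariances.  Solvent conformational entropy is
  averaged over all solvent molecules — conformer populations are
  insensitive to shell membership at the fixture scale, and pure-liquid
  averaging pools all molecules anyway.
* **Replicates**: enthalpies and entropies are averaged over repeats
  first; ΔG and logP are formed from the averages.  The SEM uses the
  sample standard deviation (n−1) over repeats divided by √n.
* Both MAE and RMSE are always reported for predicted-vs-experiment
  comparisons.

## Synthetic fixtures: what they establish

The generators draw configurations from the exact Boltzmann distribution
of simple potentials — no integrator, so oracle tests carry no timestep
bias — and forces satisfy F = −∇U identically.

* `harmonic_liquid`: independent isotropic springs on a lattice.  Exact
  frequencies (1/2π)√(k/m) and QHO entropies; mean energy 3N·k_BT by
  equipartition (half sampled potential, half constant kinetic).  An
  optional AR(1) memory produces time-correlated series with the same
  marginal for robustness checks.
* `dihedral_chain`: multi-well angle series with known populations,
  independent or copy-correlated.
* `toy_shell_geometry`: hand-checkable RAD configurations plus a naive
  reference evaluation of the blocking inequality.
* `composite_solution`: four harmonic boxes with identical solvent
  parameters (all solvent terms cancel in expectation), a prescribed ΔH
  as a constant energy offset, and a solute spring difference fixing ΔS.
  The oracle entropy is the *expectation of the estimator* — the QHO
  entropy at the mean-field-halved frequencies — so the end-to-end test
  probes estimator correctness, not the mean-field approximation itself.

Because the particles are points, these fixtures exercise the
translational-vibrational, positional, orientational and conformational
paths plus the full four-box assembly, but not molecule rotation or UA
torques end-to-end; those stages are pinned by direct geometric oracles
(brute-force r×F, inertia-tensor diagonalisation, equivariance under
random rigid motions).  None of the fixtures mimics real water or octanol
structure: passing tests demonstrate correct estimation for systems obeying
the generating assumptions, not force-field accuracy for real liquids.

## Problem sizes

The defaults keep every oracle comfortably converged on one CPU: harmonic
recovery uses 10⁴–10⁵ frames (frequency error ≲ √(2/n)), conformer tests
use (4–20)×10³ frames (binomial error), and the four-box composite uses
10⁵ frames of 24 solvent particles + 1 solute per box, where the residual
logP error (≲1%) is dominated by the enthalpy means, exactly as in
production use of energy-entropy methods.

## Known limitations

* Orthorhombic (in practice cubic) boxes only; no velocities, restarts, or
  trajectory concatenation; no GROMACS/CHARMM dialects.
* Rotational topographical entropy of united atoms is structurally
  excluded (negligible by rigidity/symmetry/solvent correlation), and
  dissolution of water in octanol is ignored.
* The prmtop reader is a deliberate minimal subset (masses, elements,
  bonds, residue labels); exotic topologies should use the YAML dialect.
* Auto-detected rotatable bonds treat every non-ring bond as single;
  conjugated non-ring double bonds would need an explicit dihedral list.
* Whole-box energies are used for H by default; shell-restricted energies
  would reduce noise but require per-group energy decomposition upstream.
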