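# eemcc — Energy-Entropy Multiscale Cell Correlation

`eemcc` computes absolute entropies, water→octanol transfer free energies
and the partition coefficient logP directly from molecular-dynamics
trajectories that carry **forces** as well as coordinates.  It is aimed at
computational chemists who want a free-energy estimate that also *explains*
where the entropy lives: in which molecules, at which length scale, and in
which kind of motion.

## The method

The free energy of each simulation box is evaluated directly as
G = H − TS.  The enthalpy H is the mean total (potential + kinetic) energy
of the box, neglecting the small pressure–volume term.  The entropy S is a
multiscale sum of components

S = Σ_a Σ_b Σ_c Σ_d S_ab^cd

over molecule kind *a* (solute, water, octanol), level *b* (whole molecule
M, or united atom UA — a heavy atom with its bonded hydrogens as one rigid
body), motion *c* (translation, rotation) and minima type *d* (vibrational
within an energy well, topographical across wells):

* **Vibrational** — each unit vibrates in the mean field of its
  neighbours.  The eigenvalues λᵢ of the mass-weighted force covariance
  matrix (or the moment-of-inertia-weighted torque covariance matrix)
  give frequencies νᵢ = (1/2π)√(λᵢ/k_BT), each contributing a quantum
  harmonic oscillator entropy
  S_vib = k_B Σᵢ [ x/(eˣ−1) − ln(1−e⁻ˣ) ], x = hνᵢ/k_BT.
  Forces and torques are halved in the mean-field approximation except the
  UA forces; the six softest UA translational modes are removed because
  they duplicate whole-molecule motion.
* **Positional** — S_pos = k_B ln(V°/V_solvent), with V_solvent the
  pure-solvent box volume per molecule; V° cancels between solvents.
* **Orientational** — S_or = k_B Σ p(N_c) ln[max(1, (N_c³π)^{1/2}/σ)],
  with N_c the first-shell coordination number from the parameter-free
  Relative Angular Distance (RAD) construction on molecular centres of
  mass, σ the molecular symmetry number (2 for water), and an extra factor
  ¼ inside the logarithm for water's hydrogen-bond directionality.
* **Conformational** — conformers of each flexible dihedral are wells of
  its angle distribution; S_conf = k_B Σ λᵢ ln(1/λᵢ) over the eigenvalues
  of a conformer correlation matrix, so correlated dihedrals are not
  counted twice.

The water→octanol transfer combines four independent boxes — solute in
water X(aq), solute in octanol X(oct), pure water, pure octanol:

ΔG = (G_X(oct) + G_wat) − (G_oct + G_X(aq)),  logP = −ΔG/(ln 10 · k_BT).

Only the solvent molecules in the solute's first shell enter the solution
entropies, balanced by the same count of bulk molecules in the pure
liquids.

## Worked example

The package ships generators for synthetic systems whose entropies are
known in closed form, so the whole pipeline can be validated without an MD
engine.  The four-box composite below prescribes ΔH = −1.364 kcal/mol and
ΔS = 0, hence logP = 1.00 exactly:

```python
from eemcc import composite_solution, composite_transfer

bundle = composite_solution(seed=42, n_frames=20000)
summary = composite_transfer(bundle)
print(f"oracle : dG = {bundle.oracle.delta_g:+.3f}  logP = {bundle.oracle.log_p:.3f}")
print(f"EE-MCC : dG = {summary.delta_g:+.3f}  logP = {summary.log_p:.3f}")
```

prints

```
oracle : dG = -1.364  logP = 1.001
EE-MCC : dG = -1.415  logP = 1.037
```

i.e. the full pipeline — RAD shells, force/torque covariances, QHO
entropies, four-box assembly — recovers the constructed logP to a few
percent at 2×10⁴ frames; the residual is Monte-Carlo noise in the mean
energies and shrinks as 1/√n_frames.

The same machinery is exposed as a CLI (`mcc parse-check`, `mcc shells`,
`mcc vib`, `mcc topo`, `mcc logp`, `mcc synth`) operating on a documented
plain-text fixture dialect, a minimal AMBER prmtop subset, and AMBER
NetCDF trajectories with a `forces` variable.

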