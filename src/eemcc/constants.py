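"""Physical constants and the internal unit system.

Internal units are fixed throughout the package: length in Å, mass in amu,
energy in kcal mol⁻¹, temperature in K.  Entropies are reported in
J K⁻¹ mol⁻¹ (the conventional unit for entropy components) with kcal-based
views available where free energies are assembled.
"""

import math

#: Boltzmann constant in internal units, kcal mol⁻¹ K⁻¹.
KB_KCAL = 0.0019872041

#: Molar gas constant, J K⁻¹ mol⁻¹ (per-mole Boltzmann constant).
R_J = 8.314462618

#: Boltzmann constant, J K⁻¹ (SI, per molecule).
KB_SI = 1.380649e-23

#: Planck constant, J s.
H_PLANCK = 6.62607015e-34

#: Avogadro constant, mol⁻¹.
N_AVOGADRO = 6.02214076e23

#: Thermochemical calorie: 1 kcal = 4184 J exactly.
KCAL_TO_J = 4184.0
J_TO_KCAL = 1.0 / KCAL_TO_J

# Conversion of a squared angular frequency expressed in internal units
# (kcal mol⁻¹ Å⁻² amu⁻¹, i.e. spring constant over mass) into SI s⁻².
# Because amu·N_A = 1 g/mol, the factor collapses to
#   4184 J/kcal / (1e-3 kg/mol / N_A · N_A · 1e-20 m²)  = 4184 / 1e-23.
OMEGA_SQ_TO_SI = KCAL_TO_J / (N_AVOGADRO * 1.0e-20 * (1.0e-3 / N_AVOGADRO))

TWO_PI = 2.0 * math.pi

#: Speed of light in cm/s, for reporting frequencies as wavenumbers.
C_CM_PER_S = 2.99792458e10
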