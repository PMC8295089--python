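"""Vibrational entropy from force/torque covariance matrices.

Within the mean-field cell picture every unit vibrates in an effective
harmonic well.  The well stiffness is read off from force fluctuations: the
eigenvalues λᵢ of the mass-weighted force covariance matrix (translations)
or the moment-of-inertia-weighted torque covariance matrix (rotations)
convert to frequencies

    νᵢ = (1/2π) √(λᵢ / k_B T)

and each frequency contributes a quantum-harmonic-oscillator entropy

    S_vib = k_B Σᵢ [ x/(eˣ − 1) − ln(1 − e⁻ˣ) ],   x = hνᵢ/k_B T.

Weighted samples enter as Fₐ/√mₐ (or τₐ/√Iₐ), so a covariance matrix
element is ⟨Fₐ F_b⟩/√(mₐ m_b); the mean is subtracted, since nonzero mean
forces at equilibrium are sampling artifacts.  The six lowest UA
translational modes duplicate whole-molecule motion and are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (C_CM_PER_S, H_PLANCK, KB_KCAL, KB_SI, OMEGA_SQ_TO_SI,
                        R_J, TWO_PI)

__all__ = [
    "CovarianceAccumulator",
    "ModeSpectrum",
    "frequencies_from_covariance",
    "qho_entropy",
    "qho_entropy_single",
    "remove_lowest_modes",
]

#: eigenvalues below this fraction of trace/N are treated as exact zeros
ZERO_MODE_RTOL = 1e-12
#: most negative eigenvalue tolerated (relative to trace/N) before erroring
PSD_RTOL = 1e-8


@dataclass
class CovarianceAccumulator:
    """Single-pass accumulator for a weighted force/torque covariance.

    Samples are weighted generalized forces of one (level, motion) block of
    one species, pooled over frames (and over all molecules of the species —
    per-molecule matrices would never converge).  The readout is the central
    second moment, symmetric and positive semi-definite up to sampling
    noise.
    """

    dimension: int
    level: str = "M"       # 'M' | 'UA'
    motion: str = "trans"  # 'trans' | 'rot'
    species: str = ""
    _n: int = field(default=0, init=False)
    _sum: np.ndarray = field(init=False, repr=False)
    _outer: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._sum = np.zeros(self.dimension)
        self._outer = np.zeros((self.dimension, self.dimension))

    @property
    def n_samples(self) -> int:
        return self._n

    def add_batch(self, samples: np.ndarray) -> "CovarianceAccumulator":
        """Accumulate a (n_samples, dimension) block of weighted samples."""
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        if samples.shape[1] != self.dimension:
            raise ValueError(
                f"sample dimension {samples.shape[1]} != accumulator "
                f"dimension {self.dimension}")
        self._n += samples.shape[0]
        self._sum += samples.sum(axis=0)
        self._outer += samples.T @ samples
        return self

    def covariance(self) -> np.ndarray:
        """Central covariance ⟨xxᵀ⟩ − ⟨x⟩⟨x⟩ᵀ (population normalisation)."""
        if self._n == 0:
            raise ValueError("no samples accumulated")
        mean = self._sum / self._n
        cov = self._outer / self._n - np.outer(mean, mean)
        return 0.5 * (cov + cov.T)


@dataclass
class ModeSpectrum:
    """Vibrational frequencies (s⁻¹, ascending) with provenance."""

    frequencies: np.ndarray
    level: str = "M"
    motion: str = "trans"
    species: str = ""
    removed_modes: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.sort(np.asarray(self.frequencies, dtype=float))
        if np.any(self.frequencies < 0):
            raise ValueError("negative frequency in mode spectrum")

    @property
    def wavenumbers(self) -> np.ndarray:
        """Frequencies as cm⁻¹."""
        return self.frequencies / C_CM_PER_S

    def __len__(self) -> int:
        return len(self.frequencies)


def frequencies_from_covariance(accumulator_or_matrix,
                                temperature: float,
                                level: str = "M", motion: str = "trans",
                                species: str = "") -> ModeSpectrum:
    """Eigenvalues of a weighted covariance → vibrational frequencies.

    Slightly negative eigenvalues (≥ −1e-8 × trace/N) are sampling noise and
    clipped to zero; eigenvalues below 1e-12 × trace/N are exact-constraint
    zeros and yield ν = 0, which contributes no entropy downstream.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if isinstance(accumulator_or_matrix, CovarianceAccumulator):
        acc = accumulator_or_matrix
        cov, level, motion = acc.covariance(), acc.level, acc.motion
        species = species or acc.species
    else:
        cov = np.asarray(accumulator_or_matrix, dtype=float)
    eigvals = np.linalg.eigvalsh(cov)
    scale = max(np.trace(cov) / max(cov.shape[0], 1), 0.0)
    if np.any(eigvals < -PSD_RTOL * scale):
        raise ValueError(
            f"covariance is not positive semi-definite: min eigenvalue "
            f"{eigvals.min():g} vs trace/N {scale:g}")
    eigvals = np.clip(eigvals, 0.0, None)
    eigvals[eigvals < ZERO_MODE_RTOL * scale] = 0.0
    omega_sq = eigvals * OMEGA_SQ_TO_SI / (KB_KCAL * temperature)
    freqs = np.sqrt(omega_sq) / TWO_PI
    return ModeSpectrum(freqs, level=level, motion=motion, species=species)


def qho_entropy_single(nu: float, temperature: float) -> float:
    """QHO entropy of one mode, J K⁻¹ mol⁻¹.  ν = 0 contributes 0."""
    if nu < 0:
        raise ValueError("negative frequency")
    if nu == 0.0:
        return 0.0
    x = H_PLANCK * nu / (KB_SI * temperature)
    emx = np.exp(-x)
    # x/(eˣ−1) written as x·e⁻ˣ/(1−e⁻ˣ): no overflow for stiff modes
    return R_J * (x * emx / (1.0 - emx) - np.log1p(-emx))


def qho_entropy(spectrum: ModeSpectrum, temperature: float) -> float:
    """Total QHO vibrational entropy of a spectrum, J K⁻¹ mol⁻¹.

    Zero-frequency modes (exact constraints or degenerate inputs) are
    excluded by convention: the classical expression diverges as ν → 0, and
    such modes carry no well-defined vibrational entropy.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    nu = spectrum.frequencies
    nz = nu[nu > 0]
    if nz.size == 0:
        return 0.0
    x = H_PLANCK * nz / (KB_SI * temperature)
    emx = np.exp(-x)
    return float(R_J * np.sum(x * emx / (1.0 - emx) - np.log1p(-emx)))


def remove_lowest_modes(spectrum: ModeSpectrum, n: int = 6) -> ModeSpectrum:
    """Drop the n lowest UA translational modes.

    Whole-molecule translation and rotation reappear as the six softest
    modes of the united-atom force covariance matrix; removing them avoids
    double counting with the molecule level.  Applying this to any other
    (level, motion) block is a contract violation.
    """
    if not (spectrum.level == "UA" and spectrum.motion == "trans"):
        raise ValueError(
            f"mode removal applies only to UA translational spectra, not "
            f"({spectrum.level}, {spectrum.motion})")
    if len(spectrum) < n:
        raise ValueError(
            f"spectrum has {len(spectrum)} modes; cannot remove {n}")
    return ModeSpectrum(spectrum.frequencies[n:], level=spectrum.level,
                        motion=spectrum.motion, species=spectrum.species,
                        removed_modes=n)
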