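"""Topographical entropy: positional, orientational and conformational.

Topographical entropy counts discrete energy wells and their probabilities,
complementing the vibrational entropy within each well.

* Positional (molecule translation): the volume V° available to a dilute
  solute is discretised by the solvent molecular volume,
  S_pos = k_B ln(V°/V_solvent).  V° cancels between the two solvents, so
  the water→octanol transfer term depends only on the solvent molecular
  volumes.
* Orientational (molecule rotation): the number of distinguishable
  orientations grows with coordination number as Ω = (N_c³ π)^½ / σ,
  clamped below at one, and weighted by the observed p(N_c).  Water gets an
  extra factor ¼ inside the logarithm for hydrogen-bond directionality.
* Conformational (united-atom translation): flexible-dihedral conformers
  are identified from the maxima of each angle distribution; the entropy is
  −k_B Σ λ ln λ over the eigenvalues of a conformer correlation matrix, so
  correlated dihedrals are not double counted.

All entropies are returned in J K⁻¹ mol⁻¹.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import R_J
from .rad_shells import minimum_image

__all__ = [
    "DihedralStateSeries",
    "positional_entropy",
    "positional_transfer_entropy",
    "orientational_entropy",
    "dihedral_angles",
    "assign_conformers",
    "conformational_entropy",
]

MIN_FRAMES_FOR_CONFORMERS = 50
DEFAULT_N_BINS = 72           # 5° bins
MAXIMUM_FLOOR = 0.01          # peaks below 1% occupancy are noise


# ---------------------------------------------------------------------------
# positional
# ---------------------------------------------------------------------------

def positional_entropy(v_standard: float, v_solvent: float) -> float:
    """S_pos = k_B ln(V°/V_solvent), J K⁻¹ mol⁻¹ (volumes in Å³)."""
    if v_standard <= 0 or v_solvent <= 0:
        raise ValueError("volumes must be positive")
    return R_J * math.log(v_standard / v_solvent)


def positional_transfer_entropy(v_solvent_from: float,
                                v_solvent_to: float) -> float:
    """ΔS_pos for transfer between solvents with the given per-molecule
    volumes (Å³); the standard-state volume V° cancels."""
    if v_solvent_from <= 0 or v_solvent_to <= 0:
        raise ValueError("volumes must be positive")
    return R_J * math.log(v_solvent_from / v_solvent_to)


# ---------------------------------------------------------------------------
# orientational
# ---------------------------------------------------------------------------

def orientational_entropy(p_nc: dict[int, float], sigma: float,
                          is_water: bool = False) -> float:
    """S_or = k_B Σ p(N_c) ln[max(1, Ω(N_c))], J K⁻¹ mol⁻¹.

    Ω = (N_c³ π)^½ / σ; for water an additional factor ¼ multiplies Ω
    inside the logarithm (hydrogen-bond directionality) before clamping.
    """
    if sigma < 1:
        raise ValueError(f"symmetry number {sigma} < 1")
    total = sum(p_nc.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"p(Nc) sums to {total}, expected 1")
    s = 0.0
    for nc, p in p_nc.items():
        if nc < 0:
            raise ValueError(f"negative coordination number {nc}")
        omega = math.sqrt(nc**3 * math.pi) / sigma
        if is_water:
            omega *= 0.25
        s += p * math.log(max(1.0, omega))
    return R_J * s


# ---------------------------------------------------------------------------
# dihedral angles and conformer assignment
# ---------------------------------------------------------------------------

def dihedral_angles(coords: np.ndarray, box: np.ndarray,
                    quad: tuple[int, int, int, int]) -> np.ndarray:
    """Dihedral angle (degrees, in [0, 360)) for atoms a–b–c–d, per frame.

    ``coords`` is (n_frames, n_atoms, 3); bond vectors use the minimum
    image so wrapped molecules are handled.
    """
    a, b, c, d = quad
    b1 = minimum_image(coords[:, b] - coords[:, a], box)
    b2 = minimum_image(coords[:, c] - coords[:, b], box)
    b3 = minimum_image(coords[:, d] - coords[:, c], box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("fi,fi->f", n1, n2)
    y = np.einsum("fi,fi->f", m1, n2)
    return np.degrees(np.arctan2(y, x)) % 360.0


@dataclass
class DihedralStateSeries:
    """Per-frame conformer labels of one flexible dihedral."""

    labels: np.ndarray            # (n_frames,) ints in [0, n_conformers)
    n_conformers: int
    boundaries: np.ndarray        # degrees, one boundary per conformer
    angles: np.ndarray | None = None

    @property
    def probabilities(self) -> np.ndarray:
        return np.bincount(self.labels,
                           minlength=self.n_conformers) / len(self.labels)

    @property
    def shannon_entropy(self) -> float:
        """Marginal Shannon entropy of the conformer distribution, J/K/mol."""
        p = self.probabilities
        p = p[p > 0]
        return float(-R_J * np.sum(p * np.log(p)))


def assign_conformers(angle_series: np.ndarray,
                      n_bins: int = DEFAULT_N_BINS) -> DihedralStateSeries:
    """Label each frame with a conformer from the angle distribution.

    A periodic histogram (default 72 × 5° bins) is smoothed with a 3-bin
    circular moving average; local maxima above a 1% occupancy floor define
    conformers, with boundaries at the minima between adjacent maxima.
    Fewer than 50 frames cannot support a distribution — the dihedral is
    marked rigid (one conformer, zero entropy contribution).
    """
    angles = np.asarray(angle_series, dtype=float).ravel() % 360.0
    n = angles.size
    if n < MIN_FRAMES_FOR_CONFORMERS:
        warnings.warn(
            f"only {n} frames for dihedral; marking it rigid", stacklevel=2)
        return DihedralStateSeries(labels=np.zeros(n, dtype=int),
                                   n_conformers=1,
                                   boundaries=np.array([0.0]), angles=angles)
    width = 360.0 / n_bins
    hist, _ = np.histogram(angles, bins=n_bins, range=(0.0, 360.0))
    smoothed = (hist + np.roll(hist, 1) + np.roll(hist, -1)) / 3.0
    floor = MAXIMUM_FLOOR * n
    is_max = ((smoothed > np.roll(smoothed, 1))
              & (smoothed >= np.roll(smoothed, -1))
              & (smoothed >= floor))
    maxima = np.flatnonzero(is_max)
    if maxima.size <= 1:
        return DihedralStateSeries(labels=np.zeros(n, dtype=int),
                                   n_conformers=1,
                                   boundaries=np.array([0.0]), angles=angles)
    # boundary between consecutive maxima (circularly): deepest bin between
    boundaries = []
    for i, m in enumerate(maxima):
        nxt = maxima[(i + 1) % maxima.size]
        span = (nxt - m) % n_bins
        seg = [(m + k) % n_bins for k in range(1, span)] or [m]
        low = min(seg, key=lambda b: (smoothed[b], b))
        boundaries.append(((low + 1) % n_bins) * width)
    boundaries = np.sort(np.array(boundaries))
    labels = np.searchsorted(boundaries, angles, side="left") % maxima.size
    return DihedralStateSeries(labels=labels, n_conformers=maxima.size,
                               boundaries=boundaries, angles=angles)


# ---------------------------------------------------------------------------
# conformational entropy
# ---------------------------------------------------------------------------

def conformational_entropy(state_series: list[DihedralStateSeries]) -> float:
    """S_conf from the conformer correlation matrix, J K⁻¹ mol⁻¹.

    The matrix is indexed by (dihedral, conformer) pairs: the diagonal
    holds marginal conformer probabilities, off-diagonal entries between
    different dihedrals hold joint co-occurrence probabilities, and entries
    between conformers of the same dihedral are zero.  Its eigenvalues are
    clipped at zero and renormalised to sum to one; the entropy is the
    eigenvalue Shannon entropy, which reduces to the marginal Shannon
    entropy for a single dihedral and does not double count perfectly
    correlated dihedrals.

    Rigid dihedrals (a single conformer) contribute nothing and are
    excluded from the matrix.
    """
    active = [s for s in state_series if s.n_conformers > 1]
    if not active:
        return 0.0
    n_frames = len(active[0].labels)
    for s in active:
        if len(s.labels) != n_frames:
            raise ValueError("dihedral series have mismatched frame counts")
    offsets = np.cumsum([0] + [s.n_conformers for s in active])
    dim = int(offsets[-1])
    m = np.zeros((dim, dim))
    for i, s in enumerate(active):
        p = s.probabilities
        sl = slice(offsets[i], offsets[i + 1])
        m[sl, sl] = np.diag(p)
        for j in range(i + 1, len(active)):
            t = active[j]
            joint = np.zeros((s.n_conformers, t.n_conformers))
            np.add.at(joint, (s.labels, t.labels), 1.0)
            joint /= n_frames
            sl2 = slice(offsets[j], offsets[j + 1])
            m[sl, sl2] = joint
            m[sl2, sl] = joint.T
    eigvals = np.linalg.eigvalsh(m)
    eigvals = np.clip(eigvals, 0.0, None)
    total = eigvals.sum()
    if total <= 0:
        raise ValueError("conformer correlation matrix is all zero")
    lam = eigvals / total
    lam = lam[lam > 0]
    return float(-R_J * np.sum(lam * np.log(lam)))
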