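"""First-solvation-shell detection with the Relative Angular Distance rule.

Shells are built on molecular centres of mass under the minimum-image
convention.  A candidate neighbour j of centre i (taken in order of
increasing distance) joins the shell unless some already-accepted closer
neighbour k blocks it:

    1/r_ij² < (1/r_ik²)·cos θ_jik

with θ_jik the angle at i between j and k.  The rule is parameter-free: a
closer neighbour shadows an angular cone behind it, so the shell closes
itself once the accepted set covers all directions.

Coordination-number statistics p(Nc) feed the orientational entropy; for a
solute the central molecule is fixed, while for a pure liquid every molecule
of the species is pooled over all frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .md_io import FrameSet, MolecularTopology

__all__ = [
    "ShellStatistics",
    "GeometryError",
    "centers_of_mass",
    "rad_shell",
    "estimate_rad_cutoff",
    "shell_statistics",
]


class GeometryError(ValueError):
    """Raised for degenerate or unsupported geometries."""


@dataclass
class ShellStatistics:
    """Coordination-number distribution accumulated over frames."""

    counts: dict[int, int]
    per_frame_shells: list[frozenset[int]] | None = None

    @property
    def n_samples(self) -> int:
        return sum(self.counts.values())

    @property
    def p_nc(self) -> dict[int, float]:
        total = self.n_samples
        return {nc: c / total for nc, c in sorted(self.counts.items())}

    @property
    def mean_nc(self) -> float:
        total = self.n_samples
        return sum(nc * c for nc, c in self.counts.items()) / total


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the primary image (orthorhombic box)."""
    return delta - box * np.round(delta / box)


def unwrap_molecule(coords: np.ndarray, box: np.ndarray,
                    check: bool = True) -> np.ndarray:
    """Unwrap a molecule's atoms relative to its first atom.

    ``coords`` is (..., n_atoms, 3); ``box`` broadcasts as (..., 3).  Valid
    for molecules compact relative to the box: a molecule reaching (nearly)
    half the box makes the minimum-image reconstruction ambiguous and is a
    geometry error.
    """
    first = coords[..., :1, :]
    delta = minimum_image(coords - first, box[..., None, :])
    if check and np.any(np.abs(delta) > 0.45 * box[..., None, :]):
        raise GeometryError(
            "molecule spans more than half the box after unwrapping; "
            "minimum-image reconstruction is ambiguous")
    return first + delta


def centers_of_mass(frames: FrameSet,
                    topology: MolecularTopology) -> np.ndarray:
    """Per-molecule COM positions, shape (n_frames, n_molecules, 3).

    Each molecule is unwrapped about its first atom before mass averaging;
    the COM is then wrapped back into the primary box [0, L).
    """
    masses = topology.masses
    out = np.empty((frames.n_frames, len(topology.molecules), 3))
    for mi, mol in enumerate(topology.molecules):
        idx = list(mol.atom_indices)
        m = masses[idx]
        if np.any(m <= 0):
            raise GeometryError(f"molecule {mi} has non-positive masses")
        unwrapped = unwrap_molecule(frames.coordinates[:, idx, :], frames.box)
        com = (unwrapped * m[None, :, None]).sum(axis=1) / m.sum()
        out[:, mi, :] = com % frames.box
    return out


def rad_shell(com_positions: np.ndarray, center_index: int,
              box: np.ndarray, rcut: float | None = None) -> frozenset[int]:
    """First-shell molecule indices around one centre in one frame.

    ``rcut`` is a pure speed pre-cut on candidates; it must not exclude any
    acceptable neighbour (if it empties the candidate list it is lifted).
    Ties in distance are broken by molecule index so the result is
    deterministic.
    """
    com = np.asarray(com_positions, dtype=float)
    n = com.shape[0]
    if n < 2:
        raise GeometryError("need at least one candidate neighbour")
    others = np.array([j for j in range(n) if j != center_index])
    d = minimum_image(com[others] - com[center_index], np.asarray(box, float))
    r2 = (d * d).sum(axis=1)
    if np.any(r2 <= 0.0):
        bad = others[r2 <= 0.0]
        raise GeometryError(
            f"molecule(s) {bad.tolist()} coincide with centre "
            f"{center_index} (r = 0)")
    if rcut is not None:
        keep = r2 <= rcut * rcut
        if np.any(keep):
            others, d, r2 = others[keep], d[keep], r2[keep]
    # stable sort: ascending distance, ties by molecule index (already the
    # order within 'others')
    order = np.argsort(r2, kind="stable")
    others, d, r2 = others[order], d[order], r2[order]
    inv_r2 = 1.0 / r2
    r = np.sqrt(r2)
    accepted: list[int] = []
    for j in range(len(others)):
        blocked = False
        for k in accepted:
            cos_jik = float(d[j] @ d[k]) / (r[j] * r[k])
            if inv_r2[j] < inv_r2[k] * cos_jik:
                blocked = True
                break
        if not blocked:
            accepted.append(j)
    return frozenset(int(others[j]) for j in accepted)


def estimate_rad_cutoff(com: np.ndarray, box: np.ndarray,
                        fallback: float = 12.0) -> float:
    """Cheap candidate pre-cut: 2× the first minimum of the COM g(r).

    Uses a coarse pair-distance histogram of one frame; falls back to 12 Å
    when no clear first minimum exists.  Always capped at half the shortest
    box edge so minimum-image distances stay unambiguous.
    """
    box = np.asarray(box, dtype=float)
    cap = 0.5 * float(box.min())
    n = com.shape[0]
    if n < 8:
        return min(fallback, cap)
    d = minimum_image(com[:, None, :] - com[None, :, :], box)
    r = np.sqrt((d * d).sum(axis=-1))[np.triu_indices(n, k=1)]
    bins = np.arange(0.0, cap, 0.25)
    if len(bins) < 8:
        return cap
    hist, edges = np.histogram(r, bins=bins)
    # shell-volume normalisation so the histogram approximates g(r)
    centers = 0.5 * (edges[:-1] + edges[1:])
    gr = hist / np.maximum(centers**2, 1e-12)
    gr = np.convolve(gr, np.ones(3) / 3.0, mode="same")
    peak = int(np.argmax(gr))
    for i in range(peak + 1, len(gr) - 1):
        # a convincing first minimum: an upturn well below the first peak
        if gr[i] <= gr[i + 1] and gr[i] < 0.5 * gr[peak]:
            return float(min(max(2.0 * centers[i], 4.0), cap))
    # no clear solvation structure: do not risk cutting acceptable neighbours
    return cap


def shell_statistics(com_series: np.ndarray, box_series: np.ndarray,
                     center_selector: int | list[int],
                     stride: int = 1, rcut: float | None = None,
                     keep_shells: bool = False) -> ShellStatistics:
    """Pool RAD shells into a coordination-number distribution.

    ``center_selector`` is a single molecule index (solute) or a list of
    indices (all molecules of a species, pooled for better statistics).
    ``stride`` subsamples frames — p(Nc) converges far faster than the
    vibrational accumulators, so sparse sampling is sufficient.
    """
    com_series = np.asarray(com_series, dtype=float)
    if com_series.ndim != 3:
        raise ValueError("com_series must be (n_frames, n_molecules, 3)")
    if com_series.shape[0] == 0:
        raise ValueError("empty frame set")
    centers = [center_selector] if np.isscalar(center_selector) \
        else list(center_selector)
    counts: dict[int, int] = {}
    shells: list[frozenset[int]] | None = [] if keep_shells else None
    cut = rcut if rcut is not None else \
        estimate_rad_cutoff(com_series[0], box_series[0])
    for f in range(0, com_series.shape[0], stride):
        box = box_series[f]
        for c in centers:
            shell = rad_shell(com_series[f], int(c), box, rcut=cut)
            nc = len(shell)
            counts[nc] = counts.get(nc, 0) + 1
            if shells is not None:
                shells.append(shell)
    return ShellStatistics(counts=counts, per_frame_shells=shells)
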