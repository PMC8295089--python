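"""Body-fixed reference frames and generalized forces.

Molecules vibrate as rigid units in the mean field of their neighbours;
their reference frame is the principal-axis frame at the centre of mass.
United atoms (a heavy atom plus its bonded hydrogens) use the heavy atom as
origin with axes derived from the covalent bonds to neighbouring heavy
atoms.  Atomic forces are summed into net forces and torques expressed in
these frames; the mean-field approximation halves every series except the
united-atom forces, whose correlations are already captured at the molecule
level.

Axis conventions are fixed so covariances accumulate in a consistent frame:
eigenvectors are ordered by ascending moment of inertia, each of the first
two axes is flipped so its largest-magnitude component is positive, the
third axis completes a right-handed set, and frame-to-frame sign continuity
is enforced to stop near-degenerate moments flipping axes mid-trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .md_io import FrameSet, MolecularTopology, Molecule
from .rad_shells import GeometryError, unwrap_molecule

__all__ = [
    "HALVING_FACTORS",
    "BodyFrameSeries",
    "GeneralizedForceSeries",
    "molecule_frame",
    "united_atom_dof",
    "ua_axes",
    "net_force_torque",
    "molecule_generalized_forces",
    "ua_generalized_forces",
]

#: Mean-field halving factors by (level, motion).  Only the united-atom
#: force covariance escapes halving.
HALVING_FACTORS = {
    ("M", "trans"): 0.5,
    ("M", "rot"): 0.5,
    ("UA", "trans"): 1.0,
    ("UA", "rot"): 0.5,
}

_COLLINEAR_RTOL = 1e-8


@dataclass
class BodyFrameSeries:
    """Per-frame origin, orthonormal axes (rows) and inertia moments."""

    origin: np.ndarray    # (F, 3) Å
    axes: np.ndarray      # (F, 3, 3), rows are the body axes
    moments: np.ndarray   # (F, 3) amu Å², ascending


@dataclass
class GeneralizedForceSeries:
    """Net body-frame forces/torques for one unit, with halving provenance."""

    level: str            # 'M' | 'UA'
    force: np.ndarray     # (F, 3) kcal mol⁻¹ Å⁻¹ (halving already applied)
    torque: np.ndarray    # (F, n_rot) kcal mol⁻¹ rad⁻¹
    rot_axes_kept: tuple[int, ...]
    halving: dict[str, float]
    moments: np.ndarray   # (F, n_rot) amu Å² about the kept axes
    mass: float           # total unit mass, amu


def _apply_sign_convention(axes: np.ndarray) -> np.ndarray:
    """Flip each of the first two axes so its largest component is positive."""
    axes = axes.copy()
    for k in (0, 1):
        a = axes[:, k, :]
        comp = np.argmax(np.abs(a), axis=1)
        sign = np.sign(np.take_along_axis(a, comp[:, None], axis=1))[:, 0]
        sign[sign == 0] = 1.0
        axes[:, k, :] = a * sign[:, None]
    return axes


def _apply_continuity(axes: np.ndarray) -> np.ndarray:
    """Cumulative sign matching of axes 0 and 1 to the previous frame."""
    if axes.shape[0] < 2:
        return axes
    axes = axes.copy()
    for k in (0, 1):
        dots = np.einsum("fi,fi->f", axes[1:, k, :], axes[:-1, k, :])
        s = np.sign(dots)
        s[s == 0] = 1.0
        flips = np.concatenate([[1.0], np.cumprod(s)])
        axes[:, k, :] *= flips[:, None]
    return axes


def molecule_frame(frames: FrameSet, topology: MolecularTopology,
                   mol_index: int) -> BodyFrameSeries:
    """Principal-axis frames of one molecule for every frame.

    A single-atom molecule gets laboratory axes and zero moments (it has no
    rotational degrees of freedom); a collinear polyatomic molecule is
    rejected — all species treated here are non-linear.
    """
    mol = topology.molecules[mol_index]
    idx = list(mol.atom_indices)
    coords = unwrap_molecule(frames.coordinates[:, idx, :], frames.box)
    m = topology.masses[idx]
    com = (coords * m[None, :, None]).sum(axis=1) / m.sum()
    n_frames = frames.n_frames
    if len(idx) == 1:
        eye = np.broadcast_to(np.eye(3), (n_frames, 3, 3)).copy()
        return BodyFrameSeries(origin=com, axes=eye,
                               moments=np.zeros((n_frames, 3)))
    rel = coords - com[:, None, :]
    r2 = (rel * rel).sum(axis=-1)
    inertia = (np.einsum("a,fa->f", m, r2)[:, None, None] * np.eye(3)
               - np.einsum("a,fai,faj->fij", m, rel, rel))
    moments, vecs = np.linalg.eigh(inertia)
    if np.any(moments[:, 0] < _COLLINEAR_RTOL * np.maximum(moments[:, 2], 1e-30)):
        raise GeometryError(
            f"molecule {mol_index} is (near-)collinear; molecule-level "
            f"rotation is undefined for linear bodies")
    axes = _apply_continuity(_apply_sign_convention(vecs.transpose(0, 2, 1)))
    axes[:, 2, :] = np.cross(axes[:, 0, :], axes[:, 1, :])
    return BodyFrameSeries(origin=com, axes=axes,
                           moments=np.maximum(moments, 0.0))


def united_atom_dof(topology: MolecularTopology,
                    mol_index: int) -> list[tuple[int, int]]:
    """(n_trans, n_rot) per united atom: 3 translations always; rotations
    are 3 for a non-linear UA (≥2 H), 2 for a linear one (1 H), 0 for a
    bare heavy atom."""
    out = []
    for ua in topology.molecules[mol_index].united_atoms:
        n_h = ua.n_hydrogens
        out.append((3, 3 if n_h >= 2 else (2 if n_h == 1 else 0)))
    return out


def _heavy_neighbours(topology: MolecularTopology, mol: Molecule,
                      heavy: int) -> list[int]:
    return [b for b in topology.atoms[heavy].bonded
            if b in mol.atom_indices and not topology.atoms[b].is_hydrogen]


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _single_bond_axes(b1: np.ndarray) -> np.ndarray:
    """Deterministic frame from one bond vector: axis1 along the bond,
    axis2 built from the least-aligned Cartesian axis."""
    n_frames = b1.shape[0]
    a1 = _normalize(b1)
    e_idx = np.argmin(np.abs(a1), axis=1)
    e = np.zeros((n_frames, 3))
    e[np.arange(n_frames), e_idx] = 1.0
    a2 = _normalize(e - np.einsum("fi,fi->f", e, a1)[:, None] * a1)
    a3 = np.cross(a1, a2)
    return np.stack([a1, a2, a3], axis=1)


def ua_axes(frames: FrameSet, topology: MolecularTopology,
            mol_index: int) -> list[BodyFrameSeries]:
    """Bond-derived body frames of every united atom in one molecule.

    ≥2 heavy neighbours: axis1 along the bisector of the two lowest-index
    bond vectors, axis2 in their plane; exactly 1: axis1 along that bond
    with a deterministic perpendicular; 0 (isolated UA): falls back to the
    molecule's principal-axis frame.  Moments are the diagonal elements of
    the UA inertia tensor (about the heavy atom) in the body frame.
    """
    mol = topology.molecules[mol_index]
    idx = list(mol.atom_indices)
    coords = unwrap_molecule(frames.coordinates[:, idx, :], frames.box)
    pos_of = {ai: k for k, ai in enumerate(idx)}
    masses = topology.masses
    out = []
    mol_fallback: BodyFrameSeries | None = None
    for ua in mol.united_atoms:
        origin = coords[:, pos_of[ua.heavy], :]
        hnb = _heavy_neighbours(topology, mol, ua.heavy)
        if len(hnb) >= 2:
            b1 = coords[:, pos_of[hnb[0]], :] - origin
            b2 = coords[:, pos_of[hnb[1]], :] - origin
            u1, u2 = _normalize(b1), _normalize(b2)
            bis = u1 + u2
            norm = np.linalg.norm(bis, axis=1)
            if np.any(norm < 1e-8):  # exactly opposed bonds: degenerate bisector
                axes = _single_bond_axes(b1)
            else:
                a1 = bis / norm[:, None]
                a2 = _normalize(u1 - np.einsum("fi,fi->f", u1, a1)[:, None] * a1)
                a3 = np.cross(a1, a2)
                axes = np.stack([a1, a2, a3], axis=1)
        elif len(hnb) == 1:
            axes = _single_bond_axes(coords[:, pos_of[hnb[0]], :] - origin)
        else:
            if mol_fallback is None:
                mol_fallback = molecule_frame(frames, topology, mol_index)
            axes = mol_fallback.axes
        # UA inertia about the heavy atom; only hydrogens contribute
        moments = np.zeros((frames.n_frames, 3))
        for h in ua.hydrogens:
            d = coords[:, pos_of[h], :] - origin
            d2 = (d * d).sum(axis=1)
            proj = np.einsum("fai,fi->fa", axes, d)  # (F, 3)
            moments += masses[h] * (d2[:, None] - proj**2)
        out.append(BodyFrameSeries(origin=origin, axes=axes, moments=moments))
    return out


def net_force_torque(coords_unit: np.ndarray, forces_unit: np.ndarray,
                     body: BodyFrameSeries,
                     halve: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Net force and torque of a unit, rotated into its body frame.

    ``coords_unit`` must already be unwrapped consistently with the frame
    origin.  Returns ((F, 3) force, (F, 3) torque), both scaled by
    ``halve``.
    """
    f_lab = forces_unit.sum(axis=1)
    rel = coords_unit - body.origin[:, None, :]
    t_lab = np.cross(rel, forces_unit).sum(axis=1)
    f_body = np.einsum("fij,fj->fi", body.axes, f_lab)
    t_body = np.einsum("fij,fj->fi", body.axes, t_lab)
    return halve * f_body, halve * t_body


def molecule_generalized_forces(frames: FrameSet, topology: MolecularTopology,
                                mol_index: int) -> GeneralizedForceSeries:
    """Molecule-level net force/torque series in the principal-axis frame.

    Both series are halved (mean-field rule).  Monatomic molecules carry no
    rotational coordinates.
    """
    mol = topology.molecules[mol_index]
    idx = list(mol.atom_indices)
    body = molecule_frame(frames, topology, mol_index)
    coords = unwrap_molecule(frames.coordinates[:, idx, :], frames.box)
    force, torque = net_force_torque(
        coords, frames.forces[:, idx, :], body,
        halve=1.0)
    h_f = HALVING_FACTORS[("M", "trans")]
    h_t = HALVING_FACTORS[("M", "rot")]
    n_rot = 0 if len(idx) == 1 else 3
    kept = tuple(range(n_rot))
    return GeneralizedForceSeries(
        level="M",
        force=h_f * force,
        torque=h_t * torque[:, :n_rot],
        rot_axes_kept=kept,
        halving={"force": h_f, "torque": h_t},
        moments=body.moments[:, :n_rot],
        mass=float(topology.masses[idx].sum()),
    )


def ua_generalized_forces(frames: FrameSet, topology: MolecularTopology,
                          mol_index: int) -> list[GeneralizedForceSeries]:
    """United-atom force/torque series for one molecule.

    UA forces are NOT halved; UA torques are.  A UA keeps as many torque
    components as it has rotational degrees of freedom — the axes with the
    smallest mean inertia are dropped first (a linear UA has no inertia
    about its bond axis), with ties broken by axis index.
    """
    mol = topology.molecules[mol_index]
    idx = list(mol.atom_indices)
    coords = unwrap_molecule(frames.coordinates[:, idx, :], frames.box)
    pos_of = {ai: k for k, ai in enumerate(idx)}
    bodies = ua_axes(frames, topology, mol_index)
    dof = united_atom_dof(topology, mol_index)
    h_t = HALVING_FACTORS[("UA", "rot")]
    h_f = HALVING_FACTORS[("UA", "trans")]
    out = []
    for ua, body, (_, n_rot) in zip(mol.united_atoms, bodies, dof):
        apos = [pos_of[a] for a in ua.atoms]
        force, torque = net_force_torque(
            coords[:, apos, :], frames.forces[:, [idx[p] for p in apos], :],
            body, halve=1.0)
        mean_i = body.moments.mean(axis=0)
        kept = tuple(sorted(np.argsort(-mean_i, kind="stable")[:n_rot].tolist()))
        out.append(GeneralizedForceSeries(
            level="UA",
            force=h_f * force,
            torque=h_t * torque[:, list(kept)] if n_rot else
            np.empty((frames.n_frames, 0)),
            rot_axes_kept=kept,
            halving={"force": h_f, "torque": h_t},
            moments=body.moments[:, list(kept)] if n_rot else
            np.empty((frames.n_frames, 0)),
            mass=float(topology.masses[list(ua.atoms)].sum()),
        ))
    return out
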