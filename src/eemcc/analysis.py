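"""Whole-box analysis: from frames with forces to an entropy breakdown.

This module wires the stages together.  For each simulation box it

1. computes molecular centres of mass and RAD first shells,
2. accumulates molecule-level and united-atom-level force/torque
   covariances (pooled per species, with the mean-field halving rules),
3. converts covariance eigenvalues to frequencies and QHO entropies,
4. evaluates positional, orientational and conformational terms,
5. assembles a :class:`~eemcc.energy_logp.SystemResult`.

In a solution box only the solvent molecules inside the solute's first
shell contribute vibrational and orientational statistics; in a pure
liquid all molecules are pooled.  Coordination-number statistics converge
much faster than covariances, so shell membership of shell members
themselves is sampled on a stride.
"""

from __future__ import annotations

import numpy as np

from .body_frames import molecule_generalized_forces, ua_generalized_forces
from .energy_logp import SystemResult, mean_enthalpy
from .md_io import EnergySeries, FrameSet, MolecularTopology
from .rad_shells import (centers_of_mass, estimate_rad_cutoff, rad_shell,
                         shell_statistics)
from .topographical import (assign_conformers, conformational_entropy,
                            dihedral_angles, orientational_entropy,
                            positional_entropy)
from .vibrational import (CovarianceAccumulator, frequencies_from_covariance,
                          qho_entropy, remove_lowest_modes)

__all__ = [
    "species_vibrational_terms",
    "species_conformational_entropy",
    "analyze_pure_liquid",
    "analyze_solution",
    "composite_transfer",
]

_TINY_INERTIA = 1e-12


def _weighted_mol_samples(gfs) -> tuple[np.ndarray, np.ndarray]:
    """Mass- and inertia-weighted molecule-level samples for one molecule."""
    trans = gfs.force / np.sqrt(gfs.mass)
    if gfs.torque.shape[1]:
        rot = gfs.torque / np.sqrt(np.maximum(gfs.moments, _TINY_INERTIA))
    else:
        rot = np.empty((gfs.force.shape[0], 0))
    return trans, rot


def species_vibrational_terms(frames: FrameSet, topology: MolecularTopology,
                              mol_indices: list[int],
                              member_mask: np.ndarray | None = None,
                              species: str = "",
                              ) -> dict[str, float]:
    """Per-molecule vibrational entropies of one species, J K⁻¹ mol⁻¹.

    Covariances pool all listed molecules (and, if ``member_mask`` is given
    as a (n_frames, n_molecules) boolean array, only the frames where each
    molecule is a first-shell member).  Molecules with a single united atom
    are treated only at the molecule level: their UA slots are zero.
    """
    t = frames.temperature
    first = topology.molecules[mol_indices[0]]
    n_ua = len(first.united_atoms)
    ua_active = n_ua > 1
    acc_mt = CovarianceAccumulator(3, "M", "trans", species)
    is_monatomic = first.n_atoms == 1
    acc_mr = None if is_monatomic else CovarianceAccumulator(3, "M", "rot",
                                                             species)
    acc_ut = acc_ur = None
    if ua_active:
        dim_ut = 3 * n_ua
        acc_ut = CovarianceAccumulator(dim_ut, "UA", "trans", species)
    for mi in mol_indices:
        sel = None if member_mask is None else member_mask[:, mi]
        gfs = molecule_generalized_forces(frames, topology, mi)
        trans, rot = _weighted_mol_samples(gfs)
        acc_mt.add_batch(trans if sel is None else trans[sel])
        if acc_mr is not None:
            acc_mr.add_batch(rot if sel is None else rot[sel])
        if ua_active:
            uas = ua_generalized_forces(frames, topology, mi)
            ut = np.concatenate(
                [u.force / np.sqrt(u.mass) for u in uas], axis=1)
            acc_ut.add_batch(ut if sel is None else ut[sel])
            ur_parts = [u.torque / np.sqrt(np.maximum(u.moments,
                                                      _TINY_INERTIA))
                        for u in uas if u.torque.shape[1]]
            if ur_parts:
                ur = np.concatenate(ur_parts, axis=1)
                if acc_ur is None:
                    acc_ur = CovarianceAccumulator(ur.shape[1], "UA", "rot",
                                                   species)
                acc_ur.add_batch(ur if sel is None else ur[sel])
    terms = {
        "M_transvib": qho_entropy(
            frequencies_from_covariance(acc_mt, t), t),
        "M_rovib": 0.0 if acc_mr is None else qho_entropy(
            frequencies_from_covariance(acc_mr, t), t),
    }
    if ua_active:
        spec_ut = frequencies_from_covariance(acc_ut, t)
        if len(spec_ut) >= 6:
            spec_ut = remove_lowest_modes(spec_ut, 6)
        terms["UA_transvib"] = qho_entropy(spec_ut, t)
        terms["UA_rovib"] = 0.0 if acc_ur is None else qho_entropy(
            frequencies_from_covariance(acc_ur, t), t)
    else:
        terms["UA_transvib"] = 0.0
        terms["UA_rovib"] = 0.0
    return terms


def species_conformational_entropy(frames: FrameSet,
                                   topology: MolecularTopology,
                                   mol_indices: list[int]) -> float:
    """Mean per-molecule conformational entropy of a species, J/K/mol."""
    values = []
    for mi in mol_indices:
        quads = topology.molecules[mi].flexible_dihedrals
        if not quads:
            values.append(0.0)
            continue
        series = [assign_conformers(
            dihedral_angles(frames.coordinates, frames.box, q))
            for q in quads]
        values.append(conformational_entropy(series))
    return float(np.mean(values))


def analyze_pure_liquid(frames: FrameSet, energy: EnergySeries,
                        topology: MolecularTopology, species: str,
                        shell_stride: int = 50) -> SystemResult:
    """Analyse a pure-liquid box; solvent terms are per-molecule."""
    mols = topology.molecules_of(species)
    if not mols:
        raise ValueError(f"no molecules of species '{species}' in topology")
    com = centers_of_mass(frames, topology)
    stats = shell_statistics(com, frames.box, mols, stride=shell_stride)
    sigma = topology.molecules[mols[0]].sigma
    terms = species_vibrational_terms(frames, topology, mols, species=species)
    terms["or"] = orientational_entropy(stats.p_nc, sigma,
                                        is_water=species == "water")
    terms["conf"] = species_conformational_entropy(frames, topology, mols)
    return SystemResult(
        label=energy.label, temperature=frames.temperature,
        enthalpy=mean_enthalpy(energy), solvent_kind=species,
        solvent_terms=terms, mean_nc=stats.mean_nc, solute_terms=None,
        extras={"p_nc": stats.p_nc, "n_solvent": len(mols)})


def analyze_solution(frames: FrameSet, energy: EnergySeries,
                     topology: MolecularTopology, solvent_species: str,
                     member_stride: int = 50) -> SystemResult:
    """Analyse a solution box: one solute plus its first-shell solvent.

    The solute's shell is evaluated on every frame (it gates which solvent
    molecules feed the shell-solvent covariances and supplies p(N_c) for
    the solute's orientational term); the shell members' own coordination
    statistics are sampled every ``member_stride`` frames.
    """
    solutes = topology.molecules_of("solute")
    if len(solutes) != 1:
        raise ValueError(
            f"solution box must contain exactly one solute, found "
            f"{len(solutes)}")
    solute = solutes[0]
    solvent = topology.molecules_of(solvent_species)
    if not solvent:
        raise ValueError(f"no '{solvent_species}' molecules in topology")
    t = frames.temperature
    com = centers_of_mass(frames, topology)
    n_frames, n_mol = com.shape[:2]
    rcut = estimate_rad_cutoff(com[0], frames.box[0])

    member_mask = np.zeros((n_frames, n_mol), dtype=bool)
    solute_nc: dict[int, int] = {}
    member_counts: dict[int, int] = {}
    for f in range(n_frames):
        shell = rad_shell(com[f], solute, frames.box[f], rcut=rcut)
        member_mask[f, list(shell)] = True
        solute_nc[len(shell)] = solute_nc.get(len(shell), 0) + 1
        if f % member_stride == 0:
            for m in shell:
                mnc = len(rad_shell(com[f], m, frames.box[f], rcut=rcut))
                member_counts[mnc] = member_counts.get(mnc, 0) + 1
    n_shell_samples = member_mask.sum()
    if n_shell_samples == 0:
        raise ValueError("solute has an empty first shell in every frame")
    p_nc_solute = {k: v / n_frames for k, v in sorted(solute_nc.items())}
    mean_nc = sum(k * v for k, v in p_nc_solute.items())
    tot = sum(member_counts.values())
    p_nc_members = {k: v / tot for k, v in sorted(member_counts.items())}

    # --- solute terms -----------------------------------------------------
    mol = topology.molecules[solute]
    solute_terms = species_vibrational_terms(frames, topology, [solute],
                                             species="solute")
    box_volume = float(np.prod(frames.box.mean(axis=0)))
    v_solvent = box_volume / len(solvent)
    solute_terms["pos"] = positional_entropy(box_volume, v_solvent)
    solute_terms["or"] = orientational_entropy(p_nc_solute, mol.sigma,
                                               is_water=False)
    solute_terms["conf"] = species_conformational_entropy(
        frames, topology, [solute])

    # --- first-shell solvent terms (per molecule) ------------------------
    solvent_terms = species_vibrational_terms(
        frames, topology, solvent, member_mask=member_mask,
        species=solvent_species)
    sigma = topology.molecules[solvent[0]].sigma
    solvent_terms["or"] = orientational_entropy(
        p_nc_members, sigma, is_water=solvent_species == "water")
    solvent_terms["conf"] = species_conformational_entropy(
        frames, topology, solvent)

    return SystemResult(
        label=energy.label, temperature=t, enthalpy=mean_enthalpy(energy),
        solvent_kind=solvent_species, solvent_terms=solvent_terms,
        mean_nc=mean_nc, solute_terms=solute_terms,
        extras={"p_nc_solute": p_nc_solute, "p_nc_members": p_nc_members,
                "v_solvent": v_solvent, "v_standard": box_volume})


def composite_transfer(bundle, member_stride: int = 50,
                       shell_stride: int = 50):
    """Run the full four-box pipeline on a synthetic composite bundle."""
    from .energy_logp import transfer

    topo, frames, energy = bundle.systems["X(aq)"]
    x_aq = analyze_solution(frames, energy, topo, "water",
                            member_stride=member_stride)
    topo, frames, energy = bundle.systems["X(oct)"]
    x_oct = analyze_solution(frames, energy, topo, "octanol",
                             member_stride=member_stride)
    topo, frames, energy = bundle.systems["wat"]
    wat = analyze_pure_liquid(frames, energy, topo, "water",
                              shell_stride=shell_stride)
    topo, frames, energy = bundle.systems["oct"]
    oct_ = analyze_pure_liquid(frames, energy, topo, "octanol",
                               shell_stride=shell_stride)
    return transfer(x_oct, wat, oct_, x_aq)
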