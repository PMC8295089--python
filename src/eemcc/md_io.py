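"""Topology, trajectory and energy input/output.

Two dialects are supported for each input:

* a minimal AMBER subset (``prmtop`` topologies, NetCDF trajectories with a
  ``forces`` variable, ``mdout`` energy logs), and
* the package's own plain-text fixture dialect: a YAML topology plus a text
  frame file (header ``natoms nframes [temperature]``, then per frame one box
  line, ``natoms`` coordinate lines and ``natoms`` force lines).

All quantities are converted on load to the internal unit system of
:mod:`eemcc.constants`: Å, amu, kcal mol⁻¹, kcal mol⁻¹ Å⁻¹.
Trajectories must carry forces — the force/torque covariance analysis is
meaningless without them, so their absence is a hard error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "UnitedAtom",
    "Molecule",
    "MolecularTopology",
    "FrameSet",
    "EnergySeries",
    "TopologyError",
    "TrajectoryError",
    "load_topology",
    "read_frames",
    "iter_frame_blocks",
    "write_frames",
    "write_topology",
    "load_energy_series",
]

# Default masses (amu) for elements appearing in the supported systems.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
    # generic synthetic point particle
    "X": 18.0,
}

HYDROGEN_MASS_CUTOFF = 3.5  # amu; heavier atoms are "heavy" for UA purposes


class TopologyError(ValueError):
    """Raised for malformed or inconsistent molecular topologies."""


class TrajectoryError(ValueError):
    """Raised for malformed trajectory or energy inputs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    mass: float
    bonded: tuple[int, ...] = ()

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H" or self.mass < HYDROGEN_MASS_CUTOFF


@dataclass(frozen=True)
class UnitedAtom:
    """A heavy atom with its bonded hydrogens, treated as one rigid body."""

    heavy: int
    hydrogens: tuple[int, ...] = ()

    @property
    def atoms(self) -> tuple[int, ...]:
        return (self.heavy, *self.hydrogens)

    @property
    def n_hydrogens(self) -> int:
        return len(self.hydrogens)


@dataclass
class Molecule:
    """A covalently bonded unit with a species label and symmetry number."""

    atom_indices: tuple[int, ...]
    species: str = "other"  # solute | water | octanol | other
    sigma: float = 1.0
    united_atoms: tuple[UnitedAtom, ...] = ()
    flexible_dihedrals: tuple[tuple[int, int, int, int], ...] = ()

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


@dataclass
class MolecularTopology:
    atoms: list[Atom]
    molecules: list[Molecule]
    _masses: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return self._masses

    def molecules_of(self, species: str) -> list[int]:
        return [i for i, m in enumerate(self.molecules) if m.species == species]

    def validate(self) -> None:
        seen: dict[int, int] = {}
        for mi, mol in enumerate(self.molecules):
            for ai in mol.atom_indices:
                if ai in seen:
                    raise TopologyError(
                        f"atom {ai} belongs to molecules {seen[ai]} and {mi}")
                seen[ai] = mi
            if mol.sigma < 1.0:
                raise TopologyError(
                    f"molecule {mi}: symmetry number {mol.sigma} < 1")
            ua_atoms = [a for ua in mol.united_atoms for a in ua.atoms]
            if sorted(ua_atoms) != sorted(mol.atom_indices):
                raise TopologyError(
                    f"molecule {mi}: united atoms do not partition the "
                    f"molecule's atoms exactly once")
            for ua in mol.united_atoms:
                if self.atoms[ua.heavy].is_hydrogen:
                    raise TopologyError(
                        f"united atom centred on atom {ua.heavy} has a "
                        f"hydrogen as its heavy atom")
            mol_set = set(mol.atom_indices)
            for quad in mol.flexible_dihedrals:
                if len(quad) != 4 or not set(quad) <= mol_set:
                    raise TopologyError(
                        f"molecule {mi}: dihedral {quad} references atoms "
                        f"outside the molecule")
        if len(seen) != self.n_atoms:
            missing = set(range(self.n_atoms)) - set(seen)
            raise TopologyError(f"atoms {sorted(missing)} belong to no molecule")


@dataclass
class FrameSet:
    """A block of trajectory frames with coordinates, forces and boxes.

    ``coordinates`` and ``forces`` have shape (n_frames, n_atoms, 3) in Å and
    kcal mol⁻¹ Å⁻¹; ``box`` has shape (n_frames, 3) — orthorhombic edge
    lengths in Å.
    """

    coordinates: np.ndarray
    forces: np.ndarray
    box: np.ndarray
    temperature: float = 298.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.shape != self.forces.shape:
            raise TrajectoryError(
                f"coordinates {self.coordinates.shape} and forces "
                f"{self.forces.shape} differ in shape")
        if self.coordinates.ndim != 3 or self.coordinates.shape[-1] != 3:
            raise TrajectoryError("coordinates must be (n_frames, n_atoms, 3)")
        if self.box.shape != (self.n_frames, 3):
            raise TrajectoryError("box must be (n_frames, 3)")
        if self.n_frames < 1:
            raise TrajectoryError("a FrameSet needs at least one frame")
        if np.any(self.box <= 0):
            raise TrajectoryError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class EnergySeries:
    """Per-frame total (potential + kinetic) energy of one simulation box."""

    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise TrajectoryError(f"energy series '{self.label}' is empty")
        if not np.all(np.isfinite(self.values)):
            raise TrajectoryError(
                f"energy series '{self.label}' contains non-finite values")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


# ---------------------------------------------------------------------------
# united atoms and flexible dihedrals
# ---------------------------------------------------------------------------

def derive_united_atoms(atoms: Sequence[Atom],
                        atom_indices: Sequence[int]) -> tuple[UnitedAtom, ...]:
    """Partition a molecule into heavy-atom + bonded-hydrogen groups."""
    idx_set = set(atom_indices)
    uas = []
    claimed: dict[int, int] = {}
    for ai in atom_indices:
        atom = atoms[ai]
        if atom.is_hydrogen:
            heavies = [b for b in atom.bonded
                       if b in idx_set and not atoms[b].is_hydrogen]
            if len(heavies) != 1:
                raise TopologyError(
                    f"hydrogen atom {ai} is bonded to {len(heavies)} heavy "
                    f"atoms; exactly one is required for a united atom")
            claimed[ai] = heavies[0]
    for ai in atom_indices:
        if atoms[ai].is_hydrogen:
            continue
        hs = tuple(sorted(h for h, heavy in claimed.items() if heavy == ai))
        uas.append(UnitedAtom(heavy=ai, hydrogens=hs))
    if not uas and atom_indices:
        raise TopologyError(
            f"molecule with atoms {tuple(atom_indices)} has no heavy atom")
    return tuple(uas)


def detect_flexible_dihedrals(atoms: Sequence[Atom],
                              atom_indices: Sequence[int]
                              ) -> tuple[tuple[int, int, int, int], ...]:
    """Enumerate one heavy-atom dihedral per rotatable bond.

    A bond b–c is rotatable when both ends are non-terminal in the heavy-atom
    graph and the bond is not part of a ring.  One representative 4-tuple
    (a, b, c, d) is chosen per bond with a and d the lowest-index heavy
    neighbours, so each torsion is counted once.
    """
    idx_set = set(atom_indices)
    heavy = [ai for ai in atom_indices if not atoms[ai].is_hydrogen]
    neigh = {ai: sorted(b for b in atoms[ai].bonded
                        if b in idx_set and not atoms[b].is_hydrogen)
             for ai in heavy}
    ring_edges = _ring_edges(neigh)
    quads = []
    for b in heavy:
        for c in neigh[b]:
            if c <= b:
                continue
            if len(neigh[b]) < 2 or len(neigh[c]) < 2:
                continue  # terminal heavy atom on one end
            if (b, c) in ring_edges:
                continue
            a = next(x for x in neigh[b] if x != c)
            d = next(x for x in neigh[c] if x != b)
            quads.append((a, b, c, d))
    return tuple(quads)


def _ring_edges(neigh: dict[int, list[int]]) -> set[tuple[int, int]]:
    """Edges lying on a cycle of the heavy-atom graph (bridges removed)."""
    # iterative DFS bridge finding (Tarjan); non-bridge edges are ring edges
    disc: dict[int, int] = {}
    low: dict[int, int] = {}
    bridges: set[tuple[int, int]] = set()
    timer = 0
    for root in neigh:
        if root in disc:
            continue
        stack = [(root, -1, iter(neigh[root]))]
        disc[root] = low[root] = timer
        timer += 1
        while stack:
            node, parent, it = stack[-1]
            advanced = False
            for nb in it:
                if nb == parent:
                    continue
                if nb in disc:
                    low[node] = min(low[node], disc[nb])
                else:
                    disc[nb] = low[nb] = timer
                    timer += 1
                    stack.append((nb, node, iter(neigh[nb])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                if parent != -1:
                    low[parent] = min(low[parent], low[node])
                    if low[node] > disc[parent]:
                        bridges.add(tuple(sorted((parent, node))))
    edges = {tuple(sorted((a, b))) for a, nbs in neigh.items() for b in nbs}
    return edges - bridges


def _connected_components(n_atoms: int,
                          bonds: Sequence[tuple[int, int]]) -> list[list[int]]:
    parent = list(range(n_atoms))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in bonds:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, list[int]] = {}
    for i in range(n_atoms):
        comps.setdefault(find(i), []).append(i)
    return [sorted(c) for c in sorted(comps.values(), key=lambda c: c[0])]


# ---------------------------------------------------------------------------
# topology loading
# ---------------------------------------------------------------------------

def load_topology(path: str | Path, format_name: str = "yaml") -> MolecularTopology:
    """Load a topology from the YAML fixture dialect or an AMBER prmtop."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_name == "yaml":
        return _load_yaml_topology(path)
    if format_name == "prmtop":
        return _load_prmtop(path)
    raise ValueError(f"unknown topology format '{format_name}'")


def build_topology(elements: Sequence[str],
                   bonds: Sequence[tuple[int, int]],
                   molecules_spec: Sequence[dict] | None = None,
                   masses: Sequence[float] | None = None,
                   dihedral_overrides: dict[int, list] | None = None,
                   ) -> MolecularTopology:
    """Assemble a validated topology from primitive pieces.

    ``molecules_spec`` entries are dicts with keys ``atoms`` (required),
    ``species`` and ``sigma``; when omitted, molecules are the connected
    components of the bond graph with species ``other``.
    """
    n = len(elements)
    bonded: list[set[int]] = [set() for _ in range(n)]
    for a, b in bonds:
        if not (0 <= a < n and 0 <= b < n) or a == b:
            raise TopologyError(f"bond ({a}, {b}) is out of range")
        bonded[a].add(b)
        bonded[b].add(a)
    if masses is None:
        try:
            masses = [ELEMENT_MASSES[e] for e in elements]
        except KeyError as exc:
            raise TopologyError(f"no default mass for element {exc}") from exc
    atoms = [Atom(i, elements[i], float(masses[i]), tuple(sorted(bonded[i])))
             for i in range(n)]
    if molecules_spec is None:
        molecules_spec = [{"atoms": comp}
                          for comp in _connected_components(n, list(bonds))]
    dihedral_overrides = dihedral_overrides or {}
    molecules = []
    for mi, spec in enumerate(molecules_spec):
        idx = tuple(int(i) for i in spec["atoms"])
        species = spec.get("species", "other")
        sigma = float(spec.get("sigma", 2.0 if species == "water" else 1.0))
        uas = derive_united_atoms(atoms, idx)
        if mi in dihedral_overrides:
            quads = tuple(tuple(int(x) for x in q)
                          for q in dihedral_overrides[mi])
        elif "flexible_dihedrals" in spec:
            quads = tuple(tuple(int(x) for x in q)
                          for q in spec["flexible_dihedrals"])
        else:
            quads = detect_flexible_dihedrals(atoms, idx)
        molecules.append(Molecule(atom_indices=idx, species=species,
                                  sigma=sigma, united_atoms=uas,
                                  flexible_dihedrals=quads))
    return MolecularTopology(atoms=atoms, molecules=molecules)


def _load_yaml_topology(path: Path) -> MolecularTopology:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise TopologyError(f"{path}: malformed YAML: {exc}") from exc
    if not isinstance(doc, dict) or "atoms" not in doc:
        raise TopologyError(f"{path}: missing required 'atoms' list")
    elements, masses = [], []
    for i, rec in enumerate(doc["atoms"]):
        if isinstance(rec, str):
            rec = {"element": rec}
        if "element" not in rec:
            raise TopologyError(f"{path}: atom record {i} lacks 'element'")
        el = str(rec["element"])
        elements.append(el)
        masses.append(float(rec.get("mass", ELEMENT_MASSES.get(el, np.nan))))
        if not np.isfinite(masses[-1]) or masses[-1] <= 0:
            raise TopologyError(
                f"{path}: atom record {i} ({el}) has no valid mass")
    bonds = [tuple(int(x) for x in b) for b in doc.get("bonds", [])]
    return build_topology(elements, bonds, doc.get("molecules"), masses)


def write_topology(topology: MolecularTopology, path: str | Path) -> None:
    """Write a topology in the YAML fixture dialect (round-trips exactly)."""
    doc = {
        "atoms": [{"element": a.element, "mass": float(a.mass)}
                  for a in topology.atoms],
        "bonds": sorted({tuple(sorted((a.index, b)))
                         for a in topology.atoms for b in a.bonded}),
        "molecules": [
            {"atoms": list(m.atom_indices), "species": m.species,
             "sigma": float(m.sigma),
             "flexible_dihedrals": [list(q) for q in m.flexible_dihedrals]}
            for m in topology.molecules
        ],
    }
    doc["bonds"] = [list(b) for b in doc["bonds"]]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# --- minimal AMBER prmtop subset ------------------------------------------

_PRMTOP_SPECIES = {"WAT": "water", "HOH": "water", "SPC": "water",
                   "T4P": "water", "OCT": "octanol", "OCL": "octanol"}

_ATOMIC_NUMBER_TO_ELEMENT = {1: "H", 6: "C", 7: "N", 8: "O", 9: "F",
                             15: "P", 16: "S", 17: "Cl", 35: "Br", 53: "I"}


def _load_prmtop(path: Path) -> MolecularTopology:
    sections: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("%FLAG"):
                current = line.split()[1]
                sections[current] = []
            elif line.startswith("%"):
                continue
            elif current is not None:
                sections[current].append(line.rstrip("\n"))
    if "POINTERS" not in sections:
        raise TopologyError(f"{path}: missing %FLAG POINTERS record")
    pointers = [int(x) for x in " ".join(sections["POINTERS"]).split()]
    natom = pointers[0]

    def floats(flag: str) -> list[float]:
        if flag not in sections:
            raise TopologyError(f"{path}: missing %FLAG {flag} record")
        return [float(x) for x in " ".join(sections[flag]).split()]

    def ints(flag: str, required: bool = True) -> list[int]:
        if flag not in sections:
            if required:
                raise TopologyError(f"{path}: missing %FLAG {flag} record")
            return []
        return [int(x) for x in " ".join(sections[flag]).split()]

    masses = floats("MASS")
    if len(masses) != natom:
        raise TopologyError(
            f"{path}: MASS has {len(masses)} entries for {natom} atoms")
    znums = ints("ATOMIC_NUMBER", required=False)
    if znums:
        elements = [_ATOMIC_NUMBER_TO_ELEMENT.get(z, "X") for z in znums]
    else:  # fall back on the mass
        elements = ["H" if m < HYDROGEN_MASS_CUTOFF else "C" for m in masses]
    bonds: list[tuple[int, int]] = []
    for flag in ("BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN"):
        raw = ints(flag, required=False)
        # AMBER stores coordinate-array offsets (3*i) plus a bond-type index
        for k in range(0, len(raw), 3):
            bonds.append((raw[k] // 3, raw[k + 1] // 3))
    comps = _connected_components(natom, bonds)
    res_labels = sections.get("RESIDUE_LABEL")
    res_ptr = ints("RESIDUE_POINTER", required=False)
    species_of_atom = {}
    if res_labels and res_ptr:
        labels = " ".join(res_labels).split()
        starts = [p - 1 for p in res_ptr] + [natom]
        for label, s, e in zip(labels, starts[:-1], starts[1:]):
            for ai in range(s, e):
                species_of_atom[ai] = _PRMTOP_SPECIES.get(label.upper(), "other")
    mol_spec = []
    for comp in comps:
        species = species_of_atom.get(comp[0], "other")
        mol_spec.append({"atoms": comp, "species": species,
                         "sigma": 2.0 if species == "water" else 1.0})
    return build_topology(elements, bonds, mol_spec, masses)


# ---------------------------------------------------------------------------
# trajectory frames
# ---------------------------------------------------------------------------

def read_frames(path: str | Path, topology: MolecularTopology | None = None,
                format_name: str = "text") -> FrameSet:
    """Read a whole trajectory into one FrameSet (small inputs/fixtures)."""
    blocks = list(iter_frame_blocks(path, topology, format_name=format_name))
    return FrameSet(
        coordinates=np.concatenate([b.coordinates for b in blocks]),
        forces=np.concatenate([b.forces for b in blocks]),
        box=np.concatenate([b.box for b in blocks]),
        temperature=blocks[0].temperature,
    )


def iter_frame_blocks(path: str | Path,
                      topology: MolecularTopology | None = None,
                      format_name: str = "text",
                      block_size: int = 500) -> Iterator[FrameSet]:
    """Stream a trajectory as FrameSet blocks of at most ``block_size`` frames.

    Frames are never fully materialized for large files; accumulating
    consumers (covariances, shell histograms) run single-pass over blocks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_name == "text":
        yield from _iter_text_frames(path, topology, block_size)
    elif format_name == "netcdf":
        yield from _iter_netcdf_frames(path, topology, block_size)
    else:
        raise ValueError(f"unknown trajectory format '{format_name}'")


def _iter_text_frames(path: Path, topology, block_size: int) -> Iterator[FrameSet]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) not in (2, 3):
            raise TrajectoryError(
                f"{path}: header must be 'natoms nframes [temperature]'")
        natoms, nframes = int(header[0]), int(header[1])
        temperature = float(header[2]) if len(header) == 3 else 298.0
        if topology is not None and natoms != topology.n_atoms:
            raise TrajectoryError(
                f"{path}: file has {natoms} atoms, topology has "
                f"{topology.n_atoms}")

        def read_vec(what: str, frame: int) -> np.ndarray:
            line = fh.readline()
            if not line:
                raise TrajectoryError(
                    f"{path}: truncated at frame {frame} while reading {what}")
            vals = line.split()
            if len(vals) != 3:
                raise TrajectoryError(
                    f"{path}: expected 3 numbers for {what} in frame {frame}, "
                    f"got {len(vals)}")
            return np.array([float(v) for v in vals])

        done = 0
        while done < nframes:
            n = min(block_size, nframes - done)
            coords = np.empty((n, natoms, 3))
            forces = np.empty((n, natoms, 3))
            box = np.empty((n, 3))
            for f in range(n):
                frame = done + f
                box[f] = read_vec("box", frame)
                for a in range(natoms):
                    coords[f, a] = read_vec(f"coordinates of atom {a}", frame)
                for a in range(natoms):
                    forces[f, a] = read_vec(f"forces of atom {a}", frame)
            done += n
            yield FrameSet(coords, forces, box, temperature)


def _iter_netcdf_frames(path: Path, topology, block_size: int) -> Iterator[FrameSet]:
    # AMBER NetCDF convention trajectory; requires the optional 'forces'
    # variable.  NetCDF3 classic/64-bit-offset files only.
    from scipy.io import netcdf_file

    with netcdf_file(str(path), "r", mmap=False) as nc:
        if "forces" not in nc.variables:
            raise TrajectoryError(
                f"{path}: forces required for MCC but the trajectory has no "
                f"'forces' variable")
        coords_v = nc.variables["coordinates"]
        forces_v = nc.variables["forces"]
        if "cell_lengths" not in nc.variables:
            raise TrajectoryError(f"{path}: missing 'cell_lengths' variable")
        cell_v = nc.variables["cell_lengths"]
        if "cell_angles" in nc.variables:
            ang = np.asarray(nc.variables["cell_angles"][:], dtype=float)
            if not np.allclose(ang, 90.0, atol=1e-3):
                raise TrajectoryError(
                    f"{path}: non-orthorhombic box (cell angles != 90°) is "
                    f"unsupported")
        nframes, natoms = coords_v.shape[0], coords_v.shape[1]
        if topology is not None and natoms != topology.n_atoms:
            raise TrajectoryError(
                f"{path}: file has {natoms} atoms, topology has "
                f"{topology.n_atoms}")
        for start in range(0, nframes, block_size):
            stop = min(start + block_size, nframes)
            yield FrameSet(
                coordinates=np.asarray(coords_v[start:stop], dtype=float),
                forces=np.asarray(forces_v[start:stop], dtype=float),
                box=np.asarray(cell_v[start:stop], dtype=float),
            )


def write_frames(frames: FrameSet, path: str | Path) -> None:
    """Write a FrameSet in the text fixture dialect.

    Numbers are written with repr-level precision so a write/read round trip
    is bitwise exact.
    """
    with open(path, "w") as fh:
        fh.write(f"{frames.n_atoms} {frames.n_frames} "
                 f"{frames.temperature!r}\n")
        for f in range(frames.n_frames):
            fh.write(" ".join(repr(float(v)) for v in frames.box[f]) + "\n")
            for block in (frames.coordinates, frames.forces):
                for a in range(frames.n_atoms):
                    fh.write(" ".join(repr(float(v))
                                      for v in block[f, a]) + "\n")


# ---------------------------------------------------------------------------
# energy series
# ---------------------------------------------------------------------------

_ETOT_RE = re.compile(r"Etot\s*=\s*([-+0-9.EeDd]+)", re.IGNORECASE)


def load_energy_series(path: str | Path, label: str) -> EnergySeries:
    """Load per-frame total energies from a two-column table or AMBER mdout.

    The table format is ``frame energy`` per line (``#`` comments allowed);
    mdout logs are recognised by their ``Etot =`` records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if _ETOT_RE.search(text):
        vals = [float(m.group(1).replace("D", "E").replace("d", "e"))
                for m in _ETOT_RE.finditer(text)]
        return EnergySeries(np.array(vals), label)
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise TrajectoryError(
                f"{path}:{ln}: expected 'frame energy', got {len(parts)} "
                f"fields")
        try:
            rows.append(float(parts[1]))
        except ValueError as exc:
            raise TrajectoryError(
                f"{path}:{ln}: non-numeric energy '{parts[1]}'") from exc
    return EnergySeries(np.array(rows), label)
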