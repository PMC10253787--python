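"""Structures, trajectories, selections and van der Waals radii.

The data model every analysis consumes: a :class:`Topology` (shared atom
metadata), a :class:`StructureFrame` (one coordinate set) and a
:class:`Trajectory` (an ordered stack of frames).  File I/O goes through
MDAnalysis (PDB, DCD) and gemmi (mmCIF); coordinates are kept as plain
numpy arrays in Å.

Residue numbering follows the author numbering of the input file (1-based,
matching residue labels such as C387 or A658); selection ranges are
inclusive.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    FormatError,
    PartialReadError,
    TopologyError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Topology",
    "StructureFrame",
    "Trajectory",
    "Selection",
    "VdwTable",
    "BONDI_RADII",
    "HOLE_SIMPLE_RADII",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
    "assign_vdw",
    "infer_elements",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Per-atom metadata shared by every frame of a trajectory."""

    atom_name: np.ndarray
    element: np.ndarray
    residue_number: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray

    def __post_init__(self):
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.residue_number = np.asarray(self.residue_number, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        n = len(self.atom_name)
        for arr in (self.element, self.residue_number, self.residue_name, self.chain_id):
            if len(arr) != n:
                raise TopologyError("topology attribute arrays have unequal lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_number) pairs."""
        seen, out = set(), []
        for c, r in zip(self.chain_id, self.residue_number):
            key = (c, int(r))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def same_atoms(self, other: "Topology") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.atom_name, other.atom_name)
            and np.array_equal(self.residue_number, other.residue_number)
            and np.array_equal(self.chain_id, other.chain_id)
        )


@dataclass
class StructureFrame:
    """One set of atomic coordinates (Å) with its topology."""

    topology: Topology
    coordinates: np.ndarray
    frame_time: float | None = None  # ps

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TopologyError("coordinates must have shape (n_atoms, 3)")
        if self.coordinates.shape[0] != self.topology.n_atoms:
            raise TopologyError(
                f"coordinate count {self.coordinates.shape[0]} != topology atom "
                f"count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise TopologyError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


@dataclass
class Trajectory:
    """Ordered frames sharing one topology; the unit all analyses consume."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3), Å
    stride_ps: float = 1.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TopologyError("trajectory coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise TopologyError("trajectory must contain at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TopologyError("trajectory atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * float(self.stride_ps)

    def frame(self, i: int) -> StructureFrame:
        return StructureFrame(self.topology, self.coordinates[i],
                              frame_time=float(i) * float(self.stride_ps))

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    def slice(self, start=None, stop=None, step=None) -> "Trajectory":
        sl = slice(start, stop, step)
        coords = self.coordinates[sl]
        if coords.shape[0] == 0:
            raise EmptySelectionError("frame slice selected no frames")
        stride = self.stride_ps * (step or 1)
        return Trajectory(self.topology, coords.copy(), stride_ps=stride)


@dataclass
class Selection:
    """A resolved, order-stable set of atom indices."""

    label: str
    atom_indices: np.ndarray
    spec: str = ""

    def __post_init__(self):
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        if self.atom_indices.size == 0:
            raise EmptySelectionError(f"selection '{self.spec or self.label}' is empty")
        if np.any(np.diff(self.atom_indices) <= 0):
            raise TopologyError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.atom_indices)


# ---------------------------------------------------------------------------
# van der Waals radii
# ---------------------------------------------------------------------------

#: Bondi (1964) van der Waals radii, Å.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "HE": 1.40, "NE": 1.54,
    "AR": 1.88, "K": 2.75, "NA": 2.27, "MG": 1.73, "ZN": 1.39, "SE": 1.90,
}

#: The "simple" radius set shipped with the HOLE distribution, Å.
HOLE_SIMPLE_RADII = {"C": 1.85, "O": 1.65, "S": 2.00, "N": 1.75, "H": 1.00, "P": 2.10}


@dataclass
class VdwTable:
    """Element → van der Waals radius map with a fallback for unknowns."""

    radii: dict = field(default_factory=lambda: dict(BONDI_RADII))
    default_radius: float = 1.70

    def __post_init__(self):
        if self.default_radius <= 0 or any(r <= 0 for r in self.radii.values()):
            raise ValueError("van der Waals radii must be positive")
        self.radii = {k.upper(): float(v) for k, v in self.radii.items()}

    @classmethod
    def bondi(cls) -> "VdwTable":
        return cls(dict(BONDI_RADII), default_radius=1.70)

    @classmethod
    def hole_simple(cls) -> "VdwTable":
        return cls(dict(HOLE_SIMPLE_RADII), default_radius=1.85)

    def lookup(self, element: str) -> float:
        return self.radii.get(str(element).upper(), self.default_radius)


_TWO_LETTER = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "SE", "HE", "NE", "AR"}


def _element_from_name(name: str) -> str:
    """Guess an element symbol from a PDB atom name (heuristic only)."""
    stripped = re.sub(r"[^A-Za-z]", "", str(name)).upper()
    if not stripped:
        return ""
    if str(name)[0].isdigit():
        return "H"  # names like 1HB
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2]
    return stripped[0]


def infer_elements(topology: Topology) -> np.ndarray:
    """Fill missing element symbols from atom names in place; return them."""
    elements = topology.element
    for i, (el, name) in enumerate(zip(elements, topology.atom_name)):
        if not str(el).strip():
            elements[i] = _element_from_name(name)
    return elements


def assign_vdw(topology: Topology, table: VdwTable | None = None) -> np.ndarray:
    """Per-atom van der Waals radii (Å); unknown elements get the default."""
    table = table or VdwTable.bondi()
    infer_elements(topology)
    radii = np.empty(topology.n_atoms)
    unknown = set()
    for i, el in enumerate(topology.element):
        key = str(el).upper()
        if key in table.radii:
            radii[i] = table.radii[key]
        else:
            radii[i] = table.default_radius
            unknown.add(key or "?")
    if unknown:
        logger.info("unknown elements %s assigned default radius %.2f Å",
                    sorted(unknown), table.default_radius)
    return radii


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "CYX", "GLN", "GLU", "GLY", "HIS",
    "HID", "HIE", "HIP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER",
    "THR", "TRP", "TYR", "VAL",
}
_WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC"}

_RANGE_RE = re.compile(r"^(-?\d+)\s*[-–—]\s*(-?\d+)$")


def _parse_residue_tokens(tokens):
    numbers = []
    for tok in tokens:
        m = _RANGE_RE.match(tok)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            numbers.append((lo, hi))
        else:
            numbers.append((int(tok), int(tok)))
    return numbers


def resolve_selection(topology: Topology, spec: str, label: str | None = None) -> Selection:
    """Resolve a textual selection spec to atom indices.

    Grammar: comma/semicolon-separated clauses, combined with AND. Each
    clause is a keyword followed by values (OR within a clause):

    - ``chain A B``
    - ``residues 432-713 720`` (inclusive ranges, author numbering)
    - ``atoms CA CB`` / ``name CA``
    - ``resname ALA HOH``
    - ``element O``
    - bare keywords ``backbone`` (atoms N, CA, C, O), ``protein``,
      ``water``, ``heavy`` (non-hydrogen), ``all``

    Example: ``"chain A, residues 658-692, atoms CA"``.
    Resolution is deterministic and depends only on the topology.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    infer_elements(topology)
    atom_names_upper = np.array([str(n).upper() for n in topology.atom_name], dtype=object)
    known_names = set(atom_names_upper)
    for raw in re.split(r"[,;]", spec):
        clause = raw.strip()
        if not clause:
            continue
        tokens = clause.split()
        key = tokens[0].lower()
        vals = tokens[1:]
        if key in ("chain", "chains", "segid"):
            wanted = {v.upper() for v in vals}
            mask &= np.array([str(c).upper() in wanted for c in topology.chain_id])
        elif key in ("residue", "residues", "resid", "resids", "resnum"):
            ranges = _parse_residue_tokens(vals)
            rn = topology.residue_number
            sub = np.zeros_like(mask)
            for lo, hi in ranges:
                sub |= (rn >= lo) & (rn <= hi)
            mask &= sub
        elif key in ("atom", "atoms", "name", "names"):
            wanted = {v.upper() for v in vals}
            missing = wanted - known_names
            if missing:
                warnings.warn(f"selection '{spec}': unknown atom name(s) {sorted(missing)}",
                              stacklevel=2)
            mask &= np.isin(atom_names_upper, sorted(wanted))
        elif key in ("resname", "resnames"):
            wanted = {v.upper() for v in vals}
            mask &= np.array([str(r).upper() in wanted for r in topology.residue_name])
        elif key in ("element", "elements"):
            wanted = {v.upper() for v in vals}
            mask &= np.array([str(e).upper() in wanted for e in topology.element])
        elif key == "backbone":
            mask &= np.isin(atom_names_upper, BACKBONE_ATOMS)
        elif key == "protein":
            mask &= np.array([str(r).upper() in _PROTEIN_RESNAMES for r in topology.residue_name])
        elif key == "water":
            mask &= np.array([str(r).upper() in _WATER_RESNAMES for r in topology.residue_name])
        elif key == "heavy":
            mask &= np.array([str(e).upper() != "H" for e in topology.element])
        elif key == "all":
            pass
        else:
            raise FormatError(f"selection '{spec}': unknown clause keyword '{key}'")
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise EmptySelectionError(f"selection '{spec}' matched no atoms")
    return Selection(label=label or spec, atom_indices=indices, spec=spec)


# ---------------------------------------------------------------------------
# file I/O (MDAnalysis for PDB/DCD, gemmi for mmCIF)
# ---------------------------------------------------------------------------

def _topology_from_universe(u) -> Topology:
    ag = u.atoms
    names = ag.names
    try:
        elements = np.asarray(ag.elements, dtype=object)
    except Exception:
        elements = np.array([""] * len(ag), dtype=object)
    try:
        chains = np.asarray(ag.chainIDs, dtype=object)
    except Exception:
        chains = np.asarray(ag.segids, dtype=object)
    top = Topology(
        atom_name=np.asarray(names, dtype=object),
        element=elements,
        residue_number=np.asarray(ag.resids, dtype=int),
        residue_name=np.asarray(ag.resnames, dtype=object),
        chain_id=chains,
    )
    infer_elements(top)
    return top


def _to_universe(topology: Topology, coordinates: np.ndarray, dt: float = 1.0):
    """Build an in-memory MDAnalysis Universe from the package data model."""
    import MDAnalysis as mda

    coords = np.asarray(coordinates, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = topology.n_atoms
    # consecutive (chain, resid) runs define residues; chains define segments
    resindex = np.empty(n_atoms, dtype=int)
    res_keys, seg_names = [], []
    prev = None
    for i, key in enumerate(zip(topology.chain_id, topology.residue_number,
                                topology.residue_name)):
        if key != prev:
            res_keys.append(key)
            prev = key
        resindex[i] = len(res_keys) - 1
    seg_of_res = []
    for chain, _, _ in res_keys:
        if chain not in seg_names:
            seg_names.append(chain)
        seg_of_res.append(seg_names.index(chain))
    u = mda.Universe.empty(
        n_atoms,
        n_residues=len(res_keys),
        n_segments=len(seg_names),
        atom_resindex=resindex,
        residue_segindex=np.asarray(seg_of_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in topology.atom_name])
    u.add_TopologyAttr("elements", [str(e) for e in topology.element])
    u.add_TopologyAttr("chainIDs", [str(c) for c in topology.chain_id])
    u.add_TopologyAttr("resids", [int(r) for _, r, _ in res_keys])
    u.add_TopologyAttr("resnames", [str(rn) for _, _, rn in res_keys])
    u.add_TopologyAttr("segids", [str(s) for s in seg_names])
    u.add_TopologyAttr("occupancies", np.ones(n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(n_atoms))
    u.load_new(coords.astype(np.float32), order="fac", dt=dt)
    return u


def _read_structure_mmcif(path, model: int) -> StructureFrame:
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError with line info
        raise FormatError(f"could not parse mmCIF file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    if model < 1 or model > len(st):
        raise FormatError(f"{path}: model {model} requested but file has {len(st)}")
    mdl = st[model - 1]
    names, elements, resnums, resnames, chains, xyz = [], [], [], [], [], []
    for chain in mdl:
        for residue in chain:
            for atom in residue:
                names.append(atom.name)
                elements.append(atom.element.name)
                resnums.append(residue.seqid.num)
                resnames.append(residue.name)
                chains.append(chain.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not names:
        raise EmptyStructureError(f"{path}: model {model} contains no atoms")
    top = Topology(names, elements, resnums, resnames, chains)
    return StructureFrame(top, np.asarray(xyz))


def read_structure(path, format: str | None = None, model: int = 1) -> StructureFrame:
    """Read one model of a PDB or mmCIF file.

    ``model`` is 1-based; multi-model files yield the first model unless a
    model index is given. Author residue numbering and chain ids are
    preserved.
    """
    path = str(path)
    if format is None:
        lower = path.lower()
        format = "mmcif" if lower.endswith((".cif", ".mmcif")) else "pdb"
    format = format.lower()
    if format in ("mmcif", "cif"):
        return _read_structure_mmcif(path, model)
    if format != "pdb":
        raise FormatError(f"unsupported structure format '{format}'")

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(path)
        except Exception as exc:
            raise FormatError(f"could not parse PDB file {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise EmptyStructureError(f"{path}: no atoms in model")
    n_models = len(u.trajectory)
    if model < 1 or model > n_models:
        raise FormatError(f"{path}: model {model} requested but file has {n_models}")
    u.trajectory[model - 1]
    top = _topology_from_universe(u)
    return StructureFrame(top, u.atoms.positions.astype(float))


def write_structure(frame: StructureFrame, path) -> None:
    """Write a StructureFrame as a PDB file (fixed-width, 1e-3 Å precision)."""
    u = _to_universe(frame.topology, frame.coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _dcd_declared_frames(path) -> int | None:
    """Frame count (NSET) declared in a DCD header, or None if not a DCD.

    Readers infer the frame count from the file size, so a truncated file
    is read short silently; the header value exposes the truncation.
    """
    import struct

    try:
        with open(path, "rb") as fh:
            head = fh.read(12)
    except OSError:
        return None
    if len(head) < 12 or head[4:8] != b"CORD":
        return None
    for endian in ("<", ">"):
        (blocksize,) = struct.unpack(endian + "i", head[:4])
        if blocksize == 84:
            return struct.unpack(endian + "i", head[8:12])[0]
    return None


def read_trajectory(topology_path, traj_path, stride_ps: float | None = None) -> Trajectory:
    """Read a trajectory (DCD/XTC + PDB topology) into memory.

    ``stride_ps`` overrides the time step recorded in the file metadata.
    Raises :class:`TopologyError` on an atom-count mismatch and
    :class:`PartialReadError` (carrying the frames recovered) on a
    truncated trajectory file.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(topology_path), str(traj_path))
        except ValueError as exc:
            raise TopologyError(
                f"topology/trajectory mismatch for {traj_path}: {exc}") from exc
        except Exception as exc:
            raise PartialReadError(
                f"could not open trajectory {traj_path}: {exc}",
                n_frames_recovered=0) from exc
        top = _topology_from_universe(u)
        frames = []
        dt = None
        error = None
        try:
            for ts in u.trajectory:
                frames.append(ts.positions.astype(float).copy())
                if dt is None:
                    dt = float(getattr(ts, "dt", 1.0) or 1.0)
        except Exception as exc:  # truncated file mid-iteration
            error = exc
    stride = float(stride_ps) if stride_ps is not None else float(dt or 1.0)
    declared = _dcd_declared_frames(traj_path)
    if error is not None or (declared is not None and 0 < len(frames) < declared):
        traj = Trajectory(top, np.asarray(frames), stride_ps=stride) if frames else None
        msg = (f"trajectory {traj_path} truncated: recovered {len(frames)} frames"
               + (f" of {declared} declared" if declared else "")
               + (f" ({error})" if error is not None else ""))
        exc = PartialReadError(msg, n_frames_recovered=len(frames), trajectory=traj)
        if error is not None:
            raise exc from error
        raise exc
    if not frames:
        raise EmptyStructureError(f"{traj_path}: no frames")
    return Trajectory(top, np.asarray(frames), stride_ps=stride)


def write_trajectory(traj: Trajectory, topology_path, traj_path) -> None:
    """Write topology as PDB and frames as a DCD trajectory."""
    import MDAnalysis as mda

    u = _to_universe(traj.topology, traj.coordinates, dt=traj.stride_ps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.trajectory[0]
        u.atoms.write(str(topology_path))
        with mda.Writer(str(traj_path), n_atoms=traj.n_atoms,
                        dt=float(traj.stride_ps)) as w:
            for ts in u.trajectory:
                w.write(u.atoms)


def subset_frame(frame: StructureFrame, sel: Selection) -> StructureFrame:
    """A new frame containing only the selected atoms."""
    idx = sel.atom_indices
    top = frame.topology
    sub = Topology(top.atom_name[idx], top.element[idx], top.residue_number[idx],
                   top.residue_name[idx], top.chain_id[idx])
    return StructureFrame(sub, frame.coordinates[idx], frame_time=frame.frame_time)
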