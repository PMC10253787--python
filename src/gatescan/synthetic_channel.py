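"""Synthetic tetrameric-channel structures and trajectories with known truth.

The generator emulates the statistical structure of a pore-forming helix
bundle sampled by molecular dynamics, without any force field:

* four (by default) ideal α-helical backbone traces placed with exact
  n-fold symmetry about the z axis, each tilted by prescribed tangential
  and radial angles about its own centroid;
* a dense gate ring of atoms at z = 0 whose axis-constrained clearance
  equals a prescribed aperture analytically (ring radius = aperture +
  carbon vdW radius), optionally switching between a closed and an open
  aperture in an exact planted fraction of frames;
* per-residue isotropic Gaussian positional fluctuation with prescribed
  σ (so the expected RMSF of a residue is σ√3);
* planted donor–H–acceptor triplets whose geometry satisfies the
  hydrogen-bond criteria in exactly a prescribed fraction of frames;
* single-particle waters that either traverse the pore monotonically
  from below the lower gate plane to above the upper gate plane, or
  oscillate below the lower plane without ever crossing it.

Every dataset carries a ground-truth manifest (a JSON-serialisable dict);
recovery tests read truth only from the manifest.  A fixed seed yields
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import SpecError
from .structure_io import (
    BONDI_RADII,
    StructureFrame,
    Topology,
    Trajectory,
    write_structure,
    write_trajectory,
)

__all__ = [
    "ChannelSpec",
    "PlantedHBond",
    "build_reference",
    "simulate_trajectory",
    "morph_states",
    "planted_dihedral_series",
    "write_dataset",
    "ideal_helix_backbone",
]

# canonical α-helix backbone dihedrals (deg)
HELIX_PHI = -57.0
HELIX_PSI = -47.0

# standard backbone geometry (Engh–Huber-like): bond lengths Å, angles deg
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5

_GATE_VDW = BONDI_RADII["C"]  # gate ring atoms are carbons


@dataclass
class PlantedHBond:
    """A donor–H–acceptor triplet planted with an exact occupancy."""

    occupancy: float = 0.75
    present_distance: float = 2.8   # d(A,D) Å on frames where the bond holds
    absent_distance: float = 4.5    # d(A,D) Å on frames where it is broken

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise SpecError("H-bond occupancy must lie in [0, 1]")


@dataclass
class ChannelSpec:
    """Parameters of one synthetic channel state.

    Defaults mirror the analysed system: a tetramer whose chains span
    residues 432–713, 2000 stored snapshots at 250 ps (500 ns), a closed
    gate aperture of 0.59 Å and a tangential helix tilt of 25°.
    """

    n_subunits: int = 4
    residue_start: int = 432
    helix_residues: int = 282                # chains span 432..713 by default
    helix_radius_from_axis: float = 10.0     # Å, centroid distance from z axis
    helix_tilt_tangential_deg: float = 25.0
    helix_tilt_radial_deg: float = 0.0
    gate_aperture: float = 0.59              # Å, closed-gate axis clearance
    gate_open_aperture: float | None = None  # Å, aperture on "open" frames
    open_fraction: float = 0.0               # exact fraction of open frames
    gate_ring_atoms: int = 48
    per_residue_sigma: float | np.ndarray = 0.5  # Å, per-coordinate Gaussian σ
    planted_hbonds: list = field(default_factory=list)
    n_waters_traversing: int = 3
    n_waters_resident: int = 3
    upper_gate_z: float = 5.0
    lower_gate_z: float = -5.0
    n_frames: int = 2000
    stride_ps: float = 250.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subunits < 1 or self.helix_residues < 2:
            raise SpecError("need at least one subunit with two residues")
        if self.gate_aperture <= 0:
            raise SpecError("gate aperture must be positive (negative clearance)")
        if self.gate_open_aperture is not None and self.gate_open_aperture <= 0:
            raise SpecError("open aperture must be positive")
        if not 0.0 <= self.open_fraction <= 1.0:
            raise SpecError("open_fraction must lie in [0, 1]")
        if self.helix_radius_from_axis <= 0 or self.gate_ring_atoms < 3:
            raise SpecError("invalid gate/bundle geometry")
        if self.upper_gate_z <= self.lower_gate_z:
            raise SpecError("upper gate plane must lie above the lower gate plane")
        if self.n_frames < 1:
            raise SpecError("need at least one frame")
        sig = np.broadcast_to(np.asarray(self.per_residue_sigma, dtype=float),
                              (self.helix_residues,)).copy()
        if np.any(sig < 0):
            raise SpecError("per-residue σ must be non-negative")
        self.per_residue_sigma = sig

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.arange(self.residue_start, self.residue_start + self.helix_residues)


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d bonded to c with angle(b,c,d) and torsion(a,b,c,d)."""
    ang, tor = np.radians(angle_deg), np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tor),
                  bond * np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def ideal_helix_backbone(n_residues: int, phi: float = HELIX_PHI,
                         psi: float = HELIX_PSI, omega: float = 180.0) -> np.ndarray:
    """Backbone N, CA, C, O coordinates of an ideal helix, shape (n, 4, 3).

    Built by sequential internal-coordinate placement with standard bond
    lengths and angles; the default (φ, ψ) = (−57°, −47°) is the canonical
    α-helix.
    """
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    atoms = [[N, CA, C]]
    for _ in range(1, n_residues):
        Np, CAp, Cp = atoms[-1]
        Nn = _nerf(Np, CAp, Cp, _B_C_N, _A_CA_C_N, psi)
        CAn = _nerf(CAp, Cp, Nn, _B_N_CA, _A_C_N_CA, omega)
        Cn = _nerf(Cp, Nn, CAn, _B_CA_C, _A_N_CA_C, phi)
        atoms.append([Nn, CAn, Cn])
    out = np.empty((n_residues, 4, 3))
    for i, (Ni, CAi, Ci) in enumerate(atoms):
        out[i, 0], out[i, 1], out[i, 2] = Ni, CAi, Ci
        if i + 1 < n_residues:
            Nn = atoms[i + 1][0]
            out[i, 3] = _nerf(Nn, CAi, Ci, _B_C_O, _A_CA_C_O, psi + 180.0)
        else:
            out[i, 3] = _nerf(Ni, CAi, Ci, _B_C_O, _A_CA_C_O, psi + 180.0)
    return out


def _axis_to_z(coords: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Rotate so the helix principal axis points along +z, centroid at origin."""
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
    return rot.apply(coords - centroid)


def _gate_ring(spec: ChannelSpec, aperture: float) -> np.ndarray:
    ring_radius = aperture + _GATE_VDW
    theta = 2.0 * np.pi * np.arange(spec.gate_ring_atoms) / spec.gate_ring_atoms
    ring = np.zeros((spec.gate_ring_atoms, 3))
    ring[:, 0] = ring_radius * np.cos(theta)
    ring[:, 1] = ring_radius * np.sin(theta)
    return ring


def _hbond_base(i: int) -> np.ndarray:
    """Anchor point of planted triplet i, far from the pore (lateral 30 Å)."""
    angle = 2.0 * np.pi * (i + 0.25) / 16.0
    return np.array([30.0 * np.cos(angle), 30.0 * np.sin(angle), 12.0 * i - 30.0])


def _hbond_coords(base: np.ndarray, ad_distance: float) -> np.ndarray:
    """D, H, A coordinates along x̂ from the anchor; angle(A,H,D) = 180°."""
    return np.vstack([base,
                      base + np.array([1.0, 0.0, 0.0]),
                      base + np.array([ad_distance, 0.0, 0.0])])


def _water_start_positions(spec: ChannelSpec) -> np.ndarray:
    n = spec.n_waters_traversing + spec.n_waters_resident
    pos = np.zeros((n, 3))
    for i in range(spec.n_waters_traversing):
        pos[i] = [0.5, 0.3 * i, spec.lower_gate_z - 7.0]
    for j in range(spec.n_waters_resident):
        i = spec.n_waters_traversing + j
        pos[i] = [1.0 + 0.3 * j, -1.0, spec.lower_gate_z - 4.0]
    return pos


def build_reference(spec: ChannelSpec) -> StructureFrame:
    """The noise-free reference structure of a channel spec.

    Helix k sits at ``helix_radius_from_axis`` from the z axis, rotated by
    2πk/n about z; tilts are applied about the helix centroid — radial
    tilt first (about the tangential direction), tangential tilt second
    (about the radial direction), so the twist angle recovered after
    projecting out the radial component equals the tangential tilt
    exactly, independent of the radial tilt.
    """
    bb = ideal_helix_backbone(spec.helix_residues)
    flat = bb.reshape(-1, 3)
    flat = _axis_to_z(flat, bb[:, 1, :])
    tan = Rotation.from_euler("x", spec.helix_tilt_tangential_deg, degrees=True)
    rad = Rotation.from_euler("y", spec.helix_tilt_radial_deg, degrees=True)
    flat = (tan * rad).apply(flat)
    flat = flat + np.array([spec.helix_radius_from_axis, 0.0, 0.0])

    names, elements, resnums, resnames, chains, xyz = [], [], [], [], [], []
    chain_letters = [chr(ord("A") + k) for k in range(spec.n_subunits)]
    for k, chain in enumerate(chain_letters):
        rot = Rotation.from_euler("z", 360.0 * k / spec.n_subunits, degrees=True)
        coords_k = rot.apply(flat)
        for r, resnum in enumerate(spec.residue_numbers):
            for a, (name, el) in enumerate(zip(("N", "CA", "C", "O"), "NCCO")):
                names.append(name)
                elements.append(el)
                resnums.append(int(resnum))
                resnames.append("ALA")
                chains.append(chain)
                xyz.append(coords_k[r * 4 + a])

    for p in _gate_ring(spec, spec.gate_aperture):
        names.append("C")
        elements.append("C")
        resnums.append(801)
        resnames.append("GLY")
        chains.append("P")
        xyz.append(p)

    for i, w in enumerate(_water_start_positions(spec)):
        names.append("OW")
        elements.append("O")
        resnums.append(901 + i)
        resnames.append("HOH")
        chains.append("W")
        xyz.append(w)

    for i, hb in enumerate(spec.planted_hbonds):
        base = _hbond_base(i)
        dha = _hbond_coords(base, hb.present_distance)
        for name, el, resnum, resname in (("N", "N", 1001 + 2 * i, "DNR"),
                                          ("H1", "H", 1001 + 2 * i, "DNR"),
                                          ("O", "O", 1002 + 2 * i, "ACP")):
            names.append(name)
            elements.append(el)
            resnums.append(resnum)
            resnames.append(resname)
            chains.append("X")
        xyz.extend(dha)

    top = Topology(names, elements, resnums, resnames, chains)
    return StructureFrame(top, np.asarray(xyz))


def _atom_sigma(spec: ChannelSpec, topology: Topology) -> np.ndarray:
    """Per-atom Gaussian σ: the residue's σ for helix atoms, 0 elsewhere."""
    sigma = np.zeros(topology.n_atoms)
    res_sigma = dict(zip(spec.residue_numbers, spec.per_residue_sigma))
    for i, (chain, resnum) in enumerate(zip(topology.chain_id, topology.residue_number)):
        if chain in {chr(ord("A") + k) for k in range(spec.n_subunits)}:
            sigma[i] = res_sigma.get(int(resnum), 0.0)
    return sigma


def simulate_trajectory(spec: ChannelSpec) -> tuple[Trajectory, dict]:
    """Generate a trajectory and its ground-truth manifest.

    Helix atoms are displaced from the reference by i.i.d. Gaussian noise
    per frame (no autocorrelation).  Gate, water and planted-triplet atoms
    follow the deterministic paths described in the module docstring.
    """
    rng = np.random.default_rng(spec.seed)
    ref = build_reference(spec)
    top = ref.topology
    n, m = spec.n_frames, top.n_atoms
    coords = np.repeat(ref.coordinates[None], n, axis=0)

    sigma = _atom_sigma(spec, top)
    noisy = sigma > 0
    if np.any(noisy):
        coords[:, noisy, :] += rng.standard_normal((n, int(noisy.sum()), 3)) * \
            sigma[noisy][None, :, None]

    # gate: exact planted open/closed frame sets
    gate_idx = np.flatnonzero(top.chain_id == "P")
    n_open = int(round(spec.open_fraction * n)) if spec.gate_open_aperture else 0
    open_frames = np.sort(rng.permutation(n)[:n_open])
    if n_open:
        scale = (spec.gate_open_aperture + _GATE_VDW) / (spec.gate_aperture + _GATE_VDW)
        sub = coords[np.ix_(open_frames, gate_idx)]
        sub[:, :, :2] *= scale
        coords[np.ix_(open_frames, gate_idx)] = sub

    # waters
    t = np.arange(n)
    frac = t / max(n - 1, 1)
    water_idx = np.flatnonzero(top.chain_id == "W")
    for i in range(spec.n_waters_traversing):
        ai = water_idx[i]
        z0 = spec.lower_gate_z - 7.0
        z1 = spec.upper_gate_z + 7.0
        coords[:, ai, 2] = z0 + (z1 - z0) * frac
    for j in range(spec.n_waters_resident):
        ai = water_idx[spec.n_waters_traversing + j]
        coords[:, ai, 2] = (spec.lower_gate_z - 4.0
                            + 1.5 * np.sin(2.0 * np.pi * (3.0 * frac + 0.17 * j)))

    # planted H-bonds: exact present-frame sets
    hbond_truth = []
    for i, hb in enumerate(spec.planted_hbonds):
        base = _hbond_base(i)
        triplet = np.flatnonzero((top.chain_id == "X")
                                 & np.isin(top.residue_number, [1001 + 2 * i, 1002 + 2 * i]))
        n_present = int(round(hb.occupancy * n))
        present = np.zeros(n, dtype=bool)
        present[np.sort(rng.permutation(n)[:n_present])] = True
        coords[np.ix_(present, triplet)] = _hbond_coords(base, hb.present_distance)
        coords[np.ix_(~present, triplet)] = _hbond_coords(base, hb.absent_distance)
        hbond_truth.append({
            "donor": ["X", 1001 + 2 * i, "N"],
            "hydrogen": ["X", 1001 + 2 * i, "H1"],
            "acceptor": ["X", 1002 + 2 * i, "O"],
            "occupancy": n_present / n,
            "n_present": n_present,
        })

    traj = Trajectory(top, coords, stride_ps=spec.stride_ps)
    manifest = {
        "seed": spec.seed,
        "n_frames": n,
        "n_atoms": m,
        "residue_numbers": spec.residue_numbers.tolist(),
        "per_residue_sigma": spec.per_residue_sigma.tolist(),
        "tilt_tangential_deg": spec.helix_tilt_tangential_deg,
        "tilt_radial_deg": spec.helix_tilt_radial_deg,
        "gate": {
            "closed_aperture": spec.gate_aperture,
            "open_aperture": spec.gate_open_aperture,
            "n_open_frames": n_open,
            "open_fraction": n_open / n,
            "open_frames": open_frames.tolist(),
        },
        "waters": {
            "n_traversing": spec.n_waters_traversing,
            "n_resident": spec.n_waters_resident,
            "upper_gate_z": spec.upper_gate_z,
            "lower_gate_z": spec.lower_gate_z,
        },
        "hbonds": hbond_truth,
        "spec": _spec_dict(spec),
    }
    return traj, manifest


def _spec_dict(spec: ChannelSpec) -> dict:
    d = asdict(spec)
    d["per_residue_sigma"] = np.asarray(spec.per_residue_sigma).tolist()
    d["planted_hbonds"] = [asdict(h) for h in spec.planted_hbonds]
    return d


def morph_states(spec_a: ChannelSpec, spec_b: ChannelSpec):
    """Two trajectories sharing one topology but differing in ground truth.

    Used to emulate a pair of states (e.g. oxidized vs reduced) that differ
    in gate aperture dynamics, tilt angles, fluctuation profile and planted
    H-bonds.  Returns ``((traj_a, manifest_a), (traj_b, manifest_b))``.
    """
    for attr in ("n_subunits", "residue_start", "helix_residues", "gate_ring_atoms",
                 "n_waters_traversing", "n_waters_resident", "n_frames"):
        if getattr(spec_a, attr) != getattr(spec_b, attr):
            raise SpecError(f"specs differ in topology-defining field '{attr}'")
    if len(spec_a.planted_hbonds) != len(spec_b.planted_hbonds):
        raise SpecError("specs must plant the same number of H-bond triplets")
    return simulate_trajectory(spec_a), simulate_trajectory(spec_b)


def planted_dihedral_series(n_frames: int, n_dihedrals: int,
                            mode_sigmas_deg: dict[int, float],
                            base_deg: float = HELIX_PHI,
                            seed: int = 0) -> np.ndarray:
    """Angle time series (deg) with independent Gaussian modes planted.

    Dihedral ``j`` listed in ``mode_sigmas_deg`` fluctuates about
    ``base_deg`` with the given σ; all others are frozen at ``base_deg``.
    Used to test that dihedral PCA recovers planted variance ordering.
    """
    rng = np.random.default_rng(seed)
    angles = np.full((n_frames, n_dihedrals), base_deg)
    for j, s in mode_sigmas_deg.items():
        angles[:, j] = base_deg + rng.standard_normal(n_frames) * s
    return ((angles + 180.0) % 360.0) - 180.0


def write_dataset(spec: ChannelSpec, out_dir) -> dict:
    """Write reference PDB, DCD trajectory and manifest JSON to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj, manifest = simulate_trajectory(spec)
    ref = build_reference(spec)
    write_structure(ref, out / "reference.pdb")
    write_trajectory(traj, out / "topology.pdb", out / "trajectory.dcd")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
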