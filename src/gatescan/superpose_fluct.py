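"""Least-squares superposition, RMSD/RMSF, and fractional RMSF comparison.

The state comparison statistic is the fractional fluctuation change

    ΔRMSF/RMSF̄ = 2 (RMSF₁ − RMSF₂) / (RMSF₁ + RMSF₂),

a unitless, antisymmetric quantity bounded in [−2, 2] (±2 when one state
is completely rigid), computed per residue after both trajectories have
been superposed on a common fit region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import AlignmentError, DegenerateFitError
from .structure_io import Selection, StructureFrame, Trajectory, resolve_selection

__all__ = [
    "RmsfProfile",
    "FluctuationComparison",
    "superpose",
    "rmsd_series",
    "rmsf_profile",
    "delta_rmsf",
    "chain_average",
]

DEFAULT_FIT_SPEC = "residues 432-713, backbone"


@dataclass
class RmsfProfile:
    """Per-residue RMSF (Å), keyed by (chain_id, residue_number)."""

    residue_keys: list
    rmsf: np.ndarray
    state_label: str = ""
    fit_spec: str = ""

    def __post_init__(self):
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF values must be non-negative")
        if len(self.residue_keys) != len(self.rmsf):
            raise AlignmentError("one RMSF value per residue required")


@dataclass
class FluctuationComparison:
    """Per-residue ΔRMSF/RMSF̄ between two labeled states."""

    residue_keys: list
    delta_frac: np.ndarray
    state_labels: tuple = ("state1", "state2")

    def __post_init__(self):
        self.delta_frac = np.asarray(self.delta_frac, dtype=float)
        if np.any(np.abs(self.delta_frac) > 2.0 + 1e-12):
            raise ValueError("ΔRMSF/RMSF̄ is bounded in [-2, 2]")


def _check_fit_atoms(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear")


def superpose(traj: Trajectory, fit: Selection,
              reference: StructureFrame | int = 0) -> Trajectory:
    """Rigid-body superpose every frame onto a reference over the fit atoms.

    The optimal rotation is the least-squares (Kabsch) solution; the
    resulting transform is applied to *all* atoms of the frame.
    ``reference`` is a frame index (default: the first frame) or a
    StructureFrame with compatible atom ordering.
    """
    if isinstance(reference, int):
        ref_coords = traj.coordinates[reference]
    else:
        ref_coords = reference.coordinates
    idx = fit.atom_indices
    ref_fit = ref_coords[idx]
    _check_fit_atoms(ref_fit)
    ref_centroid = ref_fit.mean(axis=0)
    ref_centered = ref_fit - ref_centroid

    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        mob = traj.coordinates[f]
        mob_centroid = mob[idx].mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # align_vectors warns on exact fits
            rot, _ = Rotation.align_vectors(ref_centered, mob[idx] - mob_centroid)
        out[f] = rot.apply(mob - mob_centroid) + ref_centroid
    return Trajectory(traj.topology, out, stride_ps=traj.stride_ps)


def rmsd_series(traj: Trajectory, sel: Selection,
                reference: StructureFrame | int = 0) -> np.ndarray:
    """Per-frame RMSD (Å) of the selected atoms from the reference."""
    if isinstance(reference, int):
        ref = traj.coordinates[reference]
    else:
        ref = reference.coordinates
    idx = sel.atom_indices
    diff = traj.coordinates[:, idx, :] - ref[None, idx, :]
    return np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))


def rmsf_profile(traj: Trajectory, sel: Selection | None = None,
                 state_label: str = "", representative_atom: str = "CA") -> RmsfProfile:
    """Per-residue RMSF about the time-mean position, for superposed input.

    One value per residue in the selection, taken from the representative
    atom (Cα by default).  A single-frame trajectory yields zeros with a
    warning.
    """
    top = traj.topology
    if sel is None:
        sel = resolve_selection(top, f"atoms {representative_atom}")
    names = np.array([str(n).upper() for n in top.atom_name[sel.atom_indices]])
    rep = sel.atom_indices[names == representative_atom.upper()]
    if rep.size == 0:
        rep = sel.atom_indices
    if traj.n_frames < 2:
        warnings.warn("single-frame trajectory: RMSF defined as all zeros")
    coords = traj.coordinates[:, rep, :]
    mean = coords.mean(axis=0)
    fluct = np.sqrt(((coords - mean[None]) ** 2).sum(axis=2).mean(axis=0))
    keys = [(str(c), int(r)) for c, r in zip(top.chain_id[rep], top.residue_number[rep])]
    return RmsfProfile(keys, fluct, state_label=state_label)


def delta_rmsf(p1: RmsfProfile, p2: RmsfProfile) -> FluctuationComparison:
    """Fractional RMSF change 2(RMSF₁−RMSF₂)/(RMSF₁+RMSF₂) per residue.

    Residues where both profiles are exactly zero get 0 by convention.
    """
    if p1.residue_keys != p2.residue_keys:
        raise AlignmentError("RMSF profiles cover different residue sets")
    s = p1.rmsf + p2.rmsf
    d = np.zeros_like(s)
    nz = s > 0
    d[nz] = 2.0 * (p1.rmsf[nz] - p2.rmsf[nz]) / s[nz]
    return FluctuationComparison(list(p1.residue_keys), d,
                                 state_labels=(p1.state_label, p2.state_label))


def chain_average(profile: RmsfProfile) -> RmsfProfile:
    """Average RMSF across chains, keyed by residue number alone.

    Subunits of a symmetric tetramer sample equivalent environments, so a
    chain-averaged profile halves the sampling noise of state comparisons.
    """
    by_res: dict[int, list] = {}
    order = []
    for (chain, resnum), v in zip(profile.residue_keys, profile.rmsf):
        if resnum not in by_res:
            by_res[resnum] = []
            order.append(resnum)
        by_res[resnum].append(v)
    keys = [("*", r) for r in order]
    vals = np.array([np.mean(by_res[r]) for r in order])
    return RmsfProfile(keys, vals, state_label=profile.state_label,
                       fit_spec=profile.fit_spec)
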