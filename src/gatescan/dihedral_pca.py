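"""Backbone dihedral extraction, circular PCA, and free-energy surfaces.

Dihedral PCA (dPCA) maps every backbone φ/ψ angle θ to the pair
(sin θ, cos θ) before building the covariance matrix, which removes the
−180°/+180° periodicity artifact that plagues PCA on raw angles.  The
covariance matrix of the stacked sin/cos variables is eigendecomposed
and frames are projected onto the leading components; a raw-angle mode
is available behind a flag for comparison.

The free-energy surface over (PC1, PC2) is estimated from the projection
histogram as F = −k_B·T·ln(ρ/ρ_max), so the most populated bin sits at
F = 0 and empty bins are flagged undefined rather than infinite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import Trajectory

__all__ = [
    "DihedralSeries",
    "PcaResult",
    "FreeEnergySurface",
    "extract_dihedrals",
    "dpca",
    "free_energy_surface",
    "dihedral_angles",
    "KB_KCAL_PER_MOL_K",
]

KB_KCAL_PER_MOL_K = 0.0019872041   # Boltzmann constant, kcal/(mol K)
DEFAULT_TEMPERATURE_K = 303.0      # simulation temperature
CHAIN_BREAK_CN = 2.0               # Å; C(i)–N(i+1) beyond this breaks the chain


@dataclass
class DihedralSeries:
    """Per-frame φ/ψ angles in degrees, wrapped to (−180°, 180°]."""

    angles: np.ndarray     # (n_frames, n_dihedrals), degrees
    labels: list           # (chain_id, residue_number, "phi"|"psi") per column

    def __post_init__(self):
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if self.angles.shape[1] != len(self.labels):
            raise ValueError("one label per dihedral column required")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray           # descending, >= 0
    eigenvectors: np.ndarray          # columns, orthonormal
    projections: np.ndarray           # (n_frames, n_components)
    explained_variance_ratio: np.ndarray
    total_variance: float


@dataclass
class FreeEnergySurface:
    pc1_edges: np.ndarray
    pc2_edges: np.ndarray
    free_energy: np.ndarray           # kcal/mol; NaN where the bin is empty
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def dihedral_angles(p0, p1, p2, p3) -> np.ndarray:
    """Torsion angle(s) in degrees for points of shape (..., 3)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - (b0 * b1).sum(axis=-1, keepdims=True) * b1
    w = b2 - (b2 * b1).sum(axis=-1, keepdims=True) * b1
    x = (v * w).sum(axis=-1)
    y = (np.cross(b1, v) * w).sum(axis=-1)
    return np.degrees(np.arctan2(y, x))


def _wrap(angles: np.ndarray) -> np.ndarray:
    out = ((angles + 180.0) % 360.0) - 180.0
    out[out == -180.0] = 180.0
    return out


def extract_dihedrals(traj: Trajectory, chains: list[str] | None = None,
                      residue_range: tuple[int, int] | None = None) -> DihedralSeries:
    """Backbone φ/ψ time series from consecutive N, CA, C atoms.

    Terminal residues lacking a complete dihedral are excluded.  Chain
    continuity is judged on the time-mean structure: a mean C(i)–N(i+1)
    distance above 2 Å breaks the chain and the spanning dihedrals are
    skipped with a warning.
    """
    top = traj.topology
    mean_coords = traj.coordinates.mean(axis=0)
    if chains is None:
        chains = sorted(set(top.chain_id))
    name_up = np.array([str(n).upper() for n in top.atom_name])
    cols, labels = [], []
    for chain in chains:
        cmask = top.chain_id == chain
        if residue_range is not None:
            cmask = cmask & (top.residue_number >= residue_range[0]) \
                          & (top.residue_number <= residue_range[1])
        resnums = sorted(set(top.residue_number[cmask].tolist()))
        bb = {}
        for r in resnums:
            rmask = cmask & (top.residue_number == r)
            idx = {}
            for nm in ("N", "CA", "C"):
                found = np.flatnonzero(rmask & (name_up == nm))
                if found.size:
                    idx[nm] = int(found[0])
            if len(idx) == 3:
                bb[r] = idx
        ordered = [r for r in resnums if r in bb]
        for i, r in enumerate(ordered):
            prev_r = ordered[i - 1] if i > 0 else None
            next_r = ordered[i + 1] if i + 1 < len(ordered) else None
            # phi(i): C(i-1), N(i), CA(i), C(i)
            if prev_r is not None and prev_r == r - 1:
                cn = np.linalg.norm(mean_coords[bb[r]["N"]] - mean_coords[bb[prev_r]["C"]])
                if cn <= CHAIN_BREAK_CN:
                    ang = dihedral_angles(
                        traj.coordinates[:, bb[prev_r]["C"]],
                        traj.coordinates[:, bb[r]["N"]],
                        traj.coordinates[:, bb[r]["CA"]],
                        traj.coordinates[:, bb[r]["C"]])
                    cols.append(_wrap(ang))
                    labels.append((str(chain), int(r), "phi"))
                else:
                    warnings.warn(f"chain {chain}: break before residue {r} "
                                  f"(C–N {cn:.2f} Å); phi skipped")
            # psi(i): N(i), CA(i), C(i), N(i+1)
            if next_r is not None and next_r == r + 1:
                cn = np.linalg.norm(mean_coords[bb[next_r]["N"]] - mean_coords[bb[r]["C"]])
                if cn <= CHAIN_BREAK_CN:
                    ang = dihedral_angles(
                        traj.coordinates[:, bb[r]["N"]],
                        traj.coordinates[:, bb[r]["CA"]],
                        traj.coordinates[:, bb[r]["C"]],
                        traj.coordinates[:, bb[next_r]["N"]])
                    cols.append(_wrap(ang))
                    labels.append((str(chain), int(r), "psi"))
                else:
                    warnings.warn(f"chain {chain}: break after residue {r} "
                                  f"(C–N {cn:.2f} Å); psi skipped")
    angles = np.column_stack(cols) if cols else np.empty((traj.n_frames, 0))
    return DihedralSeries(angles, labels)


def dpca(series: DihedralSeries, n_components: int = 2,
         circular: bool = True) -> PcaResult:
    """PCA of the (sin, cos)-mapped dihedral covariance matrix.

    With ``circular=False`` the covariance is built on raw angles
    (periodicity-naive; provided for comparison only).  Eigenvalues are
    returned in descending order; the sum of all eigenvalues equals the
    total variance of the input variables.
    """
    if series.n_frames < 2:
        raise ValueError("dPCA needs at least 2 frames")
    rad = np.radians(series.angles)
    if circular:
        X = np.concatenate([np.sin(rad), np.cos(rad)], axis=1)
    else:
        X = series.angles.astype(float)
    Xc = X - X.mean(axis=0)
    if Xc.shape[1] == 0:
        raise ValueError("no dihedrals in series")
    cov = (Xc.T @ Xc) / (series.n_frames - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    k = min(n_components, len(vals))
    proj = Xc @ vecs[:, :k]
    total = float(np.trace(cov))
    ratio = vals[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(vals, vecs, proj, ratio, total)


def free_energy_surface(projections: np.ndarray, bins: int = 50,
                        temperature: float = DEFAULT_TEMPERATURE_K) -> FreeEnergySurface:
    """F(PC1, PC2) = −k_B·T·ln(count / max count) in kcal/mol.

    The minimum over occupied bins is 0 by construction; empty bins are
    NaN (undefined) rather than infinite.
    """
    proj = np.asarray(projections, dtype=float)
    if proj.ndim != 2 or proj.shape[1] < 2:
        raise ValueError("projections must provide at least PC1 and PC2 columns")
    counts, xe, ye = np.histogram2d(proj[:, 0], proj[:, 1], bins=bins)
    if counts.max() == 0:
        raise ValueError("no occupied bins")
    kbt = KB_KCAL_PER_MOL_K * float(temperature)
    with np.errstate(divide="ignore"):
        fe = -kbt * np.log(counts / counts.max())
    fe[counts == 0] = np.nan
    return FreeEnergySurface(xe, ye, fe, float(temperature))
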