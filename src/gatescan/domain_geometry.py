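"""Radius of gyration, helix twist angles, and Cα distance-difference maps.

The twist angle of a pore-lining helix is defined against the channel
(z) axis: fit the helix Cα positions with a least-squares line (the
dominant eigenvector of their positional covariance, sign fixed toward
+z), remove the component along the radial unit vector r (the direction
from the z axis to the helix centroid, z component dropped), and measure
the angle between z and the projected axis.  The projection makes the
angle report tangential lean only — a purely radial lean projects to 0°.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, EmptySelectionError
from .structure_io import Selection, StructureFrame, Trajectory, resolve_selection

__all__ = [
    "GyrationSeries",
    "TwistFrame",
    "DistanceMatrix",
    "StateComparison",
    "rg_series",
    "twist_angle",
    "twist_series",
    "distance_matrix",
    "compare_states",
    "cys_pair_sg_distances",
]

DEFAULT_S6_RANGE = (658, 692)  # residues A658–Q692


@dataclass
class GyrationSeries:
    label: str
    rg: np.ndarray  # (n_frames,), Å

    def __post_init__(self):
        self.rg = np.asarray(self.rg, dtype=float)
        if np.any(self.rg < 0):
            raise ValueError("Rg must be non-negative")


@dataclass
class TwistFrame:
    chain_id: str
    principal_axis: np.ndarray   # unit 3-vector, z component >= 0
    radial_vector: np.ndarray    # unit 3-vector perpendicular to z
    twist_angle: float           # degrees in [0, 90]
    undefined: bool = False


@dataclass
class DistanceMatrix:
    """Time-mean Cα–Cα distances within one subunit."""

    residue_numbers: np.ndarray
    matrix: np.ndarray           # (n_res, n_res), Å, symmetric, zero diagonal
    state_label: str = ""
    chain_id: str = ""

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=float)


@dataclass
class StateComparison:
    """ΔD = D₁ − D₂ and the Pearson correlation map of its rows."""

    residue_numbers: np.ndarray
    delta: np.ndarray            # antisymmetric under state swap
    correlation: np.ndarray      # C[i, j] = corr(ΔD row i, ΔD row j); NaN where undefined
    state_labels: tuple = ("state1", "state2")


def rg_series(traj: Trajectory, sel: Selection, label: str = "") -> GyrationSeries:
    """Unweighted radius of gyration of the selected atoms per frame.

    Rg = sqrt(mean over atoms of squared distance to their centroid).
    """
    idx = sel.atom_indices
    if idx.size == 0:
        raise EmptySelectionError("Rg selection is empty")
    coords = traj.coordinates[:, idx, :]
    centroid = coords.mean(axis=1, keepdims=True)
    rg = np.sqrt(((coords - centroid) ** 2).sum(axis=2).mean(axis=1))
    return GyrationSeries(label or sel.label, rg)


def _principal_axis(ca: np.ndarray) -> np.ndarray:
    centered = ca - ca.mean(axis=0)
    cov = centered.T @ centered / len(ca)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(vals)]
    if axis[2] < 0:
        axis = -axis
    return axis


def twist_angle(frame: StructureFrame, helix: Selection,
                chain_id: str = "") -> TwistFrame:
    """Twist angle of one helix in one frame (degrees, [0°, 90°]).

    Requires at least 3 Cα atoms in the selection.  The angle is flagged
    undefined when the projection of the principal axis onto the plane
    perpendicular to r vanishes, or when the helix centroid sits on the
    z axis (r undefined).
    """
    ca = frame.coordinates[helix.atom_indices]
    if ca.shape[0] < 3:
        raise EmptySelectionError("twist angle needs at least 3 helix atoms")
    axis = _principal_axis(ca)
    centroid = ca.mean(axis=0)
    r = np.array([centroid[0], centroid[1], 0.0])
    nr = np.linalg.norm(r)
    if nr < 1e-9:
        return TwistFrame(chain_id, axis, np.zeros(3), float("nan"), undefined=True)
    r = r / nr
    proj = axis - (axis @ r) * r
    np_ = np.linalg.norm(proj)
    if np_ < 1e-9:
        return TwistFrame(chain_id, axis, r, float("nan"), undefined=True)
    cosang = np.clip(abs(proj[2]) / np_, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    return TwistFrame(chain_id, axis, r, angle)


def twist_series(traj: Trajectory, residue_range: tuple[int, int] = DEFAULT_S6_RANGE,
                 chains: list[str] | None = None):
    """Per-frame, per-chain twist angles plus the cross-chain mean.

    Returns ``(angles, chains)`` where ``angles`` has shape
    ``(n_frames, n_chains)``; the mean series is ``angles.mean(axis=1)``.
    """
    top = traj.topology
    if chains is None:
        ca_mask = np.array([str(n).upper() == "CA" for n in top.atom_name])
        rn = top.residue_number
        in_range = (rn >= residue_range[0]) & (rn <= residue_range[1])
        chains = sorted(set(top.chain_id[ca_mask & in_range]))
    if not chains:
        raise EmptySelectionError("no chains contain Cα atoms in the helix range")
    sels = [resolve_selection(
        top, f"chain {c}, residues {residue_range[0]}-{residue_range[1]}, atoms CA")
        for c in chains]
    angles = np.empty((traj.n_frames, len(chains)))
    for f in range(traj.n_frames):
        frame = traj.frame(f)
        for j, sel in enumerate(sels):
            angles[f, j] = twist_angle(frame, sel, chain_id=chains[j]).twist_angle
    return angles, chains


def distance_matrix(traj: Trajectory, chain_id: str,
                    state_label: str = "") -> DistanceMatrix:
    """Time-mean pairwise Cα–Cα distance matrix within one subunit.

    Residues lacking a Cα atom are dropped with a warning.
    """
    top = traj.topology
    mask = (top.chain_id == chain_id) & \
        np.array([str(n).upper() == "CA" for n in top.atom_name])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptySelectionError(f"chain {chain_id} has no Cα atoms")
    resnums = top.residue_number[idx]
    chain_res = sorted(set(top.residue_number[top.chain_id == chain_id]))
    missing = set(chain_res) - set(int(r) for r in resnums)
    if missing:
        warnings.warn(f"chain {chain_id}: residues without Cα dropped: {sorted(missing)}")
    coords = traj.coordinates[:, idx, :]                      # (F, R, 3)
    diff = coords[:, :, None, :] - coords[:, None, :, :]      # (F, R, R, 3)
    mean_d = np.sqrt((diff ** 2).sum(axis=3)).mean(axis=0)
    return DistanceMatrix(resnums, mean_d, state_label=state_label, chain_id=chain_id)


def compare_states(d1: DistanceMatrix, d2: DistanceMatrix) -> StateComparison:
    """ΔD = D₁ − D₂ and the row-wise Pearson correlation heat map.

    Each residue's row of ΔD is its vector of distance changes to all
    other residues; C[i, j] correlates those vectors.  Zero-variance rows
    (e.g. identical states) yield NaN, flagged rather than set to 1.
    """
    if not np.array_equal(d1.residue_numbers, d2.residue_numbers):
        raise AlignmentError("distance matrices cover different residue sets")
    delta = d1.matrix - d2.matrix
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr = np.corrcoef(delta)
    sd = delta.std(axis=1)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return StateComparison(d1.residue_numbers.copy(), delta, corr,
                           state_labels=(d1.state_label, d2.state_label))


def cys_pair_sg_distances(frame: StructureFrame, residue_a: int = 386,
                          residue_b: int = 390) -> dict[str, float]:
    """Per-chain Sγ–Sγ distance (Å) of a cysteine pair.

    A distance of roughly 2.0–2.1 Å indicates a formed disulfide bond;
    free thiol pairs sit well beyond 3 Å.  Chains lacking either SG atom
    are omitted.
    """
    top = frame.topology
    name_up = np.array([str(n).upper() for n in top.atom_name])
    out = {}
    for chain in sorted(set(top.chain_id)):
        cmask = top.chain_id == chain
        ia = np.flatnonzero(cmask & (top.residue_number == residue_a) & (name_up == "SG"))
        ib = np.flatnonzero(cmask & (top.residue_number == residue_b) & (name_up == "SG"))
        if ia.size and ib.size:
            out[str(chain)] = float(np.linalg.norm(
                frame.coordinates[ia[0]] - frame.coordinates[ib[0]]))
    return out
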