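"""Geometric hydrogen-bond detection, occupancy, and state differentials.

A hydrogen bond between acceptor A, donor hydrogen H and donor heavy
atom D is present when (both strict)

    d(A, D) < 3.0 Å   and   angle(A, H, D) > 135°,

with the angle measured at H.  Occupancy is the fraction of trajectory
frames in which a candidate triplet satisfies both criteria; the
differential report lists bonds whose occupancy changes by more than a
threshold (default 0.20, absolute) between two states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .structure_io import StructureFrame, Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "find_donors",
    "find_acceptors",
    "detect_hbonds",
    "occupancy",
    "differential",
]

DEFAULT_DIFFERENTIAL_THRESHOLD = 0.20


@dataclass
class HBondCriteria:
    max_ad_distance: float = 3.0   # Å, strict
    min_ahd_angle: float = 135.0   # degrees at H, strict

    def __post_init__(self):
        if self.max_ad_distance <= 0:
            raise ValueError("distance criterion must be positive")
        if not 0.0 < self.min_ahd_angle <= 180.0:
            raise ValueError("angle criterion must lie in (0, 180]")


@dataclass
class HBondRecord:
    donor: tuple        # (chain, resnum, atom_name)
    hydrogen: tuple
    acceptor: tuple
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    occupancy: float
    state_label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def key(self):
        return (self.donor, self.hydrogen, self.acceptor)


def _atom_key(top: Topology, i: int) -> tuple:
    return (str(top.chain_id[i]), int(top.residue_number[i]), str(top.atom_name[i]))


#: heavy-atom elements eligible as donors/acceptors (S excluded by default:
#: the bonds of interest are backbone/side-chain N–O contacts)
DEFAULT_POLAR_ELEMENTS = ("N", "O")


def find_donors(topology: Topology, coordinates: np.ndarray,
                elements: tuple = DEFAULT_POLAR_ELEMENTS,
                max_dh_distance: float = 1.2) -> list[tuple[int, int]]:
    """(donor_heavy, hydrogen) index pairs inferred from geometry.

    Each hydrogen is paired with the nearest eligible heavy atom within
    ``max_dh_distance`` of it.  Raises :class:`ConfigurationError` if the
    topology has no hydrogens (supply a protonated topology).
    """
    el = np.array([str(e).upper() for e in topology.element])
    h_idx = np.flatnonzero(el == "H")
    if h_idx.size == 0:
        raise ConfigurationError(
            "no hydrogens in topology: hydrogen-bond analysis requires a "
            "protonated topology")
    heavy_idx = np.flatnonzero(np.isin(el, [e.upper() for e in elements]))
    pairs = []
    for h in h_idx:
        d = np.sqrt(((coordinates[heavy_idx] - coordinates[h]) ** 2).sum(axis=1))
        j = int(np.argmin(d))
        if d[j] < max_dh_distance:
            pairs.append((int(heavy_idx[j]), int(h)))
    return pairs


def find_acceptors(topology: Topology,
                   elements: tuple = DEFAULT_POLAR_ELEMENTS) -> np.ndarray:
    el = np.array([str(e).upper() for e in topology.element])
    return np.flatnonzero(np.isin(el, [e.upper() for e in elements]))


def _geometry_ok(coords: np.ndarray, d: int, h: int, a: int,
                 criteria: HBondCriteria) -> bool:
    ad = np.linalg.norm(coords[a] - coords[d])
    if not ad < criteria.max_ad_distance:
        return False
    v1 = coords[a] - coords[h]
    v2 = coords[d] - coords[h]
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0:
        return False
    angle = np.degrees(np.arccos(np.clip(v1 @ v2 / denom, -1.0, 1.0)))
    return angle > criteria.min_ahd_angle


def detect_hbonds(frame: StructureFrame, criteria: HBondCriteria | None = None,
                  donors: list | None = None,
                  acceptors: np.ndarray | None = None) -> set[tuple[int, int, int]]:
    """Set of (donor, hydrogen, acceptor) index triplets present in a frame.

    Donor–hydrogen pairing is inferred from the frame geometry unless
    given; intra-residue pairs are excluded.
    """
    criteria = criteria or HBondCriteria()
    top = frame.topology
    coords = frame.coordinates
    if donors is None:
        donors = find_donors(top, coords)
    if acceptors is None:
        acceptors = find_acceptors(top)
    present = set()
    for d, h in donors:
        for a in acceptors:
            if a == d or (top.chain_id[a] == top.chain_id[d]
                          and top.residue_number[a] == top.residue_number[d]):
                continue
            if _geometry_ok(coords, d, h, int(a), criteria):
                present.add((d, h, int(a)))
    return present


def occupancy(traj: Trajectory, criteria: HBondCriteria | None = None,
              donors: list | None = None, acceptors: np.ndarray | None = None,
              state_label: str = "", prefilter_distance: float = 8.0) -> list[HBondRecord]:
    """Per-candidate-pair occupancy over a trajectory; never-present pairs omitted.

    Candidate (donor, acceptor) pairs whose A–D distance never drops below
    ``prefilter_distance`` are skipped without per-frame evaluation; every
    other pair is evaluated in every frame, so occupancies are exact.
    """
    criteria = criteria or HBondCriteria()
    top = traj.topology
    if donors is None:
        donors = find_donors(top, traj.coordinates[0])
    if acceptors is None:
        acceptors = find_acceptors(top)
    coords = traj.coordinates
    # a donor heavy atom with several hydrogens forms the bond in a frame
    # if ANY of its hydrogens satisfies the angle criterion
    by_donor: dict[int, list[int]] = {}
    for d, h in donors:
        by_donor.setdefault(d, []).append(h)
    records = []
    for d, hydrogens in by_donor.items():
        ad_all = np.sqrt(((coords[:, acceptors, :] - coords[:, d:d + 1, :]) ** 2).sum(axis=2))
        near = np.flatnonzero(ad_all.min(axis=0) < prefilter_distance)
        for j in near:
            a = int(acceptors[j])
            if a == d or (top.chain_id[a] == top.chain_id[d]
                          and top.residue_number[a] == top.residue_number[d]):
                continue
            dist_ok = ad_all[:, j] < criteria.max_ad_distance
            present = np.zeros(traj.n_frames, dtype=bool)
            best_h, best_count = hydrogens[0], -1
            for h in hydrogens:
                v1 = coords[:, a, :] - coords[:, h, :]
                v2 = coords[:, d, :] - coords[:, h, :]
                denom = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                cosang = np.divide((v1 * v2).sum(axis=1), denom,
                                   out=np.full(len(denom), -1.0), where=denom > 0)
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                sat = dist_ok & (angle > criteria.min_ahd_angle)
                present |= sat
                if int(sat.sum()) > best_count:
                    best_h, best_count = h, int(sat.sum())
            n_present = int(present.sum())
            if n_present:
                records.append(HBondRecord(
                    _atom_key(top, d), _atom_key(top, best_h), _atom_key(top, a),
                    d, best_h, a, n_present / traj.n_frames, state_label=state_label))
    return records


def differential(records1: list[HBondRecord], records2: list[HBondRecord],
                 threshold: float = DEFAULT_DIFFERENTIAL_THRESHOLD) -> pd.DataFrame:
    """Bonds whose occupancy differs by more than the threshold (absolute).

    Bonds present in only one state use 0 for the other.  Returns a frame
    sorted by |delta| descending with columns donor, hydrogen, acceptor,
    occupancy_state1, occupancy_state2, delta.
    """
    occ1 = {r.key: r.occupancy for r in records1}
    occ2 = {r.key: r.occupancy for r in records2}
    rows = []
    for key in sorted(set(occ1) | set(occ2), key=str):
        o1, o2 = occ1.get(key, 0.0), occ2.get(key, 0.0)
        delta = o1 - o2
        if abs(delta) > threshold:
            rows.append({"donor": key[0], "hydrogen": key[1], "acceptor": key[2],
                         "occupancy_state1": o1, "occupancy_state2": o2,
                         "delta": delta})
    df = pd.DataFrame(rows, columns=["donor", "hydrogen", "acceptor",
                                     "occupancy_state1", "occupancy_state2", "delta"])
    if len(df):
        df = df.reindex(df["delta"].abs().sort_values(ascending=False).index)
        df = df.reset_index(drop=True)
    return df
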