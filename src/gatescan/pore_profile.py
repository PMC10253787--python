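"""HOLE-style pore-radius profiling, permeability and water-flux counting.

At each axial slice z the pore radius is the radius of the largest probe
sphere whose center lies in that z-plane within a lateral search bound:

    R(z) = max_{|p - c| ≤ bound}  min_i ( |p - x_i| - r_i ),   p in the plane

where x_i are atom centers (3D distances) and r_i their van der Waals
radii.  The maximisation runs a dense coarse lateral grid followed by
nested local grid refinement from the top coarse starts (deterministic
multi-start), and is validated against a brute-force fine-grid oracle in
the test suite.  Radii are capped at ``max_radius`` and flagged where the
cap or an empty slice is hit.

Water permeability of a frame is judged by a strict threshold on the
minimal radius (default 1.15 Å, the radius below which single-file water
passage is blocked); complete water traversals of the two gate planes are
counted as permeation events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Selection, StructureFrame, Trajectory

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap

__all__ = [
    "PoreProfile",
    "PermeabilityStats",
    "WaterFlux",
    "PermeationEvent",
    "pore_radius_profile",
    "min_radius_series",
    "permeable_fraction",
    "count_permeations",
]

DEFAULT_PERMEABILITY_THRESHOLD = 1.15  # Å


@dataclass
class PoreProfile:
    """Per-frame radius-vs-z curves plus the minimal-radius time series."""

    z_grid: np.ndarray                   # (nz,)
    radius: np.ndarray                   # (n_frames, nz), Å
    capped: np.ndarray                   # (n_frames, nz) bool
    min_radius: np.ndarray = field(init=False)
    min_radius_z: np.ndarray = field(init=False)

    def __post_init__(self):
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.radius = np.atleast_2d(np.asarray(self.radius, dtype=float))
        self.capped = np.atleast_2d(np.asarray(self.capped, dtype=bool))
        imin = np.argmin(self.radius, axis=1)  # ties -> smallest z (first index)
        self.min_radius = self.radius[np.arange(len(imin)), imin]
        self.min_radius_z = self.z_grid[imin]


@dataclass
class PermeabilityStats:
    permeable_fraction: float
    threshold: float
    n_frames: int

    def __post_init__(self):
        if not 0.0 <= self.permeable_fraction <= 1.0:
            raise ValueError("permeable fraction must lie in [0, 1]")


@dataclass
class PermeationEvent:
    water_index: int       # atom index of the water oxygen
    entry_frame: int
    exit_frame: int
    direction: str         # "up" (lower -> upper) or "down"


@dataclass
class WaterFlux:
    n_permeation_events: int
    events: list


def _disk_grid(step: float, bound: float) -> np.ndarray:
    ax = np.arange(-bound, bound + 0.5 * step, step)
    gx, gy = np.meshgrid(ax, ax)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return pts[(pts ** 2).sum(axis=1) <= bound ** 2]


def _refine(point: np.ndarray, z: float, atoms: np.ndarray, radii: np.ndarray,
            center: np.ndarray, bound: float, step: float, levels: int = 3):
    """Nested local grid search around one start point; returns (f, point)."""
    best_p = point
    dists = np.sqrt(((best_p - atoms[:, :2]) ** 2).sum(axis=1) + (z - atoms[:, 2]) ** 2)
    best_f = float(np.min(dists - radii))
    span = step
    for _ in range(levels):
        local = _disk_grid(span / 4.0, span) + best_p
        ok = ((local - center) ** 2).sum(axis=1) <= bound ** 2
        local = local[ok]
        if local.size == 0:
            break
        d2 = ((local[:, None, :] - atoms[None, :, :2]) ** 2).sum(axis=2)
        f = np.sqrt(d2 + (z - atoms[:, 2])[None, :] ** 2) - radii[None, :]
        fmin = f.min(axis=1)
        k = int(np.argmax(fmin))
        if fmin[k] > best_f:
            best_f = float(fmin[k])
            best_p = local[k]
        span /= 4.0
    return best_f, best_p


@njit(cache=True)
def _profile_frames_kernel(coords, radii, z_grid, center, max_radius,
                           lateral_bound, offsets, coarse_step, n_starts,
                           out_r, out_c):  # pragma: no cover - exercised via wrapper
    """Compiled coarse-grid + nested-refinement search over all frames."""
    n_frames, n_atoms = coords.shape[0], coords.shape[1]
    nz = z_grid.shape[0]
    n_pts = offsets.shape[0]
    rmax = 0.0
    for i in range(n_atoms):
        if radii[i] > rmax:
            rmax = radii[i]
    margin = max_radius + rmax + 1.0
    bound2 = lateral_bound * lateral_bound
    near = np.empty(n_atoms, dtype=np.int64)
    cand = np.empty(n_atoms, dtype=np.int64)
    top_f = np.empty(n_starts)
    top_x = np.empty(n_starts)
    top_y = np.empty(n_starts)
    for f in range(n_frames):
        for s in range(nz):
            z = z_grid[s]
            n_near = 0
            for i in range(n_atoms):
                if abs(coords[f, i, 2] - z) <= margin:
                    near[n_near] = i
                    n_near += 1
            if n_near == 0:
                out_r[f, s] = max_radius
                out_c[f, s] = True
                continue
            # coarse grid: keep the n_starts best points
            n_top = 0
            for p in range(n_pts):
                px = center[0] + offsets[p, 0]
                py = center[1] + offsets[p, 1]
                fmin = 1.0e30
                for k in range(n_near):
                    i = near[k]
                    dx = px - coords[f, i, 0]
                    dy = py - coords[f, i, 1]
                    dz = z - coords[f, i, 2]
                    v = (dx * dx + dy * dy + dz * dz) ** 0.5 - radii[i]
                    if v < fmin:
                        fmin = v
                # insertion into descending top list
                if n_top < n_starts or fmin > top_f[n_top - 1]:
                    j = min(n_top, n_starts - 1)
                    while j > 0 and top_f[j - 1] < fmin:
                        top_f[j] = top_f[j - 1]
                        top_x[j] = top_x[j - 1]
                        top_y[j] = top_y[j - 1]
                        j -= 1
                    top_f[j] = fmin
                    top_x[j] = px
                    top_y[j] = py
                    if n_top < n_starts:
                        n_top += 1
            best = -1.0e30
            for t in range(n_top):
                bf = top_f[t]
                bx = top_x[t]
                by = top_y[t]
                # atoms that can still matter within 2 coarse steps of the start
                n_cand = 0
                thresh = bf + 2.0 * coarse_step + 0.5
                for k in range(n_near):
                    i = near[k]
                    dx = bx - coords[f, i, 0]
                    dy = by - coords[f, i, 1]
                    dz = z - coords[f, i, 2]
                    if (dx * dx + dy * dy + dz * dz) ** 0.5 - radii[i] < thresh:
                        cand[n_cand] = i
                        n_cand += 1
                span = coarse_step
                for _level in range(3):
                    step = span / 4.0
                    nbx = bx
                    nby = by
                    nbf = bf
                    for ix in range(-4, 5):
                        for iy in range(-4, 5):
                            px = bx + ix * step
                            py = by + iy * step
                            ddx = px - center[0]
                            ddy = py - center[1]
                            if ddx * ddx + ddy * ddy > bound2:
                                continue
                            fmin = 1.0e30
                            for k in range(n_cand):
                                i = cand[k]
                                dx = px - coords[f, i, 0]
                                dy = py - coords[f, i, 1]
                                dz = z - coords[f, i, 2]
                                v = (dx * dx + dy * dy + dz * dz) ** 0.5 - radii[i]
                                if v < fmin:
                                    fmin = v
                            if fmin > nbf:
                                nbf = fmin
                                nbx = px
                                nby = py
                    bx = nbx
                    by = nby
                    bf = nbf
                    span = step
                if bf > best:
                    best = bf
            if best >= max_radius:
                out_r[f, s] = max_radius
                out_c[f, s] = True
            else:
                out_r[f, s] = best if best > 0.0 else 0.0
                out_c[f, s] = False


def _profile_frame(coords: np.ndarray, radii: np.ndarray, z_grid: np.ndarray,
                   center: np.ndarray, max_radius: float, lateral_bound: float,
                   coarse_step: float, n_starts: int):
    """Radius(z) for one coordinate set; fully vectorised coarse stage."""
    nz = len(z_grid)
    out = np.full(nz, max_radius)
    capped = np.zeros(nz, dtype=bool)
    rmax = float(radii.max()) if len(radii) else 0.0
    margin = max_radius + rmax + 1.0
    zmask = (coords[:, 2] >= z_grid[0] - margin) & (coords[:, 2] <= z_grid[-1] + margin)
    atoms = coords[zmask]
    arad = radii[zmask]
    if atoms.shape[0] == 0:
        return out, np.ones(nz, dtype=bool)
    grid = _disk_grid(coarse_step, lateral_bound) + center
    lat2 = ((grid[:, None, :] - atoms[None, :, :2]) ** 2).sum(axis=2)  # (P, M)
    for s, z in enumerate(z_grid):
        near = np.abs(atoms[:, 2] - z) <= margin
        if not near.any():
            capped[s] = True
            continue
        f = np.sqrt(lat2[:, near] + (z - atoms[near, 2])[None, :] ** 2) - arad[None, near]
        fmin = f.min(axis=1)
        starts = np.argsort(fmin)[::-1][:n_starts]
        best = -np.inf
        for k in starts:
            fk, _ = _refine(grid[k], z, atoms[near], arad[near], center,
                            lateral_bound, coarse_step)
            best = max(best, fk)
        if best >= max_radius:
            out[s] = max_radius
            capped[s] = True
        else:
            out[s] = max(best, 0.0)
    return out, capped


def _profile_frames(coords3: np.ndarray, radii: np.ndarray, z_grid: np.ndarray,
                    center: np.ndarray, max_radius: float, lateral_bound: float,
                    coarse_step: float, n_starts: int):
    """Dispatch to the compiled kernel when numba is available."""
    n_frames = coords3.shape[0]
    out_r = np.empty((n_frames, len(z_grid)))
    out_c = np.empty((n_frames, len(z_grid)), dtype=np.bool_)
    if _HAVE_NUMBA:
        offsets = _disk_grid(coarse_step, lateral_bound)
        _profile_frames_kernel(
            np.ascontiguousarray(coords3, dtype=np.float64),
            np.ascontiguousarray(radii, dtype=np.float64),
            np.ascontiguousarray(z_grid, dtype=np.float64),
            np.ascontiguousarray(center, dtype=np.float64),
            float(max_radius), float(lateral_bound),
            np.ascontiguousarray(offsets, dtype=np.float64),
            float(coarse_step), int(n_starts), out_r, out_c)
    else:
        for f in range(n_frames):
            out_r[f], out_c[f] = _profile_frame(
                coords3[f], radii, z_grid, center, max_radius,
                lateral_bound, coarse_step, n_starts)
    return out_r, out_c


def pore_radius_profile(frame: StructureFrame, radii: np.ndarray,
                        z_range: tuple[float, float], z_step: float = 0.25,
                        center: tuple[float, float] = (0.0, 0.0),
                        max_radius: float = 10.0, lateral_bound: float = 8.0,
                        coarse_step: float = 0.8, n_starts: int = 5) -> PoreProfile:
    """Pore radius along z for a single frame oriented with the pore on z.

    ``radii`` are per-atom van der Waals radii matching the frame's atoms
    (use :func:`gatescan.structure_io.assign_vdw` on a protein-only
    subset).  Returns a single-frame :class:`PoreProfile`.
    """
    z_grid = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    r, c = _profile_frames(frame.coordinates[None], np.asarray(radii, dtype=float),
                           z_grid, np.asarray(center, dtype=float),
                           max_radius, lateral_bound, coarse_step, n_starts)
    return PoreProfile(z_grid, r, c)


def min_radius_series(traj: Trajectory, sel: Selection, radii: np.ndarray,
                      z_range: tuple[float, float], z_step: float = 0.25,
                      center: tuple[float, float] = (0.0, 0.0),
                      max_radius: float = 10.0, lateral_bound: float = 8.0,
                      coarse_step: float = 0.8, n_starts: int = 5) -> PoreProfile:
    """Per-frame radius profiles and the minimal-radius time series.

    ``sel`` restricts the atoms considered (typically the protein);
    ``radii`` must be per-atom values for the *selected* atoms (or for the
    whole topology, in which case they are subset automatically).  The
    per-frame minimum's z location breaks ties toward the smallest z.
    """
    radii = np.asarray(radii, dtype=float)
    idx = sel.atom_indices
    if radii.shape[0] == traj.n_atoms:
        radii = radii[idx]
    elif radii.shape[0] != len(idx):
        raise ValueError("radii must match either the topology or the selection")
    z_grid = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    all_r, all_c = _profile_frames(traj.coordinates[:, idx, :], radii, z_grid,
                                   np.asarray(center, dtype=float), max_radius,
                                   lateral_bound, coarse_step, n_starts)
    return PoreProfile(z_grid, all_r, all_c)


def permeable_fraction(profile: PoreProfile | np.ndarray,
                       threshold: float = DEFAULT_PERMEABILITY_THRESHOLD) -> PermeabilityStats:
    """Fraction of frames whose minimal pore radius strictly exceeds the threshold."""
    series = profile.min_radius if isinstance(profile, PoreProfile) else np.asarray(profile)
    if series.size == 0:
        raise ValueError("empty minimal-radius series")
    frac = float(np.mean(series > threshold))
    return PermeabilityStats(frac, threshold, int(series.size))


def count_permeations(traj: Trajectory, water_sel: Selection,
                      upper_gate_z: float, lower_gate_z: float,
                      lateral_bound: float = 8.0) -> WaterFlux:
    """Count complete water traversals of both gate planes.

    One event per water per complete passage from beyond one gate plane to
    beyond the other while staying within ``lateral_bound`` of the pore
    axis whenever between the planes; partial entries are not counted.
    """
    if upper_gate_z <= lower_gate_z:
        raise ValueError("gate planes must satisfy upper_gate_z > lower_gate_z")
    events = []
    for ai in water_sel.atom_indices:
        z = traj.coordinates[:, ai, 2]
        lat = np.sqrt((traj.coordinates[:, ai, :2] ** 2).sum(axis=1))
        region = np.where(z > upper_gate_z, 1, np.where(z < lower_gate_z, -1, 0))
        side = None          # last plane cleared: -1 below, +1 above
        entry_frame = None
        inside_ok = True
        for f in range(traj.n_frames):
            reg = region[f]
            if reg == 0:
                if side is not None and entry_frame is None:
                    entry_frame = f
                inside_ok = inside_ok and (lat[f] <= lateral_bound)
                continue
            if side is None:
                side = reg
            elif reg != side:
                # crossed to the opposite side: complete traversal
                if inside_ok:
                    events.append(PermeationEvent(
                        water_index=int(ai),
                        entry_frame=int(entry_frame if entry_frame is not None else f),
                        exit_frame=int(f),
                        direction="up" if reg == 1 else "down"))
                side = reg
                entry_frame = None
                inside_ok = True
            else:
                entry_frame = None
                inside_ok = True
    return WaterFlux(len(events), events)
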