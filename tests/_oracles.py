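"""Independent brute-force oracles used to validate the fast implementations."""

import numpy as np


def brute_force_pore_radius(coords, radii, z, lateral_bound=8.0, grid_step=0.05,
                            max_radius=10.0, center=(0.0, 0.0)):
    """Pore radius at one z slice by exhaustive lateral grid search.

    Evaluates f(p) = min_i(|p - x_i| - r_i) at every point of a dense
    0.05 Å grid covering the search disk and returns the maximum, capped.
    Deliberately simple and slow; the reference the local search must match.
    """
    ax = np.arange(-lateral_bound, lateral_bound + 0.5 * grid_step, grid_step)
    gx, gy = np.meshgrid(ax, ax)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts[(pts ** 2).sum(axis=1) <= lateral_bound ** 2] + np.asarray(center)
    d2 = ((pts[:, None, :] - coords[None, :, :2]) ** 2).sum(axis=2)
    f = (np.sqrt(d2 + (z - coords[:, 2])[None, :] ** 2) - radii[None, :]).min(axis=1)
    return float(min(f.max(), max_radius))


def ring_coords(radius, z, n_atoms=100, phase=0.0):
    """Coordinates of a dense ring of atoms in the plane z = const."""
    theta = 2.0 * np.pi * np.arange(n_atoms) / n_atoms + phase
    out = np.empty((n_atoms, 3))
    out[:, 0] = radius * np.cos(theta)
    out[:, 1] = radius * np.sin(theta)
    out[:, 2] = z
    return out


def constructed_pores():
    """A battery of synthetic pore geometries: (name, coords, radii, z_values).

    Rings, stacked rings, cones and mixed-radius rings, covering the
    regimes the profiler must handle.
    """
    pores = []
    c = ring_coords(5.0, 0.0)
    pores.append(("single_ring", c, np.full(len(c), 1.7), [0.0]))
    c = np.vstack([ring_coords(5.0, 0.0), ring_coords(4.0, 3.0)])
    pores.append(("stacked_rings", c, np.full(len(c), 1.7), [0.0, 1.5, 3.0]))
    c = np.vstack([ring_coords(6.0 - 0.5 * k, 1.0 * k) for k in range(7)])
    pores.append(("cone", c, np.full(len(c), 1.7), [0.0, 2.0, 4.0, 6.0]))
    c = ring_coords(4.0, 0.0, phase=0.3)
    pores.append(("offset_phase_ring", c, np.full(len(c), 1.52), [0.0, 0.5]))
    c = np.vstack([ring_coords(3.5, -2.0), ring_coords(5.5, 0.0), ring_coords(3.5, 2.0)])
    pores.append(("hourglass_inverted", c, np.full(len(c), 1.7), [-2.0, 0.0, 2.0]))
    c = np.vstack([ring_coords(5.5, -2.0), ring_coords(3.0, 0.0), ring_coords(5.5, 2.0)])
    pores.append(("hourglass", c, np.full(len(c), 1.7), [-2.0, -1.0, 0.0]))
    c = ring_coords(7.5, 0.0, n_atoms=160)
    pores.append(("wide_ring", c, np.full(len(c), 1.8), [0.0]))
    c = ring_coords(2.5, 0.0)
    pores.append(("narrow_ring", c, np.full(len(c), 1.55), [0.0, 0.25]))
    rng = np.random.default_rng(11)
    c = ring_coords(5.0, 0.0, n_atoms=80)
    radii = rng.uniform(1.4, 2.0, len(c))
    pores.append(("mixed_vdw_ring", c, radii, [0.0, 0.75]))
    c = np.vstack([ring_coords(4.5, 0.0, n_atoms=60, phase=0.1),
                   ring_coords(4.5, 0.8, n_atoms=60, phase=0.4)])
    pores.append(("double_offset", c, np.full(len(c), 1.65), [0.0, 0.4, 0.8]))
    c = np.vstack([ring_coords(5.0, 0.0),
                   ring_coords(5.0, 0.0, n_atoms=8, phase=0.05) + np.array([1.5, 0, 0])])
    pores.append(("asymmetric_clutter", c, np.full(len(c), 1.7), [0.0]))
    c = np.vstack([ring_coords(6.5, -1.0, n_atoms=120), ring_coords(6.5, 1.0, n_atoms=120)])
    pores.append(("paired_wide", c, np.full(len(c), 1.9), [-1.0, 0.0, 1.0]))
    return pores
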