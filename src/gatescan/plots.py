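"""Matplotlib renderings of the analysis outputs (heatmaps, contours)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_heatmap", "plot_free_energy_surface", "plot_min_radius_series"]


def plot_heatmap(matrix, residue_numbers, path, title="", cmap="RdBu_r"):
    fig, ax = plt.subplots(figsize=(6, 5))
    vmax = np.nanmax(np.abs(matrix)) or 1.0
    extent = [residue_numbers[0], residue_numbers[-1],
              residue_numbers[-1], residue_numbers[0]]
    im = ax.imshow(matrix, cmap=cmap, vmin=-vmax, vmax=vmax, extent=extent)
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_free_energy_surface(fes, path):
    fig, ax = plt.subplots(figsize=(6, 5))
    x = 0.5 * (fes.pc1_edges[:-1] + fes.pc1_edges[1:])
    y = 0.5 * (fes.pc2_edges[:-1] + fes.pc2_edges[1:])
    im = ax.contourf(x, y, fes.free_energy.T, levels=12, cmap="jet")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(f"Free energy (kcal/mol), T = {fes.temperature:.0f} K")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_min_radius_series(profile, path, threshold=None):
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(profile.min_radius, lw=0.8)
    if threshold is not None:
        ax.axhline(threshold, color="r", ls="--", lw=0.8)
    ax.set_xlabel("frame")
    ax.set_ylabel("min pore radius (Å)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
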