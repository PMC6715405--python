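"""PNG heatmap rendering of lattice fields.

Follows the figure convention of the study this simulator emulates:
white background outside the domain (absence of molecules), intensity
scaled between 0 and the field maximum, with the color bar reporting
molecules per voxel.
"""

from __future__ import annotations

import numpy as np

from .geometry import LatticeGeometry

__all__ = ["render_field", "save_frames"]


def render_field(geometry: LatticeGeometry, values, path, *, z=None,
                 title: str | None = None, cmap: str = "inferno") -> None:
    """Render one cross-section to a PNG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.asarray(values, dtype=float)
    if geometry.dimensionality == 3:
        if z is None:
            z = geometry.height // 2
        sel = geometry.coords[:, 2] == int(z)
    else:
        sel = np.ones(geometry.n_voxels, dtype=bool)
    n = 2 * geometry.radius + 1
    grid = np.full((n, n), np.nan)
    xs = geometry.coords[sel, 0]
    ys = geometry.coords[sel, 1]
    grid[ys, xs] = vals[sel]

    fig, ax = plt.subplots(figsize=(4, 4))
    vmax = np.nanmax(grid)
    m = ax.imshow(np.ma.masked_invalid(grid), origin="lower", cmap=cmap,
                  vmin=0, vmax=vmax if vmax > 0 else 1)
    m.cmap.set_bad("white")
    ax.set_facecolor("white")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(m, ax=ax, shrink=0.8, label="molecules per voxel")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_frames(trajectory, out_dir, species: str = "H", z=None) -> list:
    """Write one numbered PNG per snapshot; returns the file paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, state in enumerate(trajectory.snapshot_states()):
        p = out_dir / f"frame_{i:05d}.png"
        render_field(trajectory.geometry, state.species_counts(species), p,
                     z=z, title=f"[{species}] t={state.time:.2f}")
        paths.append(p)
    return paths
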