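"""Discretized spatial domains for stem cross-sections and whole stems.

The simulation domain is a set of unit cubic voxels forming either a disc
(a 2D stem cross-section) or a right circular cylinder (a 3D stem).
Boundaries are reflective (zero-flux Neumann): a voxel simply has no
neighbor across a boundary face, so no event can move a molecule out of
the domain.

Coordinates are 0-based integer triples ``(x, y, z)``; ``z`` is the
longitudinal (apical-basal) axis, with *basipetal* meaning decreasing
``z``. In 2D the ``z`` coordinate is always 0. A voxel belongs to the
disc of radius ``R`` iff the Euclidean distance from its center to the
domain center is <= ``R``; the center sits on a voxel center so masks are
symmetric under the lattice's reflections.

Named sub-regions:

``INTERIOR``
    Everything that is not in the cortical shell.
``CORTICAL_SHELL``
    The outer radial fraction of each cross-section (default 4%), where
    the peripheral inhibitor is produced.
``APEX_LAYER``
    The top z-layer of a cylinder (3D only), where the apically produced
    hormone is sourced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "INTERIOR",
    "CORTICAL_SHELL",
    "APEX_LAYER",
    "REGION_CODES",
    "LatticeGeometry",
    "build_disc",
    "build_cylinder",
    "shell_mask",
    "apex_mask",
]

INTERIOR = "INTERIOR"
CORTICAL_SHELL = "CORTICAL_SHELL"
APEX_LAYER = "APEX_LAYER"

#: Stable integer codes used by the simulation kernel's region bitmask.
REGION_CODES = {INTERIOR: 0, CORTICAL_SHELL: 1, APEX_LAYER: 2}

#: Face-neighbor offsets in kernel order: -x, +x, -y, +y, -z (down), +z (up).
FACE_OFFSETS = np.array(
    [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)],
    dtype=np.int64,
)
DOWN_DIR = 4  # index into FACE_OFFSETS of the basipetal (-z) direction
UP_DIR = 5


@dataclass(frozen=True)
class LatticeGeometry:
    """A voxelized disc or cylinder with face adjacency and region labels.

    Attributes
    ----------
    dimensionality : int
        2 for a disc, 3 for a cylinder.
    radius : int
        Disc/cylinder radius in voxels.
    height : int
        Number of z-layers (1 for a disc).
    coords : (n_voxels, 3) int array
        Integer (x, y, z) coordinates of each voxel.
    neighbors : (n_voxels, 6) int array
        Voxel index of the face neighbor in each of the six directions
        (-x, +x, -y, +y, -z, +z), or -1 where the neighbor is outside the
        domain (this omission realizes the reflective boundary).
    radial : (n_voxels,) float array
        Euclidean distance of each voxel center from the cross-section
        center axis.
    shell_fraction : float
        Radial fraction used to define the cortical shell.
    """

    dimensionality: int
    radius: int
    height: int
    coords: np.ndarray
    neighbors: np.ndarray
    radial: np.ndarray
    shell_fraction: float = 0.04
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def n_directions(self) -> int:
        """Number of face directions the dimensionality supports (4 or 6)."""
        return 4 if self.dimensionality == 2 else 6

    def voxel_index(self, x: int, y: int, z: int = 0) -> int:
        """Index of the voxel at integer coordinates, or raise KeyError."""
        return self._index[(int(x), int(y), int(z))]

    def region_labels(self) -> np.ndarray:
        """Per-voxel region bitmask (CORTICAL_SHELL=1, APEX_LAYER=2).

        A voxel can be both in the shell and at the apex; INTERIOR is the
        absence of the shell bit.
        """
        labels = np.zeros(self.n_voxels, dtype=np.int64)
        labels[shell_mask(self, self.shell_fraction)] |= 1
        if self.dimensionality == 3:
            labels[apex_mask(self)] |= 2
        return labels

    def degree(self) -> np.ndarray:
        """Number of in-domain face neighbors of each voxel."""
        return (self.neighbors >= 0).sum(axis=1)

    def to_dataframe(self):
        """Voxel list (x, y, z, r, region) as a pandas DataFrame."""
        import pandas as pd

        labels = self.region_labels()
        region = np.where(labels & 1, CORTICAL_SHELL, INTERIOR)
        region = np.where(labels & 2, APEX_LAYER, region)
        return pd.DataFrame(
            {
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "r": self.radial,
                "region": region,
            }
        )

    def grid_shape(self) -> tuple:
        """Shape of the dense bounding grid (ny, nx) or (nz, ny, nx)."""
        n = 2 * self.radius + 1
        if self.dimensionality == 2:
            return (n, n)
        return (self.height, n, n)

    def embed(self, values: np.ndarray, fill=0.0) -> np.ndarray:
        """Scatter a per-voxel vector onto the dense bounding grid.

        Returns an array of :meth:`grid_shape`; cells outside the domain
        hold ``fill``. 2D grids are indexed ``[y, x]``, 3D ``[z, y, x]``.
        """
        grid = np.full(self.grid_shape(), fill, dtype=np.asarray(values).dtype)
        x, y, z = self.coords.T
        if self.dimensionality == 2:
            grid[y, x] = values
        else:
            grid[z, y, x] = values
        return grid


def _build(radius: int, height: int, dimensionality: int,
           shell_fraction: float = 0.04) -> LatticeGeometry:
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if height < 1:
        raise ValueError(f"height must be >= 1, got {height}")
    n = 2 * radius + 1
    ax = np.arange(n)
    xx, yy = np.meshgrid(ax, ax, indexing="xy")
    rr = np.hypot(xx - radius, yy - radius)
    inside = rr <= radius + 1e-12
    ys, xs = np.nonzero(inside)
    n_disc = xs.size

    coords = np.empty((n_disc * height, 3), dtype=np.int64)
    for z in range(height):
        sl = slice(z * n_disc, (z + 1) * n_disc)
        coords[sl, 0] = xs
        coords[sl, 1] = ys
        coords[sl, 2] = z
    radial = np.tile(rr[ys, xs], height)

    index = {(int(x), int(y), int(z)): i for i, (x, y, z) in enumerate(coords)}
    ndir = 4 if dimensionality == 2 else 6
    neighbors = np.full((coords.shape[0], 6), -1, dtype=np.int64)
    for i, (x, y, z) in enumerate(coords):
        for d in range(ndir):
            dx, dy, dz = FACE_OFFSETS[d]
            j = index.get((int(x + dx), int(y + dy), int(z + dz)))
            if j is not None:
                neighbors[i, d] = j

    return LatticeGeometry(
        dimensionality=dimensionality,
        radius=radius,
        height=height,
        coords=coords,
        neighbors=neighbors,
        radial=radial,
        shell_fraction=shell_fraction,
        _index=index,
    )


def build_disc(radius_voxels: int, shell_fraction: float = 0.04) -> LatticeGeometry:
    """Build a 2D disc of the given radius (in voxels).

    The disc is the set of lattice points whose center lies within
    ``radius_voxels`` of the center point.
    """
    return _build(int(radius_voxels), 1, 2, shell_fraction)


def build_cylinder(radius_voxels: int, height_voxels: int,
                   shell_fraction: float = 0.04) -> LatticeGeometry:
    """Build a 3D right circular cylinder: a disc extruded over z-layers."""
    return _build(int(radius_voxels), int(height_voxels), 3, shell_fraction)


def shell_mask(geometry: LatticeGeometry, fraction: float = 0.04) -> np.ndarray:
    """Boolean mask of the cortical shell: voxels with r >= (1 - fraction) * R.

    Applied per z-layer in 3D, so the shell is a cylindrical sleeve. On a
    discrete lattice the shell is kept at least one voxel wide (inner
    radius capped at R - 1): at small desk-scale radii a thin fractional
    shell would otherwise capture only the few voxels at exactly r = R,
    which no continuum-scale shell does.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"shell fraction must be in (0, 1), got {fraction}")
    inner = min((1.0 - fraction) * geometry.radius, geometry.radius - 1.0)
    return geometry.radial >= inner - 1e-12


def apex_mask(geometry: LatticeGeometry) -> np.ndarray:
    """Boolean mask of the apex: exactly the voxels in the top z-layer."""
    if geometry.dimensionality != 3:
        raise ValueError("apex_mask requires a 3D (cylinder) geometry")
    return geometry.coords[:, 2] == geometry.height - 1
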