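"""Quantification of simulated vascular patterning.

A high-activator spot in a stem cross-section is read as a vascular
bundle. This module detects supra-threshold spots (connected components
of voxels with count > threshold), summarizes their number and
equivalent diameters, measures radial zonation (the width of the
SVB-free annulus between the cortical shell and the central bundle
zone), tests trajectory stationarity, and drives the diffusion-rate
sweep over (D_H, D_B/D_H) grids with replicate seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import LatticeGeometry, build_disc
from . import engine as _engine
from .network import make_model

__all__ = [
    "FACE",
    "FACE_AND_DIAGONAL",
    "Spot",
    "SpotSummary",
    "ZonationProfile",
    "SweepResult",
    "detect_spots",
    "zonation",
    "stationarity",
    "sweep",
    "relative_threshold",
]

FACE = "FACE"
FACE_AND_DIAGONAL = "FACE_AND_DIAGONAL"


@dataclass(frozen=True)
class Spot:
    """One connected supra-threshold region in a cross-section."""

    voxels: tuple            # voxel indices into the geometry
    centroid: tuple          # (x, y) in lattice coordinates
    area: int                # number of voxels
    equivalent_diameter: float
    max_count: int


@dataclass
class SpotSummary:
    """All spots detected in one field at one threshold."""

    threshold: float
    connectivity: str
    spots: list

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def diameters(self) -> np.ndarray:
        return np.array([s.equivalent_diameter for s in self.spots])

    @property
    def mean_diameter(self) -> float:
        return float(self.diameters.mean()) if self.spots else float("nan")

    @property
    def median_diameter(self) -> float:
        return float(np.median(self.diameters)) if self.spots else float("nan")

    def mask(self, geometry: LatticeGeometry) -> np.ndarray:
        """Boolean per-voxel mask of all spot voxels."""
        m = np.zeros(geometry.n_voxels, dtype=bool)
        for s in self.spots:
            m[list(s.voxels)] = True
        return m

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": np.arange(self.n_spots),
                "centroid_x": [s.centroid[0] for s in self.spots],
                "centroid_y": [s.centroid[1] for s in self.spots],
                "area": [s.area for s in self.spots],
                "diameter": [s.equivalent_diameter for s in self.spots],
                "max_count": [s.max_count for s in self.spots],
            }
        )


@dataclass
class ZonationProfile:
    """Radial structure of a cross-section pattern.

    ``zone_b_width`` is the radial extent of the annulus, immediately
    inward of the cortical shell, that contains no spot voxel — the
    analog of the SVB-free separation zone between cortex and the
    central bundle-bearing pith.
    """

    bin_edges: np.ndarray
    mean_counts: np.ndarray
    shell_width: float
    zone_b_width: float
    spot_r_max: float  # largest spot-voxel radius outside the shell (nan if none)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_lo": self.bin_edges[:-1],
            "r_hi": self.bin_edges[1:],
            "mean_count": self.mean_counts,
        })


def relative_threshold(values: np.ndarray, fraction: float = 0.5) -> float:
    """Threshold as a fraction of the field maximum.

    The absolute criterion (400 molecules/voxel) is only meaningful at
    the copy-number scale of the original full-size runs; scaled-down
    runs use a stated fraction of the maximum instead (default 50%).
    """
    return float(fraction * np.max(values))


def _slice_to_grid(field_values, geometry: LatticeGeometry, z=None):
    """Embed per-voxel values of one z-slice into a dense (ny, nx) grid."""
    vals = np.asarray(field_values)
    if geometry.dimensionality == 3:
        if z is None:
            raise ValueError("3D field requires a z-slice selection")
        sel = geometry.coords[:, 2] == int(z)
    else:
        if vals.shape[0] != geometry.n_voxels:
            raise ValueError("field length does not match geometry")
        sel = np.ones(geometry.n_voxels, dtype=bool)
    idx = np.nonzero(sel)[0]
    n = 2 * geometry.radius + 1
    grid = np.zeros((n, n), dtype=vals.dtype)
    x = geometry.coords[idx, 0]
    y = geometry.coords[idx, 1]
    grid[y, x] = vals[idx]
    return grid, idx, x, y


def detect_spots(field_values, geometry: LatticeGeometry, threshold: float,
                 connectivity: str = FACE, z=None) -> SpotSummary:
    """Connected components of voxels with count strictly above threshold.

    ``field_values`` is a per-voxel vector on the geometry (counts or
    concentrations); for a 3D geometry a single ``z`` slice must be
    selected. Connectivity FACE (4-neighbor) matches the diffusion
    topology; FACE_AND_DIAGONAL (8-neighbor) is offered for sensitivity
    checks. Equivalent diameter is ``2 sqrt(area / pi)``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if connectivity not in (FACE, FACE_AND_DIAGONAL):
        raise ValueError(f"unknown connectivity {connectivity!r}")
    grid, idx, xs, ys = _slice_to_grid(field_values, geometry, z)
    above = grid > threshold
    structure = (np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
                 if connectivity == FACE else np.ones((3, 3), dtype=int))
    labels, n = ndimage.label(above, structure=structure)

    # map dense-grid positions back to voxel indices
    pos_to_voxel = {(int(y), int(x)): int(i) for i, x, y in zip(idx, xs, ys)}
    vals = np.asarray(field_values)
    spots = []
    for lab in range(1, n + 1):
        yy, xx = np.nonzero(labels == lab)
        voxels = tuple(pos_to_voxel[(int(y), int(x))] for y, x in zip(yy, xx))
        area = len(voxels)
        spots.append(Spot(
            voxels=voxels,
            centroid=(float(xx.mean()), float(yy.mean())),
            area=area,
            equivalent_diameter=2.0 * np.sqrt(area / np.pi),
            max_count=int(np.max(vals[list(voxels)])),
        ))
    spots.sort(key=lambda s: (-s.area, s.centroid))
    return SpotSummary(threshold=float(threshold), connectivity=connectivity,
                       spots=spots)


def zonation(field_values, geometry: LatticeGeometry, threshold: float,
             bin_width: float = 1.0, z=None,
             connectivity: str = FACE) -> ZonationProfile:
    """Radial mean profile and width of the spot-free outer annulus.

    Zone B extends from the inner edge of the cortical shell down to the
    outermost spot voxel that lies outside the shell; with no spots it
    spans the whole non-shell radius.
    """
    R = geometry.radius
    shell_w = geometry.shell_fraction * R
    summary = detect_spots(field_values, geometry, threshold,
                           connectivity=connectivity, z=z)
    if geometry.dimensionality == 3:
        sel = geometry.coords[:, 2] == int(z)
    else:
        sel = np.ones(geometry.n_voxels, dtype=bool)
    r = geometry.radial[sel]
    vals = np.asarray(field_values)[sel]
    edges = np.arange(0.0, R + bin_width, bin_width)
    if edges[-1] < R:
        edges = np.append(edges, R)
    which = np.clip(np.digitize(r, edges) - 1, 0, len(edges) - 2)
    means = np.zeros(len(edges) - 1)
    for b in range(len(edges) - 1):
        m = which == b
        means[b] = vals[m].mean() if m.any() else 0.0

    inner_edge = min((1.0 - geometry.shell_fraction) * R, R - 1.0)
    spot_mask = summary.mask(geometry)
    spot_r = geometry.radial[spot_mask & (geometry.radial < inner_edge - 1e-12)]
    if spot_r.size:
        # a voxel centered at r occupies roughly [r - 1/2, r + 1/2]:
        # measure the gap from the spot voxel's outer edge
        r_max = float(spot_r.max())
        zone_b = max(inner_edge - (r_max + 0.5), 0.0)
    else:
        r_max = float("nan")
        zone_b = inner_edge
    return ZonationProfile(bin_edges=edges, mean_counts=means,
                           shell_width=shell_w, zone_b_width=zone_b,
                           spot_r_max=r_max)


def stationarity(trajectory, threshold: float, window: int = 2,
                 species: str = "H", jaccard_min: float = 0.9,
                 connectivity: str = FACE, z=None) -> dict:
    """Has the spot pattern stopped changing over the last snapshots?

    Stationary means: over the final ``window`` snapshots, the spot
    count is constant and the Jaccard similarity of consecutive
    supra-threshold masks is >= ``jaccard_min``. Returns a dict with
    ``stationary`` plus the spot-count and Jaccard series for
    diagnostics. The qualitative criterion "the pattern did not change
    substantially" is operationalized this way deliberately.
    """
    states = list(trajectory.snapshot_states())
    if len(states) < 2 or window < 2:
        raise ValueError("stationarity needs >= 2 snapshots in the window")
    states = states[-window:]
    geom = trajectory.geometry
    masks, counts = [], []
    for st in states:
        vals = st.species_counts(species)
        summary = detect_spots(vals, geom, threshold,
                               connectivity=connectivity, z=z)
        masks.append(summary.mask(geom))
        counts.append(summary.n_spots)
    jac = []
    for a, b in zip(masks[:-1], masks[1:]):
        union = (a | b).sum()
        jac.append(1.0 if union == 0 else (a & b).sum() / union)
    stationary = (len(set(counts)) == 1) and all(j >= jaccard_min for j in jac)
    return {
        "stationary": bool(stationary),
        "spot_counts": counts,
        "jaccard": jac,
        "times": [st.time for st in states],
    }


@dataclass
class SweepResult:
    """Spot statistics over a (D_H, D_B/D_H) grid with replicates."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def cell(self, D_H: float, ratio: float) -> pd.DataFrame:
        t = self.table
        return t[(np.isclose(t.D_H, D_H)) & (np.isclose(t.ratio, ratio))]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sweep(base_params: dict, D_H_values, ratio_values, replicates: int = 3,
          *, radius: int = 30, seed: int = 0, max_time: float,
          threshold: float | None = 400.0, threshold_fraction: float = 0.5,
          connectivity: str = FACE, model: str = "HB") -> SweepResult:
    """Run the 2D activator-substrate model over a diffusion-rate grid.

    For each (D_H, D_B/D_H) cell, ``replicates`` independent seeded runs
    are executed on a disc of the given radius; the final field's spots
    are summarized into a tidy table with columns D_H, ratio, replicate,
    seed, n_spots, mean_diameter, max_H, jaccard_last. ``jaccard_last``
    is the Jaccard similarity of the supra-threshold masks of the last
    two snapshots (1.0 for a frozen pattern), the persistence diagnostic.

    ``threshold`` is the absolute spot criterion in molecules/voxel
    (default 400); pass ``None`` to use ``threshold_fraction`` of each
    field's maximum instead (for runs at non-default copy-number scale).
    Replicate seeds are derived deterministically from ``seed``.
    """
    D_H_values = sorted(float(v) for v in D_H_values)
    ratio_values = sorted(float(v) for v in ratio_values)
    if any(v <= 0 for v in D_H_values) or any(v <= 0 for v in ratio_values):
        raise ValueError("diffusion values and ratios must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    rows = []
    for i, dh in enumerate(D_H_values):
        for j, ratio in enumerate(ratio_values):
            for rep in range(replicates):
                run_seed = (int(seed) * 1000003 + i * 9176 + j * 613 + rep
                            ) % (2**31 - 1)
                params = dict(base_params, D_H=dh, D_B=dh * ratio)
                net = make_model(model, params)
                geom = build_disc(radius)
                traj = _engine.run(net, geom, {
                    "seed": run_seed, "max_time": max_time,
                    "snapshot_every_time": max_time / 5.0,
                })
                h = traj.final.species_counts("H")
                max_h = int(h.max())
                thr = (float(threshold) if threshold is not None
                       else relative_threshold(h, threshold_fraction))
                if max_h > thr:
                    summary = detect_spots(h, geom, thr,
                                           connectivity=connectivity)
                    n_spots = summary.n_spots
                    mean_d = summary.mean_diameter
                else:
                    n_spots, mean_d = 0, float("nan")
                prev = traj.fields[-2][:, traj.network.species_index("H")]
                a = prev > thr
                b = h > thr
                union = (a | b).sum()
                jac = 1.0 if union == 0 else float((a & b).sum() / union)
                rows.append({
                    "D_H": dh, "ratio": ratio, "replicate": rep,
                    "seed": run_seed, "threshold": thr, "n_spots": n_spots,
                    "mean_diameter": mean_d, "max_H": max_h,
                    "jaccard_last": jac,
                })
    return SweepResult(pd.DataFrame(rows))
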