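"""Spot detection, zonation, stationarity, and the diffusion sweep."""

import numpy as np
import pytest

from svbsim import engine, geometry, patterns
from svbsim.network import Reaction, ReactionNetwork, Species
from svbsim.patterns import (
    FACE,
    FACE_AND_DIAGONAL,
    detect_spots,
    stationarity,
    sweep,
    zonation,
)


def flood_fill_oracle(grid, threshold, diagonal):
    """Brute-force connected components of grid > threshold."""
    above = grid > threshold
    seen = np.zeros_like(above, dtype=bool)
    comps = []
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if diagonal:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    for y0 in range(grid.shape[0]):
        for x0 in range(grid.shape[1]):
            if above[y0, x0] and not seen[y0, x0]:
                stack, comp = [(y0, x0)], []
                seen[y0, x0] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy, dx in steps:
                        yy, xx = y + dy, x + dx
                        if (0 <= yy < grid.shape[0]
                                and 0 <= xx < grid.shape[1]
                                and above[yy, xx] and not seen[yy, xx]):
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                comps.append(frozenset(comp))
    return set(comps)


def put_disc(field, geom, cx, cy, radius, value):
    d = np.hypot(geom.coords[:, 0] - cx, geom.coords[:, 1] - cy)
    field[d <= radius] = value


class TestDetectSpots:
    def test_empty_field(self, disc10):
        s = detect_spots(np.zeros(disc10.n_voxels), disc10, 400)
        assert s.n_spots == 0

    def test_two_discs(self):
        g = geometry.build_disc(15)
        field = np.zeros(g.n_voxels)
        put_disc(field, g, 7, 15, 3, 500)
        put_disc(field, g, 23, 15, 3, 500)
        s = detect_spots(field, g, 400)
        assert s.n_spots == 2
        disc3 = sum(1 for x in range(-3, 4) for y in range(-3, 4)
                    if x * x + y * y <= 9)
        for spot in s.spots:
            assert spot.area == disc3
            assert spot.equivalent_diameter == \
                pytest.approx(2 * np.sqrt(disc3 / np.pi))
            assert spot.max_count == 500
        assert detect_spots(field, g, 600).n_spots == 0

    def test_threshold_monotonicity(self, disc10):
        rng = np.random.default_rng(5)
        field = rng.integers(0, 800, disc10.n_voxels)
        prev = None
        for thr in (100, 200, 400, 700):
            n = detect_spots(field, disc10, thr).n_spots
            # spot count can only change by merging/vanishing, and the
            # supra-threshold area itself shrinks
            total = sum(s.area for s in detect_spots(field, disc10, thr).spots)
            if prev is not None:
                assert total <= prev
            prev = total

    @pytest.mark.parametrize("connectivity", [FACE, FACE_AND_DIAGONAL])
    def test_matches_flood_fill_oracle(self, connectivity):
        g = geometry.build_disc(9)
        rng = np.random.default_rng(11)
        for _ in range(100):
            field = rng.integers(0, 700, g.n_voxels)
            thr = int(rng.integers(100, 650))
            s = detect_spots(field, g, thr, connectivity=connectivity)
            got = {
                frozenset((int(g.coords[v, 1]), int(g.coords[v, 0]))
                          for v in spot.voxels)
                for spot in s.spots
            }
            grid = g.embed(field)
            expected = flood_fill_oracle(
                grid, thr, diagonal=connectivity == FACE_AND_DIAGONAL)
            assert got == expected

    def test_3d_needs_slice(self, cyl_small):
        field = np.zeros(cyl_small.n_voxels)
        with pytest.raises(ValueError, match="slice"):
            detect_spots(field, cyl_small, 10)
        assert detect_spots(field, cyl_small, 10, z=0).n_spots == 0


class TestZonation:
    def test_spots_only_in_center(self):
        g = geometry.build_disc(20)
        field = np.zeros(g.n_voxels)
        put_disc(field, g, 20, 20, 5, 500)  # spot well inside r < R/2
        prof = zonation(field, g, 400)
        assert prof.zone_b_width >= 10.0 - prof.shell_width

    def test_spots_everywhere(self):
        g = geometry.build_disc(20)
        field = np.full(g.n_voxels, 500.0)
        prof = zonation(field, g, 400)
        assert prof.zone_b_width == 0.0

    def test_constructed_ring_layout(self):
        g = geometry.build_disc(25)
        field = np.zeros(g.n_voxels)
        ring = (g.radial >= 20) & (g.radial <= 21)  # inside the shell edge
        field[ring] = 500
        put_disc(field, g, 25, 25, 2, 500)
        prof = zonation(field, g, 400)
        # outermost spot voxel radius, by construction; zone B runs from
        # the shell's inner edge (r = 24) to that voxel's outer edge
        r_max = g.radial[ring].max()
        assert prof.spot_r_max == pytest.approx(r_max)
        assert prof.zone_b_width == pytest.approx(24.0 - (r_max + 0.5))

    def test_radial_profile_bins(self):
        g = geometry.build_disc(10)
        field = g.radial.copy()  # mean count in a bin ~ bin center
        prof = zonation(field, g, 1000)
        mids = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
        ok = prof.mean_counts > 0
        assert np.all(np.abs(prof.mean_counts[ok] - mids[ok]) < 1.0)


class FakeTrajectory:
    """Minimal stand-in exposing snapshot_states() for stationarity."""

    def __init__(self, geom, fields, times):
        self.geometry = geom
        self.network = ReactionNetwork((Species("H", 0.0),), ())
        self.times = times
        self.fields = [f.reshape(-1, 1) for f in fields]

    def snapshot_states(self):
        from svbsim.engine import StateField

        for t, c in zip(self.times, self.fields):
            yield StateField(self.geometry, ("H",), c, t)


class TestStationarity:
    def test_frozen_pattern(self):
        g = geometry.build_disc(10)
        f = np.zeros(g.n_voxels)
        put_disc(f, g, 10, 10, 3, 500)
        traj = FakeTrajectory(g, [f, f, f], [0.0, 1.0, 2.0])
        out = stationarity(traj, 400, window=3)
        assert out["stationary"] and out["jaccard"] == [1.0, 1.0]

    def test_alternating_disjoint_masks(self):
        g = geometry.build_disc(10)
        a = np.zeros(g.n_voxels)
        b = np.zeros(g.n_voxels)
        put_disc(a, g, 5, 10, 2, 500)
        put_disc(b, g, 15, 10, 2, 500)
        traj = FakeTrajectory(g, [a, b], [0.0, 1.0])
        out = stationarity(traj, 400, window=2)
        assert not out["stationary"]
        assert out["jaccard"] == [0.0]

    def test_drifting_spot_overlap_ratio(self):
        # square 3x3 spots shifted by one voxel: overlap 6, union 12
        g = geometry.build_disc(10)
        a = np.zeros(g.n_voxels)
        b = np.zeros(g.n_voxels)
        for v in range(g.n_voxels):
            x, y = g.coords[v, 0], g.coords[v, 1]
            if 9 <= x <= 11 and 9 <= y <= 11:
                a[v] = 500
            if 10 <= x <= 12 and 9 <= y <= 11:
                b[v] = 500
        traj = FakeTrajectory(g, [a, b], [0.0, 1.0])
        out = stationarity(traj, 400, window=2)
        assert out["jaccard"][0] == pytest.approx(6 / 12)

    def test_needs_two_snapshots(self):
        g = geometry.build_disc(5)
        traj = FakeTrajectory(g, [np.zeros(g.n_voxels)], [0.0])
        with pytest.raises(ValueError):
            stationarity(traj, 400)


class TestSweep:
    def test_single_cell_records_seed(self):
        from svbsim.config import BASE_HB_PARAMS

        res = sweep(BASE_HB_PARAMS, [0.05], [10.0], replicates=1, radius=6,
                    seed=3, max_time=0.5)
        assert len(res.table) == 1
        row = res.table.iloc[0]
        assert row.D_H == 0.05 and row.ratio == 10.0
        assert 0 <= row.seed < 2**31

    def test_deterministic(self):
        from svbsim.config import BASE_HB_PARAMS

        a = sweep(BASE_HB_PARAMS, [0.05], [10.0, 100.0], replicates=2,
                  radius=6, seed=3, max_time=0.5)
        b = sweep(BASE_HB_PARAMS, [0.05], [10.0, 100.0], replicates=2,
                  radius=6, seed=3, max_time=0.5)
        assert a.table.equals(b.table)
        assert len(a.table) == 4

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            sweep({}, [0.0], [10.0], max_time=1.0)


class TestFig5Trends:
    """Qualitative diffusion-rate trends at desk scale, as replicate
    majorities over the shared sweep runs."""

    def test_spot_count_higher_at_high_ratio(self, fig5_runs):
        t = fig5_runs.table
        hi = t[(t.D_H == 0.05) & (t.ratio == 1000.0)].n_spots.values
        lo = t[(t.D_H == 0.05) & (t.ratio == 10.0)].n_spots.values
        wins = sum(h > l for h, l in zip(hi, lo))
        assert wins >= 2

    def test_no_persistent_spots_without_turing_band(self, fig5_runs):
        # below the instability threshold the field stays noisy: nothing
        # reaches the 400-molecule criterion
        t = fig5_runs.table
        lo = t[(t.D_H == 0.05) & (t.ratio == 10.0)]
        assert (lo.n_spots <= 2).all()

    def test_diameter_increases_with_dh(self, fig5_runs):
        t = fig5_runs.table
        d_hi = t[(t.D_H == 0.05) & (t.ratio == 1000.0)].mean_diameter.values
        d_lo = t[(t.D_H == 0.016) & (t.ratio == 1000.0)].mean_diameter.values
        wins = sum(h > l for h, l in zip(d_hi, d_lo))
        assert wins >= 2

    def test_high_ratio_spots_are_persistent(self, fig5_runs):
        t = fig5_runs.table
        hi = t[(t.D_H == 0.05) & (t.ratio == 1000.0)]
        assert (hi.jaccard_last >= 0.8).all()
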