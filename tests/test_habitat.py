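"""Voxel metrics: normalization, binning, strata, patches, vertical variance."""

import numpy as np
import pytest

from strataves.habitat import (
    N_PROFILE_BINS,
    PointCloud,
    VoxelGrid,
    compute_metrics,
    identify_ground,
    normalize_height,
    patch_count,
    strata_amounts,
    vertical_variance,
    voxelize,
)


def _cloud(pts, ground=None):
    pts = np.asarray(pts, float)
    return PointCloud(pts[:, 0], pts[:, 1], pts[:, 2], ground)


def flood_fill_count(raster: np.ndarray) -> int:
    """Independent 8-connectivity component count (iterative BFS)."""
    seen = np.zeros_like(raster, dtype=bool)
    n = 0
    rows, cols = raster.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if raster[r0, c0] and not seen[r0, c0]:
                n += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < rows and 0 <= cc < cols:
                                if raster[rr, cc] and not seen[rr, cc]:
                                    seen[rr, cc] = True
                                    stack.append((rr, cc))
    return n


class TestNormalize:
    def test_flat_ground_constant_offset(self):
        rng = np.random.default_rng(0)
        gx = rng.uniform(0, 20, 200)
        gy = rng.uniform(0, 20, 200)
        ground = _cloud(np.column_stack([gx, gy, np.full(200, 12.0)]),
                        np.ones(200, bool))
        veg = np.column_stack([rng.uniform(5, 15, 50), rng.uniform(5, 15, 50), np.full(50, 17.0)])
        cloud = PointCloud(
            np.concatenate([ground.x, veg[:, 0]]),
            np.concatenate([ground.y, veg[:, 1]]),
            np.concatenate([ground.z, veg[:, 2]]),
            np.concatenate([np.ones(200, bool), np.zeros(50, bool)]),
        )
        norm = normalize_height(cloud)
        assert np.allclose(norm.z[~norm.ground], 5.0)

    def test_tilted_plane_interior_heights_near_zero(self):
        # ground points on z = 0.05x + 0.02y; on-plane points normalize to ~0
        xs, ys = np.meshgrid(np.arange(0, 30, 1.0), np.arange(0, 30, 1.0))
        x, y = xs.ravel(), ys.ravel()
        z = 0.05 * x + 0.02 * y
        cloud = PointCloud(x, y, z, np.ones(x.size, bool))
        norm = normalize_height(cloud, knn=8)
        interior = (norm.x > 5) & (norm.x < 25) & (norm.y > 5) & (norm.y < 25)
        assert np.all(np.abs(norm.z[interior]) < 0.05)

    def test_below_zero_and_high_outliers_removed(self):
        rng = np.random.default_rng(1)
        n = 2000
        x, y = rng.uniform(0, 20, (2, n))
        z = np.full(n, 10.0)
        ground = np.ones(n, bool)
        extra = PointCloud(
            np.concatenate([x, [5.0, 6.0]]),
            np.concatenate([y, [5.0, 6.0]]),
            np.concatenate([z, [9.7, 200.0]]),  # one below ground, one far above
            np.concatenate([ground, [False, False]]),
        )
        norm = normalize_height(extra)
        assert np.all(norm.z >= 0)
        assert norm.z.max() < 100.0

    def test_no_ground_error_and_knn_clamp_warning(self):
        cloud = _cloud([[0, 0, 1]], np.zeros(1, bool))
        with pytest.raises(ValueError, match="ground"):
            normalize_height(cloud)
        small = _cloud([[0, 0, 0], [1, 1, 5]], np.array([True, False]))
        with pytest.warns(UserWarning, match="clamping"):
            norm = normalize_height(small, knn=10)
        assert len(norm) == 2

    def test_identify_ground_lowest_per_cell(self):
        pts = [[0.5, 0.5, 3.0], [0.6, 0.6, 1.0], [5.0, 5.0, 2.0]]
        g = identify_ground(_cloud(pts), cell=2.0)
        assert list(g) == [False, True, True]


class TestVoxelize:
    def test_many_points_one_cell(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0.0, 0.499, (100, 3))
        grid = voxelize(_cloud(pts))
        assert grid.n_occupied == 1

    def test_half_open_cell_boundary(self):
        grid = voxelize(_cloud([[0, 0, 0.1], [0, 0, 0.6]]))
        assert grid.n_occupied == 2
        edge = voxelize(_cloud([[0, 0, 0.5]]))
        assert edge.indices[0, 2] == 1  # exactly on the edge -> higher cell

    def test_idempotent_and_ground_excluded(self):
        pts = np.array([[0.1, 0.1, 0.1], [0.2, 0.2, 3.0]])
        cloud = PointCloud(pts[:, 0], pts[:, 1], pts[:, 2], np.array([True, False]))
        grid = voxelize(cloud)
        assert grid.n_occupied == 1  # ground return not counted
        again = VoxelGrid(grid.indices, grid.resolution)
        assert np.array_equal(grid.indices, again.indices)

    def test_empty_cloud_empty_grid(self):
        grid = voxelize(_cloud(np.empty((0, 3))))
        assert grid.n_occupied == 0


class TestStrata:
    def test_amounts_at_boundary(self):
        # 10 voxels centered 4.75 m (iz=9), 5 centered 5.25 m (iz=10)
        idx = [(i, 0, 9) for i in range(10)] + [(i, 0, 10) for i in range(5)]
        amounts = strata_amounts(VoxelGrid(np.array(idx)))
        assert amounts["understory"] == 10
        assert amounts["midstory"] == 5

    def test_partition_random_grids(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            idx = rng.integers(0, 40, size=(rng.integers(1, 300), 3))
            grid = VoxelGrid(idx)
            amounts = strata_amounts(grid)
            assert amounts["total"] == sum(amounts[s] for s in
                                           ("understory", "midstory", "subcanopy", "canopy"))
            assert amounts["total"] == grid.n_occupied

    def test_monotone_in_added_voxels(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 30, size=(80, 3))
        more = np.vstack([base, rng.integers(0, 30, size=(40, 3))])
        a0, a1 = strata_amounts(VoxelGrid(base)), strata_amounts(VoxelGrid(more))
        assert all(a1[k] >= a0[k] for k in a0)

    def test_empty_grid_zeros(self):
        amounts = strata_amounts(VoxelGrid(np.empty((0, 3))))
        assert all(v == 0 for v in amounts.values())


class TestPatches:
    @staticmethod
    def _grid_from_raster(raster, iz=0):
        idx = [(r, c, iz) for r, c in zip(*np.nonzero(raster))]
        return VoxelGrid(np.array(idx).reshape(-1, 3))

    def test_rectangle_one_patch(self):
        raster = np.zeros((10, 10), bool)
        raster[2:6, 3:8] = True
        assert patch_count(self._grid_from_raster(raster)) == 1

    def test_two_separated_blocks(self):
        raster = np.zeros((10, 10), bool)
        raster[0:2, 0:2] = True
        raster[5:7, 5:7] = True
        assert patch_count(self._grid_from_raster(raster)) == 2

    def test_checkerboard_is_one_patch(self):
        raster = np.indices((8, 8)).sum(axis=0) % 2 == 0
        assert patch_count(self._grid_from_raster(raster)) == 1

    def test_merging_two_patches_reduces_np_by_one(self):
        raster = np.zeros((5, 9), bool)
        raster[2, 0:3] = True
        raster[2, 6:9] = True
        n_before = patch_count(self._grid_from_raster(raster))
        raster[2, 3:6] = True
        n_after = patch_count(self._grid_from_raster(raster))
        assert n_before == 2 and n_after == 1

    def test_empty_raster_zero_patches(self):
        assert patch_count(VoxelGrid(np.empty((0, 3)))) == 0

    def test_matches_flood_fill_on_random_rasters(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            raster = rng.random((30, 30)) < rng.uniform(0.05, 0.6)
            got = patch_count(self._grid_from_raster(raster))
            assert got == flood_fill_count(raster)

    def test_stratum_restriction(self):
        # one column of understory, separate column of canopy
        grid = VoxelGrid(np.array([[0, 0, 2], [10, 10, 60]]))
        assert patch_count(grid, "understory") == 1
        assert patch_count(grid, "canopy") == 1
        assert patch_count(grid) == 2


class TestVerticalVariance:
    def test_uniform_profile_zero(self):
        # one voxel in every 1 m bin: identical counts -> zero variance
        idx = [(0, 0, 2 * b) for b in range(N_PROFILE_BINS)]
        assert vertical_variance(VoxelGrid(np.array(idx))) == 0.0

    def test_single_bin_closed_form(self):
        n = 17
        idx = [(i, 0, 0) for i in range(n)]
        expected = n**2 * (1 - 1 / N_PROFILE_BINS) / (N_PROFILE_BINS - 1)
        assert vertical_variance(VoxelGrid(np.array(idx))) == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        idx = rng.integers(0, 120, size=(300, 3))
        grid = VoxelGrid(idx)
        h = grid.center_heights()
        counts = np.zeros(N_PROFILE_BINS)
        for hi in h:
            if 0 <= hi < N_PROFILE_BINS:
                counts[int(hi)] += 1
        assert vertical_variance(grid) == pytest.approx(np.var(counts, ddof=1), rel=1e-12)


def test_compute_metrics_consistency():
    rng = np.random.default_rng(7)
    grid = VoxelGrid(rng.integers(0, 50, size=(400, 3)))
    m = compute_metrics(grid)
    assert m.total_a == m.can_a + m.sub_a + m.mid_a + m.und_a
    assert m.vert_v >= 0
    s = m.as_series()
    assert list(s.index) == list(m.NAMES)
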