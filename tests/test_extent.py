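import numpy as np
import pytest
from shapely.geometry import box

from cityframe import extent as ux
from cityframe import synthetic as syn


def brute_force_share(grid, mask):
    """Per-cell windowed built-share by direct recount (truncated at edges)."""
    n, m = grid.shape
    rad = mask.shape[0] // 2
    share = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            r0, r1 = max(0, i - rad), min(n, i + rad + 1)
            c0, c1 = max(0, j - rad), min(m, j + rad + 1)
            sub = mask[r0 - (i - rad): mask.shape[0] - ((i + rad + 1) - r1),
                       c0 - (j - rad): mask.shape[1] - ((j + rad + 1) - c1)]
            share[i, j] = (grid[r0:r1, c0:c1] & sub).sum() / sub.sum()
    return share


def flood_fill_labels(mask, connectivity):
    """Brute-force flood-fill labeling oracle."""
    n, m = mask.shape
    labels = np.zeros((n, m), dtype=int)
    nxt = 0
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    for i in range(n):
        for j in range(m):
            if mask[i, j] and labels[i, j] == 0:
                nxt += 1
                stack = [(i, j)]
                labels[i, j] = nxt
                while stack:
                    a, b = stack.pop()
                    for di, dj in steps:
                        x, y = a + di, b + dj
                        if 0 <= x < n and 0 <= y < m and mask[x, y] and labels[x, y] == 0:
                            labels[x, y] = nxt
                            stack.append((x, y))
    return labels


class TestClassifyPixels:
    def test_fully_built_all_urban(self):
        raster = ux.BuiltUpRaster(grid=np.ones((40, 40), bool), cell_size=50.0)
        classes = ux.classify_pixels(raster)
        assert (classes.classes == ux.URBAN).all()

    def test_isolated_cell_is_rural(self):
        grid = np.zeros((101, 101), bool)
        grid[50, 50] = True
        raster = ux.BuiltUpRaster(grid=grid, cell_size=12.0)
        classes = ux.classify_pixels(raster)
        assert classes.classes[50, 50] == ux.RURAL

    def test_window_smaller_than_cell_rejected(self):
        raster = ux.BuiltUpRaster(grid=np.ones((5, 5), bool), cell_size=12.0)
        with pytest.raises(ux.ExtentError):
            ux.classify_pixels(raster, window_area=100.0)

    def test_threshold_ordering_enforced(self):
        raster = ux.BuiltUpRaster(grid=np.ones((5, 5), bool), cell_size=500.0)
        with pytest.raises(ux.ExtentError):
            ux.classify_pixels(raster, urban_min=0.2, suburban_min=0.5)

    def test_share_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        mask = ux.circular_window(1e6, 12.0)
        for _ in range(3):
            grid = rng.random((50, 50)) < 0.5
            raster = ux.BuiltUpRaster(grid=grid, cell_size=12.0)
            assert (ux.built_share(raster) == brute_force_share(grid, mask)).all()

    def test_enclosed_hole_is_urbanized_open(self):
        grid = np.ones((60, 60), bool)
        grid[28:32, 28:32] = False
        raster = ux.BuiltUpRaster(grid=grid, cell_size=100.0)
        classes = ux.classify_pixels(raster)
        assert (classes.classes[29:31, 29:31] == ux.URBANIZED_OPEN).all()


class TestBuildClusters:
    def make_classes(self, mask, cell_size=100.0):
        classes = np.where(mask, ux.URBAN, ux.OUTSIDE).astype(np.uint8)
        return ux.PixelClassRaster(classes=classes, cell_size=cell_size,
                                   origin=(0.0, mask.shape[0] * cell_size))

    def test_two_separate_blocks(self):
        mask = np.zeros((30, 30), bool)
        mask[2:8, 2:8] = True
        mask[20:26, 20:26] = True
        clusters = ux.build_clusters(self.make_classes(mask))
        assert len(clusters) == 2

    def test_single_block_area(self):
        mask = np.zeros((20, 20), bool)
        mask[3:9, 4:14] = True
        (cluster,) = ux.build_clusters(self.make_classes(mask))
        assert cluster.n_cells == 60
        assert cluster.area == pytest.approx(60 * 100.0**2)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(13)
        for _ in range(25):
            mask = rng.random((50, 50)) < 0.4
            clusters = ux.build_clusters(self.make_classes(mask), connectivity)
            oracle = flood_fill_labels(mask, connectivity)
            assert len(clusters) == oracle.max()
            for c in clusters:
                labels_hit = {oracle[r, cc] for r, cc in c.cells}
                assert len(labels_hit) == 1
                assert c.n_cells == (oracle == labels_hit.pop()).sum()

    def test_ids_ordered_by_area(self):
        mask = np.zeros((30, 30), bool)
        mask[0:3, 0:3] = True     # 9 cells
        mask[10:20, 10:20] = True  # 100 cells
        clusters = ux.build_clusters(self.make_classes(mask))
        assert clusters[0].n_cells == 100 and clusters[0].cluster_id == 1


class TestAgglomerate:
    def blocks(self, *specs, cell_size=100.0, shape=(60, 60)):
        mask = np.zeros(shape, bool)
        for r0, c0, h, w in specs:
            mask[r0:r0 + h, c0:c0 + w] = True
        classes = np.where(mask, ux.URBAN, ux.OUTSIDE).astype(np.uint8)
        raster = ux.PixelClassRaster(classes=classes, cell_size=cell_size,
                                     origin=(0.0, shape[0] * cell_size))
        return ux.build_clusters(raster)

    def test_zero_distance_identity(self):
        clusters = self.blocks((0, 0, 5, 5), (0, 20, 5, 5))
        assert len(ux.agglomerate(clusters, 0)) == 2

    def test_within_distance_merges(self):
        # gap of 3 cells x 100 m = 300 m edge-to-edge
        clusters = self.blocks((10, 10, 5, 5), (10, 18, 5, 5))
        assert len(ux.agglomerate(clusters, 500)) == 1
        assert len(ux.agglomerate(clusters, 200)) == 2

    def test_chain_merges_transitively(self):
        # A-B and B-C gaps 400 m; A-C gap 1300 m > threshold, still one cluster
        clusters = ux.agglomerate(
            self.blocks((10, 0, 5, 5), (10, 9, 5, 5), (10, 18, 5, 5)), 500
        )
        assert len(clusters) == 1

    def test_idempotent(self):
        clusters = self.blocks((10, 10, 5, 5), (10, 18, 5, 5), (40, 40, 6, 6))
        once = ux.agglomerate(clusters, 500)
        twice = ux.agglomerate(once, 500)
        assert [c.n_cells for c in once] == [c.n_cells for c in twice]

    def test_total_cells_conserved(self):
        clusters = self.blocks((10, 10, 5, 5), (10, 18, 5, 5), (40, 40, 6, 6))
        merged = ux.agglomerate(clusters, 500)
        assert sum(c.n_cells for c in merged) == sum(c.n_cells for c in clusters)


class TestSelectUrbext:
    def clusters(self):
        mask = np.zeros((50, 50), bool)
        mask[0:20, 0:25] = True    # 500 cells
        mask[30:42, 30:40] = True  # 120 cells
        classes = np.where(mask, ux.URBAN, ux.OUTSIDE).astype(np.uint8)
        raster = ux.PixelClassRaster(classes=classes, cell_size=100.0, origin=(0.0, 5000.0))
        return ux.build_clusters(raster)

    def test_largest_intersecting_wins(self):
        admin = box(0, 0, 5000, 5000)
        assert ux.select_urbext(self.clusters(), admin).n_cells == 500

    def test_largest_outside_is_skipped(self):
        # admin window only covers the small cluster (rows 30-42 -> y 800-2000)
        admin = box(3000, 500, 4100, 2100)
        assert ux.select_urbext(self.clusters(), admin).n_cells == 120

    def test_no_intersection_errors(self):
        with pytest.raises(ux.ExtentError):
            ux.select_urbext(self.clusters(), box(100000, 100000, 100100, 100100))


class TestSpillover:
    admin = box(0, 0, 100, 100)
    country = box(-1000, -1000, 1000, 1000)

    def case(self, footprint, **kw):
        return ux.classify_spillover(footprint, self.admin, country_boundary=self.country, **kw)

    def test_fully_inside_is_degenerate_ignore(self):
        got = self.case(box(10, 10, 90, 90))
        assert got.case == "extends_ignore_lt20pct"
        assert got.excess_area == pytest.approx(0.0)

    def test_small_excess_ignored_and_clipped(self):
        got = self.case(box(0, 0, 100, 115))  # excess 15% of admin area
        assert got.case == "extends_ignore_lt20pct"
        assert got.fraction_of_l1admin == pytest.approx(0.15)
        assert got.urbext_footprint.equals(self.admin.intersection(box(0, 0, 100, 115)))

    def test_large_excess_flags_added_l2(self):
        got = self.case(box(0, 0, 100, 125))  # excess 25%
        assert got.case == "extends_add_l2"

    def test_neighboring_city_case(self):
        got = self.case(box(0, 0, 100, 125), other_l1admins={"other": box(0, 100, 100, 200)})
        assert got.case == "spills_other_l1"
        assert got.crossing_ids == ["other"]

    def test_border_crossing_creates_excess_extent(self):
        footprint = box(0, 0, 100, 1500)  # reaches past the country boundary
        got = self.case(footprint)
        assert got.case == "spills_other_country"
        assert got.excess_footprint.equals(footprint)
        assert got.urbext_footprint.equals(footprint.intersection(self.admin))


class TestSyntheticRasterRecovery:
    def test_planted_blocks_recovered_as_clusters(self, config):
        raster, truth = syn.generate_builtup_raster(config)
        classes = ux.classify_pixels(raster)
        clusters = ux.build_clusters(classes)
        assert len(clusters) == len(truth.cluster_cells)
        cluster_sets = [set(map(tuple, c.cells)) for c in clusters]
        for block_cells in truth.cluster_cells:
            holders = [s for s in cluster_sets if set(map(tuple, block_cells)) <= s]
            assert len(holders) == 1
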