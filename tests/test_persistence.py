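import numpy as np
import pytest

from leaftopo.images import BinaryMask, GrayImage
from leaftopo.metrics import bottleneck_distance
from leaftopo.oracle import persistence_oracle
from leaftopo.persistence import (FiltrationGrid, PersistenceDiagram,
                                  distance_map, height_filtration,
                                  read_diagram, shape_pds,
                                  sublevel_persistence, texture_venation_pds,
                                  write_diagram)


def disk_mask(radius=10, pad=3):
    n = 2 * (radius + pad) + 1
    yy, xx = np.ogrid[:n, :n]
    c = radius + pad
    return BinaryMask(((yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2), "leaf")


class TestSublevelPersistence:
    def test_constant_grid_single_essential(self):
        pd = sublevel_persistence(FiltrationGrid(np.full((4, 4), 0.7),
                                                 "texture"))
        assert pd.as_multiset() == [(0, 0.7, 0.7, True)]

    def test_strip_merge_pairing(self):
        grid = FiltrationGrid(np.array([[2.0, 1, 3, 0, 4]]), "texture")
        pd = sublevel_persistence(grid)
        assert pd.as_multiset() == [(0, 0.0, 4.0, True), (0, 1.0, 3.0, False)]

    def test_ring_has_one_hole(self):
        vals = np.zeros((3, 3))
        vals[1, 1] = 1.0
        pd = sublevel_persistence(FiltrationGrid(vals, "texture"))
        assert pd.restrict(1).as_multiset() == [(1, 0.0, 1.0, False)]
        assert pd.restrict(0).as_multiset() == [(0, 0.0, 1.0, True)]

    def test_all_background_is_an_error(self):
        with pytest.raises(ValueError):
            FiltrationGrid(np.full((3, 3), np.inf), "texture")

    def test_one_essential_class_per_finite_component(self):
        vals = np.full((9, 9), np.inf)
        vals[1:3, 1:3] = 0.2
        vals[6:8, 5:8] = 0.4
        pd = sublevel_persistence(FiltrationGrid(vals, "texture"))
        ess = pd.restrict(0).essential
        assert ess.sum() == 2


class TestOracleEquivalence:
    def test_oracle_single_cell(self):
        pd = persistence_oracle(FiltrationGrid(np.array([[0.3]]), "texture"))
        assert pd.as_multiset() == [(0, 0.3, 0.3, True)]

    def test_oracle_refuses_large_grids(self):
        with pytest.raises(ValueError):
            persistence_oracle(FiltrationGrid(np.zeros((13, 13)), "texture"))

    def test_multiset_equality_on_random_quantized_grids(self):
        """Union-find + duality path agrees exactly with boundary-matrix
        reduction on 200 random 8x8 grids with 8 intensity levels."""
        rng = np.random.default_rng(2024)
        for trial in range(200):
            vals = rng.integers(0, 8, size=(8, 8)).astype(float)
            if trial % 3 == 0:  # also exercise masked grids
                bg = rng.random((8, 8)) < 0.2
                vals[bg] = np.inf
                if not np.isfinite(vals).any():
                    continue
            grid = FiltrationGrid(vals, "texture")
            assert sublevel_persistence(grid).as_multiset() == \
                persistence_oracle(grid).as_multiset()

    def test_euler_betti_identity(self):
        """Essential degree-0 classes count the 4-connected finite
        components, and essential counts satisfy the Euler characteristic
        of the full complex (V - E + F = b0 - b1)."""
        from skimage.measure import label

        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = rng.integers(0, 5, size=(8, 8)).astype(float)
            vals[rng.random((8, 8)) < 0.25] = np.inf
            if not np.isfinite(vals).any():
                continue
            pd = sublevel_persistence(FiltrationGrid(vals, "texture"))
            ess0 = int(pd.restrict(0).essential.sum())
            ess1 = int(pd.restrict(1).essential.sum())
            fin = np.isfinite(vals)
            ncomp = label(fin, connectivity=1).max()
            assert ess0 == ncomp
            V = fin.sum()
            E = (fin[:, :-1] & fin[:, 1:]).sum() + (fin[:-1] & fin[1:]).sum()
            F = (fin[:-1, :-1] & fin[:-1, 1:] & fin[1:, :-1]
                 & fin[1:, 1:]).sum()
            assert ess0 - ess1 == V - E + F

    def test_stability_under_perturbation(self):
        """An eps-perturbation of the grid moves each degree's diagram by
        at most eps in bottleneck distance (eps = 0.01, 10 random grids)."""
        rng = np.random.default_rng(17)
        eps = 0.01
        for _ in range(10):
            vals = rng.random((10, 10))
            grid = FiltrationGrid(vals, "texture")
            noisy = FiltrationGrid(
                vals + rng.uniform(-eps, eps, vals.shape), "texture")
            pd_a = sublevel_persistence(grid)
            pd_b = sublevel_persistence(noisy)
            for deg in (0, 1):
                d = bottleneck_distance(pd_a.restrict(deg).points,
                                        pd_b.restrict(deg).points)
                assert d <= eps + 1e-12


class TestHeightFiltration:
    def test_theta_zero_minimum_at_leftmost_pixel(self):
        mask = disk_mask(8)
        grid = height_filtration(mask, 0.0)
        finite = np.isfinite(grid.values)
        rmin, cmin = np.unravel_index(np.argmin(np.where(finite, grid.values,
                                                         np.inf)),
                                      grid.values.shape)
        assert cmin == np.nonzero(finite)[1].min()

    def test_antipodal_negation(self):
        mask = disk_mask(7)
        g0 = height_filtration(mask, 0.7)
        g1 = height_filtration(mask, 0.7 + np.pi)
        fin = np.isfinite(g0.values)
        np.testing.assert_allclose(g1.values[fin], -g0.values[fin],
                                   atol=1e-12)

    def test_values_normalised_to_unit_radius(self):
        mask = disk_mask(9)
        g = height_filtration(mask, 1.1)
        fin = np.isfinite(g.values)
        assert np.abs(g.values[fin]).max() <= 1.0 + 1e-12

    def test_disk_single_essential_born_near_minus_one(self):
        mask = disk_mask(10)
        grid = height_filtration(mask, 0.3)
        pd0 = sublevel_persistence(grid).restrict(0)
        ess = pd0.births[pd0.essential]
        assert len(ess) == 1
        assert ess[0] == pytest.approx(-1.0, abs=0.15)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            height_filtration(BinaryMask(np.zeros((8, 8)), "leaf"), 0.0)


class TestShapePds:
    def test_thirty_directions_by_default(self, leaf_scene):
        _, _, leaf, _ = leaf_scene
        pds = shape_pds(leaf)
        assert len(pds) == 30
        assert [p.direction_index for p in pds] == list(range(30))
        assert all(p.kind == "shape" for p in pds)
        assert all((p.degrees == 0).all() for p in pds)

    def test_convex_disk_one_dominant_point_per_direction(self):
        """A convex shape sweeps to a single sublevel component per
        direction; rasterization adds only bars shorter than ~2/r."""
        r = 9
        pds = shape_pds(disk_mask(r), n_dirs=8)
        for p in pds:
            long_bars = (p.lifetimes > 2.0 / r).sum()
            assert long_bars == 1

    def test_rotation_permutes_diagram_list(self):
        """Rotating the mask by 90 degrees cyclically permutes the
        direction list by n_dirs/4; exact for an axis-aligned raster."""
        rng = np.random.default_rng(1)
        mask_vals = disk_mask(9).values.astype(bool)
        mask_vals[4:8, 2:6] = True  # break the symmetry
        mask = BinaryMask(mask_vals, "leaf")
        rotated = BinaryMask(np.rot90(mask_vals), "leaf")
        n = 4
        pds = shape_pds(mask, n_dirs=n)
        pds_rot = shape_pds(rotated, n_dirs=n)
        for i in range(n):
            d = bottleneck_distance(pds[i].points,
                                    pds_rot[(i + n // 4) % n].points)
            assert d <= 1e-9


class TestDistanceMap:
    def _leaf(self, n=5):
        return BinaryMask(np.ones((n, n)), "leaf")

    def test_vein_pixels_at_zero(self):
        vein = np.zeros((5, 5))
        vein[2, 2] = 1
        grid = distance_map(BinaryMask(vein, "venation"), self._leaf())
        assert grid.values[2, 2] == 0.0

    def test_corner_distance_is_euclidean(self):
        vein = np.zeros((5, 5))
        vein[2, 2] = 1
        grid = distance_map(BinaryMask(vein, "venation"), self._leaf())
        assert grid.values[0, 0] == pytest.approx(2 * np.sqrt(2))

    def test_empty_venation_is_an_error(self):
        with pytest.raises(ValueError):
            distance_map(BinaryMask(np.zeros((5, 5)), "venation"),
                         self._leaf())

    def test_areole_loop_gives_one_hole_born_zero(self):
        """A closed square vein loop yields one degree-1 class born at 0
        and dying at the loop's inradius; checked against the oracle."""
        n = 11
        vein = np.zeros((n, n))
        vein[2, 2:9] = 1
        vein[8, 2:9] = 1
        vein[2:9, 2] = 1
        vein[2:9, 8] = 1
        leaf = BinaryMask(np.ones((n, n)), "leaf")
        grid = distance_map(BinaryMask(vein, "venation"), leaf)
        pd1 = sublevel_persistence(grid).restrict(1)
        interior = pd1.lifetimes > 1.0
        assert interior.sum() == 1
        assert pd1.births[interior][0] == 0.0
        assert pd1.deaths[interior][0] == pytest.approx(3.0, abs=0.5)
        oracle_pd1 = persistence_oracle(grid).restrict(1)
        assert pd1.as_multiset() == oracle_pd1.as_multiset()


class TestTextureVenationPds:
    def test_arity_four(self, leaf_scene):
        _, img, leaf, vein = leaf_scene
        out = texture_venation_pds(img, leaf, vein)
        assert len(out) == 4
        kinds = [p.kind for p in out]
        assert kinds == ["texture", "texture", "venation", "venation"]
        degs = [set(p.degrees.tolist()) for p in out]
        assert degs[0] <= {0} and degs[1] <= {1}

    def test_constant_lamina_no_texture_holes(self):
        vals = np.full((33, 33), 0.4)
        leaf = BinaryMask(np.ones((33, 33)), "leaf")
        vein = np.zeros((33, 33))
        vein[16, 16] = 1
        tex0, tex1, _, _ = texture_venation_pds(
            GrayImage(vals), leaf, BinaryMask(vein, "venation"))
        assert len(tex1) == 0

    def test_dark_spots_appear_in_texture_pd0(self):
        """k disjoint dark spots on a bright lamina give k long-lived
        degree-0 classes with lifetime at least the spot contrast."""
        vals = np.full((33, 33), 0.8)
        spots = [(6, 6), (6, 25), (25, 16)]
        for r, c in spots:
            vals[r - 1:r + 2, c - 1:c + 2] = 0.2
        leaf = BinaryMask(np.ones((33, 33)), "leaf")
        vein = np.zeros((33, 33))
        vein[16, 2] = 1
        tex0, _, _, _ = texture_venation_pds(
            GrayImage(vals), leaf, BinaryMask(vein, "venation"))
        long_lived = (tex0.lifetimes >= 0.6 - 1e-9).sum()
        assert long_lived >= len(spots)

    def test_texture_translation_invariance(self, leaf_scene):
        _, img, leaf, vein = leaf_scene
        out = texture_venation_pds(img, leaf, vein)
        shift = 7
        def roll(a):
            return np.roll(np.roll(a, shift, 0), shift, 1)
        img2 = GrayImage(roll(img.values))
        leaf2 = BinaryMask(roll(leaf.values), "leaf")
        vein2 = BinaryMask(roll(vein.values), "venation")
        out2 = texture_venation_pds(img2, leaf2, vein2)
        for a, b in zip(out, out2):
            assert a.as_multiset() == b.as_multiset()


class TestSerialization:
    def test_round_trip(self, tmp_path, leaf_scene):
        _, img, leaf, vein = leaf_scene
        pd = texture_venation_pds(img, leaf, vein)[0]
        path = tmp_path / "pd.tsv"
        write_diagram(pd, path)
        back = read_diagram(path)
        assert back.kind == pd.kind
        assert back.essential_clamped == pd.essential_clamped
        assert back.as_multiset() == pd.as_multiset()

    def test_round_trip_empty(self, tmp_path):
        pd = PersistenceDiagram(np.empty(0), np.empty(0),
                                np.empty(0, np.int8), np.empty(0, bool),
                                "shape", 3)
        path = tmp_path / "empty.tsv"
        write_diagram(pd, path)
        back = read_diagram(path)
        assert len(back) == 0
        assert back.direction_index == 3
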