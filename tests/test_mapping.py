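"""Feature-map geometry: embedding, min-area rectangle, pixel assignment."""

import numpy as np
import pytest

from scpix.containers import ExpressionMatrix
from scpix.mapping import (
    FeatureMap,
    ImageStack,
    build_feature_map,
    cells_to_images,
    embed_features,
    inverse_lookup,
    min_area_rectangle,
)


def bbox_area_at_angle(pts: np.ndarray, angle_deg: float) -> float:
    """Oracle helper: axis-aligned bounding-box area after rotating by -angle."""
    a = np.radians(-angle_deg)
    c, s = np.cos(a), np.sin(a)
    rot = pts @ np.array([[c, -s], [s, c]]).T
    return float(
        (rot[:, 0].max() - rot[:, 0].min()) * (rot[:, 1].max() - rot[:, 1].min())
    )


def exhaustive_min_area(pts: np.ndarray, step_deg: float = 0.01) -> float:
    """Independent oracle: scan rotation angles 0-90 degrees exhaustively."""
    angles = np.arange(0.0, 90.0, step_deg)
    a = np.radians(-angles)
    c, s = np.cos(a), np.sin(a)
    rotx = np.outer(pts[:, 0], c) - np.outer(pts[:, 1], s)
    roty = np.outer(pts[:, 0], s) + np.outer(pts[:, 1], c)
    w = rotx.max(axis=0) - rotx.min(axis=0)
    h = roty.max(axis=0) - roty.min(axis=0)
    return float((w * h).min())


class TestMinAreaRectangle:
    def test_axis_aligned_unit_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        angle, w, h, area = min_area_rectangle(pts)
        assert area == pytest.approx(1.0)
        assert angle % 90 == pytest.approx(0.0, abs=1e-9)

    def test_diamond_rotated_square(self):
        pts = np.array([[0, 0], [1, 1], [2, 0], [1, -1]], float)
        angle, w, h, area = min_area_rectangle(pts)
        assert area == pytest.approx(2.0, rel=1e-9)
        assert angle == pytest.approx(45.0, abs=1e-6)
        # cross-check against the exhaustive scan oracle
        assert area == pytest.approx(exhaustive_min_area(pts), rel=1e-6)

    def test_collinear_points_zero_area(self):
        pts = np.array([[0, 0], [1, 1], [2, 2]], float)
        angle, w, h, area = min_area_rectangle(pts)
        assert area == 0.0 and h == 0.0
        assert w == pytest.approx(2 * np.sqrt(2))

    def test_single_point(self):
        assert min_area_rectangle(np.array([[3.0, 4.0]])) == (0.0, 0.0, 0.0, 0.0)

    def test_matches_exhaustive_oracle_on_random_sets(self, rng):
        for _ in range(100):
            n = rng.integers(3, 31)
            pts = rng.normal(0, 5, (int(n), 2))
            _, _, _, area = min_area_rectangle(pts)
            oracle = exhaustive_min_area(pts)
            # the scan's 0.01-degree grid can slightly overshoot the true optimum
            assert area <= oracle * (1 + 1e-6)
            assert area == pytest.approx(oracle, rel=1e-3)


class TestEmbedFeatures:
    def _scaled(self, values):
        values = np.asarray(values, float)
        n, g = values.shape
        return ExpressionMatrix(
            values,
            np.array([f"c{i}" for i in range(n)], dtype=object),
            np.array([f"g{j}" for j in range(g)], dtype=object),
            layer_tag="scaled",
        )

    def test_identical_genes_embed_nearby(self, rng):
        base = rng.random((30, 10))
        base[:, 1] = base[:, 0]  # genes 0 and 1 identical
        em = self._scaled(base)
        coords = embed_features(em, "tsne", perplexity=3, seed=0)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(coords))
        np.fill_diagonal(d, np.inf)
        # the 0-1 distance is among the very smallest of all pairs
        assert d[0, 1] <= np.quantile(d[np.isfinite(d)], 0.05)

    def test_deterministic_given_seed(self, rng):
        em = self._scaled(rng.random((20, 12)))
        a = embed_features(em, "tsne", perplexity=4, seed=11)
        b = embed_features(em, "tsne", perplexity=4, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_pca_first_axis_follows_norms(self):
        # three mutually orthogonal gene vectors with norms 3, 2, 1: projections
        # onto the leading axis separate genes by their norm
        vals = np.zeros((3, 3))
        vals[0, 0], vals[1, 1], vals[2, 2] = 3.0, 2.0, 1.0
        em = self._scaled(vals)
        coords = embed_features(em, "pca", seed=0)
        spread = np.abs(coords[:, 0] - coords[:, 0].mean())
        assert spread[0] == max(spread)

    def test_perplexity_bound_enforced(self, rng):
        em = self._scaled(rng.random((10, 5)))
        with pytest.raises(ValueError, match="perplexity"):
            embed_features(em, "tsne", perplexity=5, seed=0)

    def test_too_few_genes_rejected(self, rng):
        em = self._scaled(rng.random((10, 2)))
        with pytest.raises(ValueError, match="3 genes"):
            embed_features(em, "tsne", perplexity=1, seed=0)


class TestBuildFeatureMap:
    def test_square_corners_distinct_pixels(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        fmap = build_feature_map(coords, np.array(list("abcd")), pixel_size=2,
                                 perplexity=1, seed=0)
        assert fmap.collision_summary()["pixels_with_collision"] == 0
        pixels = {tuple(p) for p in fmap.pixel_of_gene}
        assert len(pixels) == 4

    def test_degenerate_single_location(self):
        coords = np.zeros((5, 2))
        fmap = build_feature_map(coords, np.array(list("abcde")), pixel_size=4,
                                 perplexity=1, seed=0)
        assert fmap.collision_summary()["max_genes_per_pixel"] == 5

    def test_larger_grid_never_more_collisions(self, rng, recwarn):
        # collision count = genes sharing a pixel with another gene
        # (n_genes - pixels used); finer grids never lose more genes
        for seed in range(10):
            coords = np.random.default_rng(seed).normal(0, 1, (40, 2))
            genes = np.array([f"g{j}" for j in range(40)], dtype=object)
            colliding = [
                40 - build_feature_map(coords, genes, P, 1, 0).collision_summary()[
                    "pixels_used"
                ]
                for P in (4, 8, 16, 32)
            ]
            assert colliding == sorted(colliding, reverse=True)

    def test_rotation_preserves_pairwise_distances(self, rng):
        from scipy.spatial.distance import pdist

        coords = rng.normal(0, 3, (25, 2))
        angle, *_ = min_area_rectangle(coords)
        a = np.radians(-angle)
        c, s = np.cos(a), np.sin(a)
        rot = coords @ np.array([[c, -s], [s, c]]).T
        np.testing.assert_allclose(pdist(rot), pdist(coords), atol=1e-9)

    def test_total_function_and_inverse_partition(self, rng):
        coords = rng.normal(0, 2, (60, 2))
        genes = np.array([f"g{j:02d}" for j in range(60)], dtype=object)
        fmap = build_feature_map(coords, genes, pixel_size=8, perplexity=1, seed=0)
        recovered = []
        for r in range(8):
            for c in range(8):
                recovered.extend(inverse_lookup(fmap, r, c))
        assert sorted(recovered) == sorted(map(str, genes))

    def test_json_round_trip(self, rng, tmp_path):
        coords = rng.normal(0, 2, (10, 2))
        genes = np.array([f"g{j}" for j in range(10)], dtype=object)
        fmap = build_feature_map(coords, genes, pixel_size=4, perplexity=2, seed=3)
        fmap.to_json(tmp_path / "map.json")
        fmap2 = FeatureMap.from_json(tmp_path / "map.json")
        np.testing.assert_array_equal(fmap2.pixel_of_gene, fmap.pixel_of_gene)
        assert fmap2.identifier() == fmap.identifier()

    def test_inverse_lookup_bounds(self, rng):
        coords = rng.normal(0, 2, (5, 2))
        fmap = build_feature_map(coords, np.array(list("abcde")), 4, 1, 0)
        with pytest.raises(ValueError, match="outside"):
            inverse_lookup(fmap, 4, 0)


class TestCellsToImages:
    def _setup(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [1, 1]], float)
        genes = np.array(list("abcde"), dtype=object)
        fmap = build_feature_map(coords, genes, pixel_size=2, perplexity=1, seed=0)
        return fmap, genes

    def _scaled(self, values, genes):
        values = np.asarray(values, float)
        return ExpressionMatrix(
            values,
            np.array([f"c{i}" for i in range(len(values))], dtype=object),
            genes,
            layer_tag="scaled",
        )

    def test_zero_cell_zero_image(self):
        fmap, genes = self._setup()
        stack = cells_to_images(self._scaled(np.zeros((1, 5)), genes), fmap)
        assert (stack.pixels == 0).all()

    def test_single_active_gene(self):
        fmap, genes = self._setup()
        vals = np.zeros((1, 5))
        vals[0, 0] = 1.0  # gene 'a'
        stack = cells_to_images(self._scaled(vals, genes), fmap)
        r, c = fmap.pixel_of_gene[0]
        assert stack.pixels[0, r, c] == 1.0
        assert stack.pixels.sum() == 1.0

    def test_collision_mean_and_max(self):
        fmap, genes = self._setup()
        vals = np.zeros((1, 5))
        vals[0, 3], vals[0, 4] = 0.2, 0.8  # genes d,e share a pixel
        r, c = fmap.pixel_of_gene[3]
        mean_stack = cells_to_images(self._scaled(vals, genes), fmap, "mean")
        assert mean_stack.pixels[0, r, c] == pytest.approx(0.5)
        max_stack = cells_to_images(self._scaled(vals, genes), fmap, "max")
        assert max_stack.pixels[0, r, c] == pytest.approx(0.8)

    def test_mean_aggregation_is_linear_per_pixel(self, rng):
        fmap, genes = self._setup()
        a = self._scaled(rng.random((3, 5)) / 2, genes)
        b = self._scaled(rng.random((3, 5)) / 2, genes)
        sa = cells_to_images(a, fmap, "mean").pixels
        sb = cells_to_images(b, fmap, "mean").pixels
        sab = cells_to_images(a.with_values(a.values + b.values, "scaled"), fmap,
                              "mean").pixels
        np.testing.assert_allclose(sab, sa + sb, atol=1e-12)

    def test_gene_mismatch_rejected(self):
        fmap, genes = self._setup()
        em = self._scaled(np.zeros((1, 5)), np.array(list("abcdX"), dtype=object))
        with pytest.raises(ValueError, match="match"):
            cells_to_images(em, fmap)

    def test_hdf5_round_trip(self, tmp_path, rng):
        fmap, genes = self._setup()
        stack = cells_to_images(self._scaled(rng.random((4, 5)), genes), fmap)
        stack.to_hdf5(tmp_path / "imgs.h5")
        loaded = ImageStack.from_hdf5(tmp_path / "imgs.h5")
        np.testing.assert_allclose(loaded.pixels, stack.pixels, atol=1e-6)
        assert loaded.map_ref == stack.map_ref
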