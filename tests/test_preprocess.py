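"""Normalization, HVG selection, batch correction and scaling contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from scpix.containers import ExpressionMatrix
from scpix.preprocess import (
    GeneScaling,
    align_query_genes,
    apply_scaling,
    correct_batch,
    fit_scaling,
    normalize_counts,
    select_hvg,
)


def _em(values, gene_names=None, layer="counts", batch=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ExpressionMatrix(
        values=values,
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_ids=np.array(gene_names or [f"g{j}" for j in range(g)], dtype=object),
        batch=batch,
        layer_tag=layer,
    )


class TestNormalize:
    def test_depth_proportional_gene_has_zero_residuals(self):
        # counts exactly proportional to depth -> x == mu -> residual 0
        em = _em([[1, 99], [1, 99], [2, 198], [2, 198]])
        out = normalize_counts(em, "pearson_residual")
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)
        assert out.layer_tag == "normalized"

    def test_log_cpm_of_zero_count_is_zero(self):
        em = _em([[0, 10], [0, 1000]])
        out = normalize_counts(em, "log_cpm")
        assert out.values[0, 0] == 0.0 and out.values[1, 0] == 0.0

    def test_zero_depth_cell_rejected(self):
        em = _em([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="QC"):
            normalize_counts(em)

    def test_poisson_depth_noise_standardized(self, rng):
        # 2000 cells, genes that are pure Poisson draws proportional to depth:
        # residual mean ~0 and variance ~1 per gene
        n_cells, n_genes = 2000, 30
        depth_factor = np.exp(rng.normal(0, 0.3, n_cells))
        base = rng.uniform(0.5, 5.0, n_genes)
        lam = depth_factor[:, None] * base[None, :]
        counts = rng.poisson(lam).astype(float)
        keep = counts.sum(axis=1) > 0
        out = normalize_counts(_em(counts[keep]), "pearson_residual")
        assert np.abs(out.values.mean(axis=0)).max() < 0.2
        assert np.abs(out.values.var(axis=0) - 1.0).max() < 0.2

    def test_clipping_bound_respected(self, rng):
        counts = rng.poisson(1.0, (100, 5)).astype(float)
        counts[0, 0] = 10000  # extreme outlier
        counts[counts.sum(axis=1) == 0, 0] += 1
        out = normalize_counts(_em(counts), "pearson_residual", clip=3.0)
        assert np.abs(out.values).max() <= 3.0


class TestSelectHVG:
    def test_planted_high_variance_genes_retained(self, rng):
        n = 200
        base = rng.normal(0, 1, (n, 30))
        markers = rng.normal(0, 10, (n, 5))
        em = _em(np.hstack([base, markers]), layer="normalized")
        marker_names = {f"g{j}" for j in range(30, 35)}
        out = select_hvg(em, 15)
        assert marker_names <= set(map(str, out.gene_ids))

    def test_identity_when_all_requested(self):
        em = _em([[1.0, 2.0], [3.0, 4.0]], layer="normalized")
        out = select_hvg(em, 2)
        assert out is em

    def test_tie_broken_lexicographically(self):
        # gb and ga have identical variance; only one slot after gc
        values = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 5.0]])
        em = _em(values, gene_names=["gb", "ga", "gc"], layer="normalized")
        out = select_hvg(em, 2)
        assert list(map(str, out.gene_ids)) == ["ga", "gc"]

    def test_order_preserved(self, rng):
        em = _em(rng.normal(0, 1, (50, 10)), layer="normalized")
        out = select_hvg(em, 4)
        original_order = [str(g) for g in em.gene_ids if g in set(out.gene_ids)]
        assert list(map(str, out.gene_ids)) == original_order


class TestAlignQueryGenes:
    def test_shuffled_reorder_only(self, rng):
        ref_genes = np.array(["a", "b", "c"], dtype=object)
        q = _em(rng.poisson(3, (4, 3)).astype(float), gene_names=["c", "a", "b"])
        aligned, report = align_query_genes(ref_genes, q)
        assert list(map(str, aligned.gene_ids)) == ["a", "b", "c"]
        np.testing.assert_array_equal(aligned.values[:, 0], q.values[:, 1])
        assert report == {"matched": 3, "missing": 0, "dropped": 0}

    def test_missing_gene_filled_zero(self):
        q = _em([[1.0, 2.0], [3.0, 4.0]], gene_names=["a", "b"])
        aligned, report = align_query_genes(np.array(["a", "b", "c"]), q)
        assert (aligned.values[:, 2] == 0).all()
        assert report["missing"] == 1

    def test_low_overlap_rejected(self):
        q = _em([[1.0, 2.0, 3.0, 4.0, 5.0]], gene_names=list("vwxyz"))
        with pytest.raises(ValueError, match="species|annotation"):
            align_query_genes(np.array(list("abcde")), q)


class TestCorrectBatch:
    def test_constant_shift_removed_exactly(self, rng):
        ref = _em(rng.normal(0, 1, (50, 8)), layer="normalized")
        q = ref.with_values(ref.values + 5.0, "normalized")
        out = correct_batch(ref, q)
        np.testing.assert_allclose(out.values, ref.values, atol=1e-9)

    def test_identity_when_query_equals_reference(self, rng):
        ref = _em(rng.normal(2, 3, (40, 6)), layer="normalized")
        out = correct_batch(ref, ref)
        np.testing.assert_allclose(out.values, ref.values, atol=1e-9)

    def test_moments_matched_after_correction(self, rng):
        ref = _em(rng.normal(0, 1, (100, 10)), layer="normalized")
        q = ref.with_values(ref.values * 2.0 + 1.0, "normalized")
        out = correct_batch(ref, q)
        np.testing.assert_allclose(out.values.mean(axis=0), ref.values.mean(axis=0),
                                   atol=1e-6)
        np.testing.assert_allclose(out.values.std(axis=0), ref.values.std(axis=0),
                                   rtol=1e-6)

    def test_planted_multiplicative_batch_factor_removed(self, standard_world):
        from scpix.ingest import compute_qc, filter_cells
        from scpix.preprocess import normalize_counts

        ref, query, truth = standard_world
        ref, _ = filter_cells(ref, compute_qc(ref, "MT-"))
        query, _ = filter_cells(query, compute_qc(query, "MT-"))
        ref_n = normalize_counts(ref)
        q_n = normalize_counts(query)
        out = correct_batch(ref_n, q_n)
        pooled_sd = np.std(np.vstack([ref_n.values, out.values]), axis=0)
        shift = np.abs(out.values.mean(axis=0) - ref_n.values.mean(axis=0))
        assert (shift <= 0.01 * pooled_sd + 1e-9).all()

    def test_gene_mismatch_rejected(self, rng):
        ref = _em(rng.normal(0, 1, (10, 3)), gene_names=["a", "b", "c"],
                  layer="normalized")
        q = _em(rng.normal(0, 1, (10, 3)), gene_names=["a", "c", "b"],
                layer="normalized")
        with pytest.raises(ValueError, match="gene order"):
            correct_batch(ref, q)

    def test_too_few_query_cells_rejected(self, rng):
        ref = _em(rng.normal(0, 1, (10, 3)), layer="normalized")
        q = _em(rng.normal(0, 1, (1, 3)), layer="normalized")
        with pytest.raises(ValueError, match="2 query cells"):
            correct_batch(ref, q)


class TestScaling:
    def test_fit_and_apply_basic(self):
        ref = _em([[2.0], [4.0], [6.0]], layer="normalized")
        s = fit_scaling(ref)
        assert s.per_gene_min[0] == 2 and s.per_gene_max[0] == 6
        out = apply_scaling(ref, s)
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0])
        assert out.layer_tag == "scaled"

    def test_query_clipped_to_reference_range(self):
        ref = _em([[2.0], [6.0]], layer="normalized")
        s = fit_scaling(ref)
        q = _em([[8.0], [-1.0]], layer="normalized")
        out = apply_scaling(q, s)
        np.testing.assert_allclose(out.values[:, 0], [1.0, 0.0])

    def test_constant_gene_maps_to_zero(self):
        ref = _em([[5.0], [5.0], [5.0]], layer="normalized")
        s = fit_scaling(ref)
        out = apply_scaling(_em([[7.0]], layer="normalized"), s)
        assert out.values[0, 0] == 0.0

    def test_empty_matrix_rejected(self):
        ref = ExpressionMatrix(
            np.zeros((0, 2)), np.array([], dtype=object),
            np.array(["a", "b"], dtype=object), layer_tag="normalized",
        )
        with pytest.raises(ValueError, match="empty"):
            fit_scaling(ref)

    def test_reference_scaling_attains_bounds(self, rng):
        ref = _em(rng.normal(0, 2, (30, 12)), layer="normalized")
        out = apply_scaling(ref, fit_scaling(ref))
        assert np.allclose(out.values.min(axis=0), 0.0)
        assert np.allclose(out.values.max(axis=0), 1.0)

    def test_tsv_round_trip(self, tmp_path, rng):
        ref = _em(rng.normal(0, 1, (10, 4)), layer="normalized")
        s = fit_scaling(ref)
        s.to_tsv(tmp_path / "s.tsv")
        s2 = GeneScaling.from_tsv(tmp_path / "s.tsv")
        np.testing.assert_allclose(s2.per_gene_min, s.per_gene_min)
        np.testing.assert_allclose(s2.per_gene_max, s.per_gene_max)

    @settings(deadline=None, max_examples=25)
    @given(
        ref=arrays(np.float64, (5, 3), elements=st.floats(-50, 50)),
        q=arrays(np.float64, (4, 3), elements=st.floats(-100, 100)),
    )
    def test_output_always_in_unit_interval(self, ref, q):
        s = fit_scaling(_em(ref, layer="normalized"))
        out = apply_scaling(_em(q, layer="normalized"), s)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
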