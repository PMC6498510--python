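"""QC filters, normalisation, variable-gene selection, PCA and the recipes."""

import numpy as np
import pytest

from focusmds import (
    CountMatrix,
    ValidationError,
    correlation_gene_filter,
    normalize_log,
    pca_reduce,
    qc_filter,
    run_recipe,
    top_variable_genes,
    validate_distance_matrix,
)
from focusmds.synthetic import constant_gene, synthetic_counts, zero_total_cell


def make_counts(x):
    x = np.asarray(x, dtype=float)
    return CountMatrix(
        feature_ids=tuple(f"g{i}" for i in range(x.shape[0])),
        sample_ids=tuple(f"c{i}" for i in range(x.shape[1])),
        counts=x,
    )


class TestQCFilter:
    def test_cell_threshold_is_strict(self):
        # one gene; cells with totals 2499 and 2500
        cm = make_counts([[2499.0, 2500.0]])
        out, rep = qc_filter(cm, min_gene_total=0)
        assert out.sample_ids == ("c1",)
        assert rep.cells_kept == 1

    def test_identity_when_everything_passes(self):
        cm = make_counts(np.full((3, 4), 3000.0))
        out, rep = qc_filter(cm)
        assert out.counts.shape == (3, 4)
        assert (rep.cells_kept, rep.genes_kept_by_total) == (4, 3)

    def test_gene_totals_computed_over_surviving_cells(self):
        # the gene passes only if the low-depth cell is counted; it must not be
        x = np.zeros((2, 2))
        x[0] = [30.0, 2500.0]   # gene g0: 30 in a doomed cell, none elsewhere... adjust
        x[0] = [30.0, 0.0]
        x[1] = [100.0, 2600.0]
        cm = make_counts(x)
        out, _ = qc_filter(cm, min_cell_total=2500, min_gene_total=25)
        assert "g0" not in out.feature_ids  # its 30 molecules sat in a removed cell

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_loop_oracle(self, seed):
        cm, _ = synthetic_counts(n_genes=100, n_cells=50, seed=seed)
        out, rep = qc_filter(cm)
        x = cm.counts
        keep_cells = [c for c in range(50) if x[:, c].sum() >= 2500]
        keep_genes = [g for g in range(100) if x[np.ix_([g], keep_cells)].sum() >= 25]
        assert rep.cells_kept == len(keep_cells)
        assert rep.genes_kept_by_total == len(keep_genes)
        assert np.array_equal(out.counts, x[np.ix_(keep_genes, keep_cells)])

    def test_everything_filtered_raises_with_report(self):
        cm = make_counts(np.ones((2, 2)))
        with pytest.raises(ValidationError, match="cells_in"):
            qc_filter(cm)


class TestCorrelationGeneFilter:
    @staticmethod
    def two_block_counts(rng, per_block=5, n_cells=30):
        """Two blocks of genes, perfectly correlated within and independent across."""
        a = rng.uniform(1, 100, n_cells)
        b = rng.uniform(1, 100, n_cells)
        rows = [a * (i + 1) for i in range(per_block)] + [b * (i + 1) for i in range(per_block)]
        return make_counts(np.array(rows))

    def test_block_partner_counting(self):
        # 45 pairs: 25 cross-block (rho ~ 0) below 20 within-block (rho ~ 1);
        # a percentile indexing the 24.5th order statistic interpolates the
        # cutoff strictly between the two classes, so every gene has exactly
        # its 4 perfect within-block partners
        rng = np.random.default_rng(0)
        cm = self.two_block_counts(rng)
        pct = 100 * 24.5 / 44
        with pytest.raises(ValidationError):
            correlation_gene_filter(cm, percentile=pct, min_partners=5)
        out, _ = correlation_gene_filter(cm, percentile=pct, min_partners=4)
        assert out.n_features == 10

    def test_uncorrelated_gene_removed(self):
        rng = np.random.default_rng(1)
        cm = self.two_block_counts(rng)
        lone = rng.uniform(1, 100, cm.n_samples)
        x = np.vstack([cm.counts, lone])
        cm2 = make_counts(x)
        # 55 pairs, 35 in the near-zero class: cutoff between the classes
        out, _ = correlation_gene_filter(cm2, percentile=100 * 34.5 / 54, min_partners=4)
        assert f"g{cm2.n_features - 1}" not in out.feature_ids
        assert out.n_features == 10

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_loop_oracle(self, seed):
        cm, _ = synthetic_counts(n_genes=60, n_cells=40, seed=seed, n_silent_genes=10)
        # drop constant genes exactly as the implementation defines them
        x = cm.counts[cm.counts.std(axis=1) > 0]
        out, rep = correlation_gene_filter(make_counts(x), percentile=90, min_partners=5)
        corr = np.corrcoef(x)
        off = [corr[i, j] for i in range(len(x)) for j in range(i + 1, len(x))]
        cutoff = np.percentile(off, 90)
        keep = [g for g in range(len(x))
                if sum(1 for h in range(len(x)) if h != g and corr[g, h] > cutoff) >= 5]
        assert rep.correlation_threshold_value == pytest.approx(cutoff, rel=1e-12)
        assert rep.genes_kept_by_correlation == len(keep)

    def test_constant_gene_warned_and_dropped(self):
        cm = constant_gene()
        with pytest.warns(UserWarning, match="constant"):
            out, _ = correlation_gene_filter(cm, percentile=50, min_partners=1)
        assert "g0" not in out.feature_ids


class TestNormalizeLog:
    def test_zero_count_maps_to_zero(self):
        cm = make_counts([[0.0, 5.0], [10.0, 5.0]])
        assert normalize_log(cm)[0, 0] == 0.0

    def test_sole_gene_formula(self):
        cm = make_counts([[1000.0]])
        assert normalize_log(cm)[0, 0] == pytest.approx(np.log2(1001.0))

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(20, size=(15, 6)).astype(float) + 1
        out = normalize_log(make_counts(x))
        for g in range(15):
            for c in range(6):
                expect = np.log2(x[g, c] / x[:, c].sum() * 1e3 + 1.0)
                assert out[g, c] == pytest.approx(expect, abs=1e-12)

    def test_monotone_within_cell(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(10, size=(30, 4)).astype(float) + 1
        out = normalize_log(make_counts(x))
        for c in range(4):
            order = np.argsort(x[:, c])
            assert np.all(np.diff(out[order, c]) >= 0)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValidationError, match="zero total"):
            normalize_log(zero_total_cell())


class TestTopVariableGenes:
    def test_planted_high_variance_gene_selected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 10))
        x[13] *= 100.0
        assert 13 in top_variable_genes(x, 5)

    def test_ties_broken_by_row_order(self):
        x = np.zeros((4, 3))  # all variances equal (zero)
        assert list(top_variable_genes(x, 2)) == [0, 1]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(25, 8))
        sel = top_variable_genes(x, 10)
        var = x.var(axis=1)
        expect = sorted(sorted(range(25), key=lambda g: -var[g])[:10])
        assert list(sel) == expect

    def test_too_many_requested_rejected(self):
        with pytest.raises(ValidationError):
            top_variable_genes(np.zeros((3, 3)), 4)


class TestPCAReduce:
    def test_exact_low_rank_reconstruction(self):
        rng = np.random.default_rng(6)
        basis = rng.normal(size=(2, 12))
        weights = rng.normal(size=(30, 2))
        x = (weights @ basis).T  # genes x cells data lying in a 2-plane
        scores = pca_reduce(x, n_components=2)
        # scores capture all variance: distances in PC space match cell distances
        centred = (x - x.mean(axis=1, keepdims=True)).T
        d_full = np.linalg.norm(centred[:, None] - centred[None, :], axis=-1)
        d_pc = np.linalg.norm(scores[:, None] - scores[None, :], axis=-1)
        assert np.allclose(d_full, d_pc, atol=1e-8)

    def test_component_variances_non_increasing(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(40, 15))
        scores = pca_reduce(x, n_components=5)
        v = scores.var(axis=0)
        assert np.all(np.diff(v) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 7))
        scores = pca_reduce(x, n_components=3)
        y = x.T - x.T.mean(axis=0)  # cells x genes, centred
        cov = y.T @ y / (y.shape[0] - 1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][:3]
        expect = y @ vecs[:, order]
        for m in range(3):
            col = expect[:, m]
            assert np.allclose(np.abs(scores[:, m]), np.abs(col), atol=1e-8)

    def test_excess_components_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            scores = pca_reduce(np.random.default_rng(9).normal(size=(4, 6)), n_components=10)
        assert scores.shape == (6, 4)


class TestRunRecipe:
    def test_manhattan_toy(self):
        cm = make_counts([[1.0, 4.0], [2.0, 6.0], [3.0, 3.0]])
        dist, _ = run_recipe(cm, "manhattan_dss")
        assert dist.values[0, 1] == pytest.approx(3 + 4 + 0)

    @pytest.mark.parametrize("recipe", ["correlation", "pca_euclidean"])
    def test_recipe_output_is_valid_distance_matrix(self, recipe):
        cm, _ = synthetic_counts(n_genes=250, n_cells=80, seed=3)
        dist, rep = run_recipe(cm, recipe)
        validate_distance_matrix(dist.values, dist.labels)
        assert rep.cells_kept == dist.n

    @pytest.mark.parametrize("recipe", ["correlation", "pca_euclidean"])
    def test_planted_cell_types_separate(self, recipe):
        cm, groups = synthetic_counts(n_genes=300, n_cells=90, n_types=3, seed=11, dropout=0.1)
        dist, _ = run_recipe(cm, recipe)
        gmap = groups.as_dict()
        within, between = [], []
        for i in range(dist.n):
            for j in range(i + 1, dist.n):
                same = gmap[dist.labels[i]] == gmap[dist.labels[j]]
                (within if same else between).append(dist.values[i, j])
        assert np.mean(within) < np.mean(between)

    def test_unknown_recipe_rejected(self):
        cm = make_counts(np.ones((3, 3)))
        with pytest.raises(ValueError):
            run_recipe(cm, "nope")
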