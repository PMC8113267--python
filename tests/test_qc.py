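import numpy as np
import pytest
import scipy.sparse as sp

from clseq.model import CountMatrix, InputError, make_annotations, make_gene_table
from clseq.qc import (
    QcThresholds,
    basic_filters,
    classify_library_kind,
    estimate_cluster_sizes,
    gate_by_markers,
    gene_set_score,
    regress_out,
    remove_blacklisted_genes,
)


def matrix_with_totals(totals):
    """One-gene-per-library construction hitting exact UMI totals."""
    n = len(totals)
    dense = np.zeros((max(2, n), n), dtype=np.int64)
    for i, t in enumerate(totals):
        dense[i % dense.shape[0], i] = t
    return CountMatrix(sp.csc_matrix(dense), [f"g{i}" for i in range(dense.shape[0])], [f"L{i}" for i in range(n)])


class TestClassifyLibraryKind:
    def test_published_threshold_behavior(self):
        totals = [40_000, 9_499, 20_000, 35_000, 35_001, 9_500, 1]
        m = matrix_with_totals(totals)
        ann = classify_library_kind(m, make_annotations(m))
        assert ann["kind"].tolist() == [
            "cluster",     # 40,000 > 35,000
            "single",      # 9,499 < 9,500
            "ambiguous",   # between thresholds
            "ambiguous",   # exactly 35,000 fails the strict > rule
            "cluster",     # 35,001 passes
            "ambiguous",   # exactly 9,500 fails the strict < rule
            "single",
        ]

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        totals = rng.integers(1, 60_000, size=50).tolist()
        m = matrix_with_totals(totals)
        ann = classify_library_kind(m, make_annotations(m))
        assert set(ann["kind"]) <= {"single", "cluster", "ambiguous"}

    def test_threshold_monotonicity(self, rng):
        totals = rng.integers(1, 60_000, size=80).tolist()
        m = matrix_with_totals(totals)
        loose = classify_library_kind(
            m, make_annotations(m), QcThresholds(cluster_umi_min=30_000)
        )
        strict = classify_library_kind(
            m, make_annotations(m), QcThresholds(cluster_umi_min=45_000)
        )
        assert (loose["kind"] == "cluster").sum() >= (strict["kind"] == "cluster").sum()

    def test_spot_kind_preserved(self):
        m = matrix_with_totals([500, 40_000])
        ann = make_annotations(m, kind="spot")
        out = classify_library_kind(m, ann)
        assert out["kind"].tolist() == ["spot", "spot"]

    def test_threshold_order_enforced(self):
        with pytest.raises(InputError, match="cluster_umi_min"):
            QcThresholds(cluster_umi_min=5_000, single_umi_max=9_500)


class TestBasicFilters:
    def make(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(2.0, size=(300, 5)) + 1  # all genes detected
        dense[:, 1] = 0
        dense[:250, 1] = 0
        dense[:150, 1] = 1  # library 1: 150 detected genes
        dense[0, 2] = 10_000  # library 2: dominated by the mito gene g0
        m = CountMatrix(sp.csc_matrix(dense), [f"g{i}" for i in range(300)], [f"L{i}" for i in range(5)])
        gt = make_gene_table(list(m.gene_ids), flags={"g0": {"mitochondrial"}})
        return m, make_annotations(m), gt

    def test_low_complexity_and_mito_removed(self):
        m, ann, gt = self.make()
        out, out_ann, report = basic_filters(m, ann, gt)
        assert "L1" in report["removed"] and "min_genes" in report["removed"]["L1"]
        assert "L2" in report["removed"] and "max_mito_fraction" in report["removed"]["L2"]
        assert out.n_libraries == 3
        assert report["n_kept"] == 3

    def test_all_pass_is_identity(self):
        m, ann, gt = self.make()
        keep = m.subset_libraries([0, 3, 4])
        from clseq.model import refresh_annotations

        ann2 = refresh_annotations(ann, keep)
        out, _, report = basic_filters(keep, ann2, gt)
        assert out == keep
        assert report["removed"] == {}

    def test_idempotent(self):
        m, ann, gt = self.make()
        once, ann1, _ = basic_filters(m, ann, gt)
        twice, _, report = basic_filters(once, ann1, gt)
        assert twice == once
        assert report["removed"] == {}

    def test_empty_after_qc_error(self):
        m, ann, gt = self.make()
        with pytest.raises(InputError, match="survive"):
            basic_filters(m, ann, gt, QcThresholds(min_genes=10_000))


class TestEstimateClusterSizes:
    def build(self, single_totals, cluster_totals):
        m = matrix_with_totals(single_totals + cluster_totals)
        ann = make_annotations(m)
        ann.loc[: len(single_totals) - 1, "kind"] = "single"
        ann.loc[len(single_totals):, "kind"] = "cluster"
        return m, ann

    def test_exact_ratio(self):
        m, ann = self.build([6000] * 10, [36_000])
        out = estimate_cluster_sizes(m, ann)
        assert out.loc[out["kind"] == "cluster", "est_cells"].tolist() == [6]

    def test_floor_at_two(self):
        m, ann = self.build([6000] * 10, [8_000])
        out = estimate_cluster_sizes(m, ann)
        assert out.loc[out["kind"] == "cluster", "est_cells"].tolist() == [2]

    def test_requires_enough_singles(self):
        m, ann = self.build([6000] * 5, [36_000])
        with pytest.raises(InputError, match="single"):
            estimate_cluster_sizes(m, ann)

    def test_estimates_track_truth_on_simulation(self):
        from clseq.simulate import TissueModel, generate_dataset

        model = TissueModel(n_genes=500, markers_per_state=20)
        counts, ann, truth = generate_dataset(model, 150, 80, seed=3)
        ann = classify_library_kind(counts, ann)
        ann = estimate_cluster_sizes(counts, ann)
        merged = ann.merge(truth[["library_id", "member_states"]], on="library_id")
        clusters = merged[merged["kind"] == "cluster"]
        est = clusters["est_cells"].astype(float)
        true_sizes = clusters["member_states"].map(len)
        assert abs(est.mean() - true_sizes.mean()) < 1.0


class TestBlacklist:
    def test_flagged_genes_dropped(self, tiny_matrix, gene_table):
        out = remove_blacklisted_genes(tiny_matrix, gene_table, {"sex_linked"})
        assert list(out.gene_ids) == ["gA", "gB", "gC"]

    def test_empty_flags_identity(self, tiny_matrix, gene_table):
        assert remove_blacklisted_genes(tiny_matrix, gene_table, set()) == tiny_matrix

    def test_all_flagged_error(self, tiny_matrix):
        gt = make_gene_table(
            list(tiny_matrix.gene_ids),
            flags={g: {"sex_linked"} for g in tiny_matrix.gene_ids},
        )
        with pytest.raises(InputError, match="empty gene axis"):
            remove_blacklisted_genes(tiny_matrix, gt, {"sex_linked"})


class TestGeneSetScore:
    def test_forced_self_control_gives_zero(self, rng):
        x = rng.normal(size=(10, 4))
        genes = [f"g{i}" for i in range(10)]
        score = gene_set_score(
            x, genes, ["g1", "g3"], rng, control_genes=["g1", "g3"]
        )
        np.testing.assert_allclose(score, 0.0, atol=1e-12)

    def test_zero_set_scores_nonpositive(self, rng):
        x = np.ones((6, 3))
        x[0] = 0.0  # gene set expressed nowhere, controls nonzero
        genes = [f"g{i}" for i in range(6)]
        score = gene_set_score(x, genes, ["g0"], rng)
        assert (score <= 0).all()

    def test_hand_oracle_with_forced_controls(self):
        # score = mean(set rows) - mean(control rows), computed by hand
        x = np.array(
            [
                [1.0, 2.0, 3.0],
                [0.0, 1.0, 0.5],
                [2.0, 0.0, 1.0],
                [4.0, 4.0, 4.0],
            ]
        )
        genes = ["a", "b", "c", "d"]
        rng = np.random.default_rng(0)
        score = gene_set_score(
            x, genes, ["a", "c"], rng, control_genes=["b", "d"]
        )
        expected = (x[0] + x[2]) / 2 - (x[1] + x[3]) / 2
        np.testing.assert_allclose(score, expected, atol=1e-12)

    def test_empty_set_rejected(self, rng):
        with pytest.raises(InputError, match="empty"):
            gene_set_score(np.ones((3, 2)), ["a", "b", "c"], [], rng)

    def test_binned_controls_deterministic_by_seed(self):
        x = np.random.default_rng(5).normal(size=(40, 6))
        genes = [f"g{i}" for i in range(40)]
        s1 = gene_set_score(x, genes, ["g3", "g7"], np.random.default_rng(9))
        s2 = gene_set_score(x, genes, ["g3", "g7"], np.random.default_rng(9))
        np.testing.assert_array_equal(s1, s2)


class TestRegressOut:
    def test_zero_covariate_is_identity(self, rng):
        x = rng.normal(size=(5, 8))
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_out(x, np.zeros(8))
        np.testing.assert_allclose(out, x, atol=1e-10)

    def test_gene_equal_to_covariate_becomes_constant(self, rng):
        cov = rng.normal(size=10)
        x = np.vstack([cov, rng.normal(size=10)])
        out = regress_out(x, cov)
        np.testing.assert_allclose(out[0], np.full(10, cov.mean()), atol=1e-10)

    def test_four_point_ols_matches_normal_equations(self):
        # independent solve of (X'X) beta = X'y on centered data
        cov = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 2.5, 4.0, 5.5])
        out = regress_out(y[None, :], cov)
        c = cov - cov.mean()
        beta = (c @ (y - y.mean())) / (c @ c)
        expected = (y - y.mean()) - beta * c + y.mean()
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_residuals_orthogonal_to_covariates(self, rng):
        x = rng.normal(size=(20, 30))
        cov = rng.normal(size=(30, 2))
        out = regress_out(x, cov)
        centered_cov = cov - cov.mean(axis=0)
        resid = out - out.mean(axis=1, keepdims=True)
        inner = resid @ centered_cov
        norms = np.linalg.norm(resid, axis=1, keepdims=True) * np.linalg.norm(
            centered_cov, axis=0
        )
        assert (np.abs(inner) <= 1e-8 * np.maximum(norms, 1e-30)).all()

    def test_collinear_columns_dropped_with_warning(self, rng):
        cov = rng.normal(size=10)
        dup = np.column_stack([cov, 2 * cov])
        x = rng.normal(size=(3, 10))
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_out(x, dup)
        assert out.shape == x.shape


class TestGateByMarkers:
    def setup_method(self):
        self.genes = ["Pax2", "EGFP", "Lhx1", "other"]
        self.libs = ["s1", "s2", "s3"]
        self.x = np.array(
            [
                [0.6, 0.6, 0.4],   # Pax2
                [0.9, 0.8, 0.9],   # EGFP
                [0.6, 0.6, 0.6],   # Lhx1
                [1.0, 1.0, 1.0],
            ]
        )
        self.rules = [("Pax2", 0.5), ("EGFP", 0.8), ("Lhx1", 0.5)]

    def test_published_rule_set(self):
        kept = gate_by_markers(self.x, self.genes, self.libs, self.rules)
        assert kept == ["s1"]  # s2 fails strict EGFP > 0.8, s3 fails Pax2

    def test_boundary_equality_dropped(self):
        kept = gate_by_markers(self.x, self.genes, self.libs, [("EGFP", 0.9)])
        assert kept == []

    def test_empty_rules_vacuous(self):
        assert gate_by_markers(self.x, self.genes, self.libs, []) == self.libs

    def test_unknown_gene_rejected(self):
        with pytest.raises(InputError, match="gate rule"):
            gate_by_markers(self.x, self.genes, self.libs, [("nope", 0.1)])
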