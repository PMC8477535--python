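import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.stats import chi2

from clonoscope.de import (
    CLONE_THRESHOLDS,
    DEThresholds,
    de_genes,
    deg_count_per_cluster,
    gate_subsets,
    log_fold_change,
    log_normalize,
    lr_test,
)
from clonoscope.clonotypes import CloneAssignment
from clonoscope.io import CountMatrix


def matrix_from_dense(arr, genes=None, cells=None):
    arr = np.asarray(arr)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    return CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(arr, dtype=np.int64))


class TestLogNormalize:
    def test_closed_form(self):
        cm = log_normalize(matrix_from_dense([[10], [0]]))
        col = cm.normalized[:, 0].toarray().ravel()
        assert col[0] == pytest.approx(np.log1p(1e4))
        assert col[1] == 0.0

    def test_all_zero_gene_stays_zero(self):
        cm = log_normalize(matrix_from_dense([[0, 0], [1, 2]]))
        assert cm.normalized[0].nnz == 0

    def test_depth_invariance(self):
        base = np.array([[3, 0], [7, 5]])
        cm1 = log_normalize(matrix_from_dense(base))
        cm2 = log_normalize(matrix_from_dense(base * 2))
        np.testing.assert_allclose(
            cm1.normalized[:, 0].toarray(), cm2.normalized[:, 0].toarray()
        )

    def test_zero_cell_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            cm = log_normalize(matrix_from_dense([[1, 0], [2, 0]]))
        assert cm.n_cells == 1

    def test_bad_scale(self):
        with pytest.raises(ValueError):
            log_normalize(matrix_from_dense([[1]]), scale=0)


class TestGateSubsets:
    def make(self, cd4, cd8a, foxp3, clonality="polyclonal"):
        cm = log_normalize(
            matrix_from_dense(
                [[cd4], [cd8a], [foxp3], [1]], genes=["CD4", "CD8A", "FOXP3", "HK"]
            )
        )
        asn = [CloneAssignment("c0", clonality, clone_id=None if clonality == "no_tcr" else "CT1")]
        return gate_subsets(cm, asn)[0].subset

    def test_foxp3_precedence_over_cd4(self):
        assert self.make(cd4=5, cd8a=0, foxp3=3) == "regulatory"

    def test_clone_overrides_markers(self):
        assert self.make(cd4=0, cd8a=9, foxp3=0, clonality="dominant") == "malignant"

    def test_cd8_before_cd4(self):
        assert self.make(cd4=2, cd8a=2, foxp3=0) == "cytotoxic"

    def test_cd4_only_helper(self):
        assert self.make(cd4=2, cd8a=0, foxp3=0) == "helper"

    def test_nothing_is_other(self):
        assert self.make(cd4=0, cd8a=0, foxp3=0) == "other"

    def test_missing_gating_gene_named(self):
        cm = log_normalize(matrix_from_dense([[1]], genes=["CD4"]))
        with pytest.raises(ValueError, match="CD8A"):
            gate_subsets(cm, [])

    def test_simulation_gating_matches_truth(self, small_dataset):
        ds = small_dataset
        truth = dict(zip(ds.ground_truth.cell_id, ds.ground_truth.subset))
        gated = {a.cell_id: a.subset for a in ds.assignments if a.subset is not None}
        hits = sum(truth[c] == s for c, s in gated.items())
        assert hits / len(gated) >= 0.99


class TestLRTest:
    def test_all_zero_expression(self):
        labels = np.array([0, 0, 1, 1])
        assert lr_test(np.zeros(4), labels) == 1.0

    def test_one_class_labels_error(self):
        with pytest.raises(ValueError):
            lr_test(np.arange(4.0), np.ones(4))

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(1)
        n = 150
        labels = np.concatenate([np.ones(n), np.zeros(n)])
        rej = 0
        n_genes = 2000
        for _ in range(n_genes):
            mu = rng.uniform(0.5, 4.0)
            counts = rng.negative_binomial(2.0, 2.0 / (2.0 + mu), size=2 * n)
            rej += lr_test(np.log1p(counts.astype(float)), labels) < 0.05
        assert 0.03 <= rej / n_genes <= 0.07

    def test_oracle_agreement(self):
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 100:
            n = int(rng.integers(40, 120))
            x = rng.normal(size=n)
            eta = rng.normal(0, 0.5) + rng.normal(0, 0.8) * x
            y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
            if y.min() == y.max():
                continue
            p_mine = lr_test(x, y)
            m1 = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            m0 = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
            p_oracle = chi2.sf(2 * (m1.llf - m0.llf), 1)
            assert abs(np.log10(p_mine) - np.log10(p_oracle)) < 1e-6
            checked += 1

    def test_label_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = rng.binomial(1, 0.5, size=60).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert lr_test(x, y) == pytest.approx(lr_test(x, 1 - y), rel=1e-9)


class TestLogFoldChange:
    def test_identical_groups_zero(self):
        cm = log_normalize(matrix_from_dense([[5, 5, 5, 5], [1, 1, 1, 1]]))
        lfc = log_fold_change(cm, np.array([0, 1]), np.array([2, 3]))
        np.testing.assert_allclose(lfc, 0.0, atol=1e-12)

    def test_closed_form(self):
        # group a expm1-mean = e - 1, group b = 0, pseudo 1 -> logfc exactly 1
        cm = matrix_from_dense([[1, 0]])
        cm.normalized = sp.csr_matrix(np.array([[1.0, 0.0]]))
        lfc = log_fold_change(cm, np.array([0]), np.array([1]), pseudo=1.0)
        assert lfc[0] == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        cm = log_normalize(matrix_from_dense(rng.integers(0, 9, size=(20, 30))))
        a, b = np.arange(15), np.arange(15, 30)
        np.testing.assert_allclose(
            log_fold_change(cm, a, b), -log_fold_change(cm, b, a), atol=1e-12
        )

    def test_planted_effect_recovered(self, small_dataset):
        ds = small_dataset
        clone_prog = ds.subset_cells("malignant", lesion_class="plaque")
        clone_flat = ds.subset_cells("malignant", lesion_class="patch")
        lfc = log_fold_change(ds.cm, clone_prog, clone_flat)
        for gene, planted in ds.ground_truth.planted_effects.items():
            got = lfc[ds.cm.gene_idx(gene)]
            assert got == pytest.approx(planted, abs=0.25), gene

    def test_empty_group_error(self):
        cm = log_normalize(matrix_from_dense([[1, 2]]))
        with pytest.raises(ValueError):
            log_fold_change(cm, np.array([]), np.array([0]))


class TestDeGenes:
    def test_null_no_degs(self):
        rng = np.random.default_rng(5)
        counts = rng.negative_binomial(2, 2 / (2 + 1.5), size=(2000, 200))
        cm = log_normalize(matrix_from_dense(counts))
        res = de_genes(cm, np.arange(100), np.arange(100, 200), CLONE_THRESHOLDS)
        assert res == []

    def test_planted_genes_recovered(self, small_dataset):
        ds = small_dataset
        a = ds.subset_cells("malignant", lesion_class="plaque", patient_id="P1")
        b = ds.subset_cells("malignant", lesion_class="patch", patient_id="P1")
        res = de_genes(ds.cm, a, b, CLONE_THRESHOLDS)
        planted = set(ds.ground_truth.planted_effects)
        got = {r.gene for r in res}
        assert planted <= got
        for r in res:
            if r.gene in planted:
                assert r.direction == "down"

    def test_infinite_threshold_empty(self, small_dataset):
        ds = small_dataset
        a = ds.subset_cells("malignant", lesion_class="plaque", patient_id="P1")
        b = ds.subset_cells("malignant", lesion_class="patch", patient_id="P1")
        thr = DEThresholds(min_abs_logfc=np.inf)
        assert de_genes(ds.cm, a, b, thr) == []

    def test_groups_must_be_disjoint(self, small_dataset):
        ds = small_dataset
        with pytest.raises(ValueError):
            de_genes(ds.cm, np.array([0, 1]), np.array([1, 2]))

    def test_bonferroni_monotonicity(self, small_dataset):
        ds = small_dataset
        a = ds.subset_cells("malignant", lesion_class="plaque", patient_id="P1")
        b = ds.subset_cells("malignant", lesion_class="patch", patient_id="P1")
        loose = de_genes(ds.cm, a, b, DEThresholds(min_pct=0.05))
        tight = de_genes(ds.cm, a, b, DEThresholds(min_pct=0.5))
        loose_adj = {r.gene: r.p_adj for r in loose}
        for r in tight:
            assert r.p_adj >= r.p
            if r.gene in loose_adj:
                # fewer genes tested -> adjusted p cannot increase
                assert r.p_adj <= loose_adj[r.gene] + 1e-12

    def test_subsampling_stability(self, small_dataset):
        ds = small_dataset
        rng = np.random.default_rng(6)
        a = ds.subset_cells("malignant", lesion_class="plaque")
        b = ds.subset_cells("malignant", lesion_class="patch")
        a = rng.choice(a, size=len(a) // 2, replace=False)
        b = rng.choice(b, size=len(b) // 2, replace=False)
        res = de_genes(ds.cm, a, b, CLONE_THRESHOLDS)
        assert set(ds.ground_truth.planted_effects) <= {r.gene for r in res}


class TestDegCountPerCluster:
    def make_two_cluster_data(self, effect):
        rng = np.random.default_rng(7)
        n = 120  # cells per cluster per condition
        mu = rng.uniform(0.5, 4.0, size=300)
        blocks, meta_rows = [], []
        for cluster in ("c1", "c2"):
            for cond in ("patch", "tumor"):
                m = mu.copy()
                if cluster == "c1" and cond == "tumor":
                    m[:10] = m[:10] * np.exp(effect)
                blocks.append(rng.negative_binomial(2, 2 / (2 + m[:, None]), size=(300, n)))
                for i in range(n):
                    meta_rows.append(
                        {
                            "cell_id": f"{cluster}_{cond}_{i}",
                            "sample_id": f"s_{cond}",
                            "patient_id": "P1",
                            "lesion_class": cond,
                            "cluster": cluster,
                        }
                    )
        counts = np.concatenate(blocks, axis=1)
        cells = [r["cell_id"] for r in meta_rows]
        cm = log_normalize(matrix_from_dense(counts, cells=cells))
        return cm, pd.DataFrame(meta_rows)

    def test_effects_only_in_cluster_one(self):
        cm, meta = self.make_two_cluster_data(effect=-1.0)
        counts = deg_count_per_cluster(cm, meta, "tumor", "patch")
        assert counts["c1"] > 0
        assert counts["c2"] == 0

    def test_null_gives_zero(self):
        cm, meta = self.make_two_cluster_data(effect=0.0)
        counts = deg_count_per_cluster(cm, meta, "tumor", "patch")
        assert counts == {"c1": 0, "c2": 0}

    def test_counts_bounded(self, small_dataset):
        ds = small_dataset
        counts = deg_count_per_cluster(ds.cm, ds.metadata, {"plaque"}, {"patch"})
        for v in counts.values():
            assert 0 <= v <= ds.cm.n_genes

    def test_cluster_missing_condition_absent(self):
        cm, meta = self.make_two_cluster_data(effect=0.0)
        meta = meta[~((meta["cluster"] == "c2") & (meta["lesion_class"] == "tumor"))]
        counts = deg_count_per_cluster(cm, meta, "tumor", "patch")
        assert "c2" not in counts
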