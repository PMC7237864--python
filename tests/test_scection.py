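import numpy as np
import pytest
import scipy.stats

import embryostrat as es
from embryostrat.matrix import CellAnnotation, ExpressionMatrix, GeneSet
from embryostrat.scection import (
    ConsensusMatrix,
    Scection,
    _within_cluster_consensus,
    consensus_nmf,
    filter_split_genes,
    match_cell_types_across_embryos,
    nmf_consensus_split,
    scection,
    validate_classifier_genes,
)


def _rpm(values, cells=None, genes=None):
    values = np.asarray(values, dtype=float)
    cells = cells or [f"c{i:02d}" for i in range(values.shape[0])]
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, cells, genes, "rpm")


def _blocks(n_a=6, n_b=6, n_genes=20, delta=6.0, noise=0.3, seed=0):
    """Two cell blocks with block-specific genes, log-normal noise."""
    rng = np.random.default_rng(seed)
    base = np.zeros((n_a + n_b, n_genes))
    base[:n_a, : n_genes // 2] = delta
    base[n_a:, n_genes // 2 :] = delta
    return _rpm(2 ** (base + rng.normal(0, noise, base.shape)))


class TestFilterSplitGenes:
    def test_sixteen_fold_boundary_included(self):
        m = _rpm([[64.0, 8.0], [4.0, 1.0]], genes=["at16", "at8"])
        genes = filter_split_genes(m, m.cell_ids)
        assert "at16" in genes  # 64/4 = 16-fold
        assert "at8" not in genes  # 8/1 = 8-fold

    def test_constant_subset_empty(self):
        m = _rpm(np.full((4, 5), 100.0))
        assert len(filter_split_genes(m, m.cell_ids)) == 0

    def test_max_expression_gate(self):
        # 16-fold range but everything at/below 4 RPM -> excluded
        m = _rpm([[4.0], [0.25]])
        assert len(filter_split_genes(m, m.cell_ids)) == 0


class TestConsensus:
    def test_matrix_invariants(self):
        m = _blocks()
        genes = filter_split_genes(m, m.cell_ids)
        cm, labels, score = nmf_consensus_split(m, m.cell_ids, genes, runs=20, seed=0)
        v = cm.values
        np.testing.assert_allclose(v, v.T)
        np.testing.assert_allclose(np.diag(v), 1.0)
        assert v.min() >= 0 and v.max() <= 1

    def test_separable_blocks_perfect(self):
        m = _blocks()
        genes = filter_split_genes(m, m.cell_ids)
        _, labels, score = nmf_consensus_split(m, m.cell_ids, genes, runs=30, seed=1)
        lab = np.array([labels[c] for c in m.cell_ids])
        assert score == pytest.approx(1.0, abs=1e-12)
        assert len(set(lab[:6])) == 1 and len(set(lab[6:])) == 1 and lab[0] != lab[-1]

    def test_score_invariant_to_cell_order(self):
        m = _blocks(seed=3)
        genes = filter_split_genes(m, m.cell_ids)
        _, _, s1 = nmf_consensus_split(m, m.cell_ids, genes, runs=20, seed=5)
        perm = list(np.random.default_rng(0).permutation(m.cell_ids))
        _, _, s2 = nmf_consensus_split(m, perm, genes, runs=20, seed=5)
        assert s1 == pytest.approx(s2, abs=0.05)

    def test_noise_consensus_low_in_median(self):
        scores = []
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            m = _rpm(2 ** rng.normal(3.0, 0.7, size=(12, 100)))
            genes = GeneSet(list(m.gene_ids), "all")
            _, _, score = nmf_consensus_split(m, m.cell_ids, genes, runs=30, seed=s)
            scores.append(score)
        assert np.median(scores) < 0.75

    def test_consensus_degrades_with_signal(self):
        medians = []
        for delta in (6.0, 1.0, 0.0):
            scores = []
            for s in range(5):
                m = _blocks(delta=delta, noise=1.0, seed=100 + s)
                genes = GeneSet(list(m.gene_ids), "all")
                _, _, score = nmf_consensus_split(m, m.cell_ids, genes, runs=20, seed=s)
                scores.append(score)
            medians.append(np.median(scores))
        assert medians[0] > medians[1] >= medians[2] - 0.05

    def test_degenerate_runs_reinitialized(self):
        # tiny matrix where some inits collapse; must still complete the runs
        m = _blocks(n_a=2, n_b=2, n_genes=4, delta=4.0, noise=0.1)
        cm, _ = consensus_nmf(np.maximum(m.values, 0), m.cell_ids, k=2, runs=10, seed=0)
        assert cm.run_count == 10

    def test_asymmetric_consensus_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ConsensusMatrix(np.array([[1.0, 0.2], [0.4, 1.0]]), ["a", "b"], 10)


class TestScectionRecursion:
    def test_identical_cells_single_leaf(self):
        rng = np.random.default_rng(0)
        m = _rpm(2 ** rng.normal(3, 0.3, size=(8, 40)))
        part = scection(m, m.cell_ids, seed=0)
        assert part.n_types() == 1

    def test_partition_property(self, default_series, default_rpm):
        rpm, _ = default_rpm
        cells = es.matrix.group_by_embryo(default_series.annotations)["E16.0"]
        part = Scection(rpm, cells).fit(seed=0).partition
        assert sorted(part.assignment) == sorted(cells)
        leaves = [part.cells_of(lab) for lab in part.labels]
        flat = [c for leaf in leaves for c in leaf]
        assert sorted(flat) == sorted(cells)  # disjoint cover

    def test_deterministic_given_seed(self, default_series, default_rpm):
        rpm, _ = default_rpm
        cells = es.matrix.group_by_embryo(default_series.annotations)["E16.1"]
        p1 = Scection(rpm, cells).fit(seed=7).partition
        p2 = Scection(rpm, cells).fit(seed=7).partition
        assert p1.assignment == p2.assignment

    def test_planted_16_cell_structure_recovered(self, default_series, default_rpm):
        rpm, _ = default_rpm
        for e, cells in es.matrix.group_by_embryo(default_series.annotations).items():
            res = Scection(rpm, cells).fit(seed=0)
            ari = es.adjusted_rand_index(res.partition.assignment, default_series.truth.partition(e))
            assert ari == pytest.approx(1.0)
            sizes = sorted(res.type_sizes().values())
            assert sizes == [2, 2, 4, 4, 4]

    def test_summary_mentions_structure(self, default_series, default_rpm):
        rpm, _ = default_rpm
        cells = es.matrix.group_by_embryo(default_series.annotations)["E16.0"]
        text = Scection(rpm, cells).fit(seed=0).summary()
        assert "types: 5" in text and "consensus" in text


class TestCrossEmbryoMatching:
    def test_identical_planted_types_one_to_one(self, default_series, default_rpm):
        rpm, _ = default_rpm
        parts = {
            e: Scection(rpm, cells).fit(seed=0).partition
            for e, cells in es.matrix.group_by_embryo(default_series.annotations).items()
        }
        mapping, table = match_cell_types_across_embryos(parts, rpm, default_series.annotations)
        assert len(table.index) == 5
        assert sorted(table.sum(axis=0)) == [16, 16, 16, 16]
        assert sorted(table["E16.0"]) == [2, 2, 4, 4, 4]

    def test_spurious_singleton_split_merged(self, default_series, default_rpm):
        rpm, _ = default_rpm
        parts = {
            e: Scection(rpm, cells).fit(seed=0).partition
            for e, cells in es.matrix.group_by_embryo(default_series.annotations).items()
        }
        # manually over-split one leaf of one embryo
        p = parts["E16.0"]
        lab = [l for l in p.labels if len(p.cells_of(l)) == 4][0]
        cells4 = p.cells_of(lab)
        for i, c in enumerate(cells4):
            p.assignment[c] = f"{lab}/0" if i % 2 == 0 else f"{lab}/1"
        mapping, table = match_cell_types_across_embryos(parts, rpm, default_series.annotations)
        assert len(table.index) == 5  # merged back to the planted count
        assert table.to_numpy().sum() == 64

    def test_single_embryo_identity_with_warning(self, default_series, default_rpm):
        rpm, _ = default_rpm
        e = "E16.0"
        cells = es.matrix.group_by_embryo(default_series.annotations)[e]
        part = Scection(rpm, cells).fit(seed=0).partition
        ann = [a for a in default_series.annotations if a.embryo_id == e]
        with pytest.warns(UserWarning, match="single embryo"):
            mapping, table = match_cell_types_across_embryos({e: part}, rpm, ann)
        assert len(table.index) == part.n_types()


class TestClassifierValidation:
    def _matrix_with_reference(self, n=16, seed=0):
        rng = np.random.default_rng(seed)
        ref = set(f"c{i:02d}" for i in range(n // 2))
        cells = [f"c{i:02d}" for i in range(n)]
        aligned = np.array([300.0 if c in ref else 2.0 for c in cells])
        noise = 2 ** rng.normal(4, 0.2, n) * rng.permutation([20.0] * (n // 2) + [1.0] * (n // 2)) / 10
        m = ExpressionMatrix(np.column_stack([aligned, noise]), cells, ["aligned", "random"], "rpm")
        return m, ref

    def test_aligned_candidate_significant_random_not(self):
        m, ref = self._matrix_with_reference()
        survivors, df = validate_classifier_genes(GeneSet(["aligned", "random"], "t"), m, ref)
        assert "aligned" in survivors
        row = df.set_index("gene_id").loc["random"]
        assert row["p"] > 0.01 or row["p_adj"] > 0.05

    def test_bh_with_single_test_equals_raw_p(self):
        m, ref = self._matrix_with_reference()
        _, df = validate_classifier_genes(GeneSet(["aligned"], "t"), m, ref)
        row = df.iloc[0]
        assert row["p_adj"] == pytest.approx(row["p"])

    def test_contingency_matches_direct_chi2(self):
        m, ref = self._matrix_with_reference()
        _, df = validate_classifier_genes(GeneSet(["aligned"], "t"), m, ref)
        table = np.array([[8, 0], [0, 8]])
        stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
        row = df.set_index("gene_id").loc["aligned"]
        assert row["chi2"] == pytest.approx(stat)
        assert row["p"] == pytest.approx(p)
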