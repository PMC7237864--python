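import numpy as np
import pandas as pd
import pytest

import embryostrat as es
from embryostrat.lineage import (
    LineageTree,
    StageProfiles,
    build_lineage_tree,
    bulk_gene_filter,
    embed_on_lineage,
    match_mother_daughter,
    neighbor_ordering,
    reconstruct_lineage_tree,
    stage_profiles,
)
from embryostrat.synthgen import pseudo_bulk


@pytest.fixture(scope="module")
def series_64():
    cfg = es.SeriesConfig(stages=(4, 16, 32, 64), embryos_per_stage=3)
    data = es.generate_series(cfg, seed=1)
    rpm, _ = es.normalize_pipeline(data.expression)
    assignments = dict(zip(data.truth.cells.cell_id, data.truth.cells.type))
    return data, rpm, assignments


class TestStageProfiles:
    def test_per_gene_standardization(self, series_64):
        data, rpm, assignments = series_64
        sp = stage_profiles(rpm, assignments, data.annotations, 16, genes=None)
        vals = sp.profiles.to_numpy()
        np.testing.assert_allclose(vals.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(vals.var(axis=0, ddof=1), 1, atol=1e-10)

    def test_no_bulk_warns(self, series_64):
        data, rpm, assignments = series_64
        with pytest.warns(UserWarning, match="bulk"):
            stage_profiles(rpm, assignments, data.annotations, 16, genes=None)

    def test_bulk_filter_selects_regulated_genes(self, series_64):
        data, rpm, assignments = series_64
        bulk = pseudo_bulk(data)
        genes = bulk_gene_filter(bulk, mother_stage=16, base_stage=4)
        kinds = data.truth.genes.set_index("gene_id").loc[list(genes), "kind"]
        # developmental classes dominate; constitutive/background excluded
        assert (kinds.isin(["marker", "pole", "maternal"])).mean() > 0.9


class TestMatching:
    def _profiles(self, stage, labels, counts, vectors):
        df = pd.DataFrame(np.asarray(vectors, dtype=float), index=labels,
                          columns=[f"g{i}" for i in range(np.asarray(vectors).shape[1])])
        return StageProfiles(stage, df, dict(zip(labels, counts)))

    def test_single_mother_takes_both_daughters(self):
        mothers = self._profiles(16, ["M1"], [2], [[0.0, 0.0]])
        daughters = self._profiles(32, ["D1", "D2"], [2, 2], [[0.1, 0.0], [0.0, 0.1]])
        assert sorted(match_mother_daughter(mothers, daughters)) == [("M1", "D1"), ("M1", "D2")]

    def test_planted_parentage_recovered_with_noise(self):
        rng = np.random.default_rng(0)
        base = {"M1": np.array([3.0, 0.0, 0.0]), "M2": np.array([0.0, 3.0, 0.0])}
        mothers = self._profiles(16, ["M1", "M2"], [2, 2], [base["M1"], base["M2"]])
        dvecs = [base["M1"] + rng.normal(0, 0.2, 3) for _ in range(2)] + [
            base["M2"] + rng.normal(0, 0.2, 3) for _ in range(2)
        ]
        daughters = self._profiles(32, ["D1a", "D1b", "D2a", "D2b"], [2, 2, 2, 2], dvecs)
        edges = set(match_mother_daughter(mothers, daughters))
        assert edges == {("M1", "D1a"), ("M1", "D1b"), ("M2", "D2a"), ("M2", "D2b")}

    def test_equidistant_tie_logged_and_deterministic(self):
        mothers = self._profiles(16, ["M1", "M2"], [1, 1], [[1.0, 0.0], [-1.0, 0.0]])
        daughters = self._profiles(32, ["Da", "Db"], [2, 2], [[0.0, 1.0], [0.0, -1.0]])
        with pytest.warns(UserWarning, match="tie"):
            edges = match_mother_daughter(mothers, daughters)
        with pytest.warns(UserWarning, match="tie"):
            again = match_mother_daughter(mothers, daughters)
        assert edges == again  # lexicographic tie-break is deterministic

    def test_budget_mismatch_rejected(self):
        mothers = self._profiles(16, ["M1"], [2], [[0.0]])
        daughters = self._profiles(32, ["D1"], [2], [[0.0]])
        with pytest.raises(ValueError, match="twice"):
            match_mother_daughter(mothers, daughters)


class TestTree:
    def test_planted_tree_recovered(self, series_64):
        data, rpm, assignments = series_64
        tree = reconstruct_lineage_tree(
            rpm, assignments, data.annotations, (16, 32, 64), bulk=pseudo_bulk(data)
        )
        assert es.edge_set_f1(tree.edge_labels(), data.truth.lineage_edges()) == 1.0

    def test_doubling_validated_at_every_node(self, series_64):
        data, rpm, assignments = series_64
        tree = reconstruct_lineage_tree(
            rpm, assignments, data.annotations, (16, 32, 64), bulk=pseudo_bulk(data)
        )
        tree.validate()  # raises on violation
        for node in tree.graph.nodes:
            kids = list(tree.graph.successors(node))
            if kids:
                assert sum(tree.graph.nodes[k]["n_cells"] for k in kids) == 2 * tree.graph.nodes[node]["n_cells"]

    def test_germ_lineage_passes_through_all_stages(self, series_64):
        # the transcriptionally silent germ type must still receive a budget
        data, rpm, assignments = series_64
        tree = reconstruct_lineage_tree(
            rpm, assignments, data.annotations, (16, 32, 64), bulk=pseudo_bulk(data)
        )
        labels = tree.edge_labels()
        assert ("B2.16", "germ32") in labels and ("germ32", "germ64") in labels

    def test_doubling_violation_raises(self):
        tree = LineageTree()
        tree.add_node(16, "M", 2)
        tree.add_node(32, "D", 2)
        tree.add_edge((16, "M"), (32, "D"))
        with pytest.raises(ValueError, match="doubling"):
            tree.validate()

    def test_newick_round_trips_through_dendropy(self, series_64):
        import dendropy

        data, rpm, assignments = series_64
        tree = reconstruct_lineage_tree(
            rpm, assignments, data.annotations, (16, 32, 64), bulk=pseudo_bulk(data)
        )
        text = tree.to_newick()
        parsed = dendropy.Tree.get(data=text, schema="newick")
        leaf_labels = {l.taxon.label for l in parsed.leaf_node_iter()}
        expected = {
            f"{s}:{lab}:{tree.graph.nodes[(s, lab)]['n_cells']}"
            for (s, lab) in tree.graph.nodes
            if tree.graph.out_degree((s, lab)) == 0
        }
        assert leaf_labels == expected


class TestEmbedding:
    def test_mother_at_zero_daughter_at_norm(self):
        mother = np.array([0.0, 0.0])
        daughter = np.array([3.0, 4.0])
        assert embed_on_lineage(mother, mother, daughter) == pytest.approx(0.0)
        assert embed_on_lineage(daughter, mother, daughter) == pytest.approx(5.0)
        assert embed_on_lineage(daughter, mother, daughter, normalized=True) == pytest.approx(1.0)

    def test_midpoint_half_in_normalized_units(self):
        mother = np.zeros(3)
        daughter = np.array([2.0, 2.0, 1.0])
        mid = daughter / 2
        assert embed_on_lineage(mid, mother, daughter, normalized=True) == pytest.approx(0.5)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            embed_on_lineage(np.ones(2), np.ones(2), np.ones(2))

    def test_neighbor_ordering_follows_a_line(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        order = neighbor_ordering(X, ["w", "x", "y", "z"])
        ranks = [order[c] for c in ["w", "x", "y", "z"]]
        assert ranks == sorted(ranks) or ranks == sorted(ranks, reverse=True)
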