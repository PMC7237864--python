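import numpy as np
import pytest
import scipy.stats

import embryostrat as es
from embryostrat.matrix import CellAnnotation, ExpressionMatrix
from embryostrat.noise_time import (
    TemporalExpressionModel,
    _permutation_pvalue,
    coordination_analysis,
    cv_within_vs_across,
    find_marker_genes,
    group_compare,
)
from embryostrat.synthgen import simulate_temporal


class TestCV:
    def test_constant_gene_zero_cv(self):
        ann = [CellAnnotation(f"e{e}c{i}", f"e{e}", 4) for e in range(2) for i in range(4)]
        vals = np.column_stack([np.full(8, 100.0), np.random.default_rng(0).uniform(20, 200, 8)])
        m = ExpressionMatrix(vals, [a.cell_id for a in ann], ["flat", "noisy"], "rpm")
        df = cv_within_vs_across(m, ann, seed=0)
        assert (df[df.gene_id == "flat"].cv_within == 0).all()

    def test_exchangeable_embryos_ratio_near_one(self):
        cfg = es.SeriesConfig(embryo_effect_sd_log2=0.0, timing_window=0.0)
        data = es.generate_series(cfg, seed=1)
        rpm, _ = es.normalize_pipeline(data.expression)
        df = cv_within_vs_across(rpm, data.annotations, seed=0)
        assert abs(df.ratio.median() - 1.0) < 0.05

    def test_embryo_offsets_push_ratio_below_one(self, default_series, default_rpm):
        rpm, _ = default_rpm
        df = cv_within_vs_across(rpm, default_series.annotations, seed=0)
        assert df.ratio.median() < 0.98

    def test_invariant_to_cell_order(self, default_series, default_rpm):
        rpm, _ = default_rpm
        perm = list(np.random.default_rng(0).permutation(rpm.cell_ids))
        shuffled = rpm.subset(cells=perm)
        ann_map = {a.cell_id: a for a in default_series.annotations}
        df1 = cv_within_vs_across(rpm, default_series.annotations, seed=0)
        df2 = cv_within_vs_across(shuffled, [ann_map[c] for c in perm], seed=0)
        k1 = df1.set_index(["embryo_id", "gene_id"]).cv_within.sort_index()
        k2 = df2.set_index(["embryo_id", "gene_id"]).cv_within.sort_index()
        np.testing.assert_allclose(k1.to_numpy(), k2.to_numpy())


class TestMarkers:
    def test_planted_marker_fractions(self, default_series, default_rpm):
        rpm, _ = default_rpm
        truth = default_series.truth
        assignments = dict(zip(truth.cells.cell_id, truth.cells.type))
        report = find_marker_genes(rpm, assignments)
        planted = truth.genes[truth.genes.kind == "marker"]
        planted16 = planted[planted.node.isin(["a16", "A16", "b16", "B1.16"])].gene_id
        found = report.table.set_index("gene_id")
        hits = [g for g in planted16 if g in found.index]
        assert len(hits) >= 0.9 * len(planted16)
        sub = found.loc[hits]
        assert (sub.frac_pos > 0.9).mean() > 0.9
        assert (sub.frac_neg < 0.35).mean() > 0.9  # spurious rate ~0.1 plus noise

    def test_level_gap_recovered_within_twofold(self):
        # plant a 50-fold gap between expressing positives and negatives
        cfg = es.SeriesConfig(spurious_level_ratio=0.02)
        data = es.generate_series(cfg, seed=2)
        rpm, _ = es.normalize_pipeline(data.expression)
        truth = data.truth
        assignments = dict(zip(truth.cells.cell_id, truth.cells.type))
        report = find_marker_genes(rpm, assignments)
        tab = report.table.dropna(subset=["median_pos", "median_neg"])
        tab = tab[tab.gene_id.str.startswith("mk_")]
        gaps = tab.median_pos / tab.median_neg
        assert 25 <= np.median(gaps) <= 100

    def test_uniform_gene_not_marker(self):
        ann = {f"c{i}": "T0" if i < 3 else "T1" for i in range(6)}
        vals = np.column_stack([np.full(6, 50.0), [100, 90, 110, 1, 2, 1]])
        m = ExpressionMatrix(vals, [f"c{i}" for i in range(6)], ["uniform", "marker"], "rpm")
        report = find_marker_genes(m, ann)
        assert report.marker_genes == ["marker"]


@pytest.fixture(scope="module")
def timed_series():
    cfg = es.SeriesConfig(stages=(16, 32), embryos_per_stage=12, timing_window=0.5)
    data = es.generate_series(cfg, seed=0)
    rpm, _ = es.normalize_pipeline(data.expression)
    return data, rpm


class TestCoordination:
    def _mothers_daughters(self, data):
        cells = data.truth.cells
        mo = {
            "A1.32": cells[(cells.stage == 16) & (cells.type == "A16")].cell_id.tolist(),
            "b32": cells[(cells.stage == 16) & (cells.type == "b16")].cell_id.tolist(),
        }
        da = {t: cells[(cells.stage == 32) & (cells.type == t)].cell_id.tolist() for t in mo}
        return mo, da

    def test_rescale_maps_mother_to_zero_daughter_to_one(self, timed_series):
        data, rpm = timed_series
        mo, da = self._mothers_daughters(data)
        table, _ = coordination_analysis(rpm, data.annotations, mo, da, seed=0)
        # mean summed level of mothers ~0, daughters ~1 by construction
        g = table.groupby(["daughter_type", "role"]).summed_level.mean()
        for t in da:
            assert g[(t, "mother")] == pytest.approx(0.0, abs=1e-9)
            assert g[(t, "daughter")] == pytest.approx(1.0, abs=1e-9)

    def test_shared_embryo_clock_detected(self, timed_series):
        data, rpm = timed_series
        mo, da = self._mothers_daughters(data)
        _, pairs = coordination_analysis(rpm, data.annotations, mo, da, seed=0)
        assert len(pairs) == 1
        assert pairs.r.iloc[0] > 0.5
        assert pairs.p.iloc[0] < 0.01

    def test_permutation_p_uniform_under_null(self):
        # calibration of the randomization machinery itself
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            r = float(np.corrcoef(x, y)[0, 1])
            ps.append(_permutation_pvalue(x, y, r, 200, rng))
        stat, p = scipy.stats.kstest(ps, "uniform")
        assert p > 0.01


class TestTemporalModel:
    def test_noiseless_parameters_recovered_up_to_gauge(self):
        x, truth = simulate_temporal(20, 40, 0.0, seed=2)
        res = TemporalExpressionModel(x).fit()
        assert res.sse < 1e-12
        assert np.abs(res.residuals).max() < 1e-6
        # gauge fixed: mean time 0, mean rate 1
        assert res.t.mean() == pytest.approx(0.0, abs=1e-9)
        assert res.alpha.mean() == pytest.approx(1.0, abs=1e-9)
        # time ordering preserved (affine gauge freedom only) for identifiable
        # cells: times before every onset are unconstrained (all genes silent)
        ident = truth["t"] > truth["t0"].min()
        rho = scipy.stats.spearmanr(res.t[ident], truth["t"][ident]).statistic
        assert rho == pytest.approx(1.0)

    def test_single_gene_all_active_is_line_fit(self):
        t = np.linspace(1.0, 2.0, 10)
        x = (1.5 * (t - 0.5))[:, None]
        res = TemporalExpressionModel(x).fit()
        assert res.sse < 1e-12

    def test_rate_recovery_under_noise(self):
        errs = []
        for seed in range(3):
            x, truth = simulate_temporal(20, 40, 0.1, seed=seed)
            res = TemporalExpressionModel(x).fit()
            A = np.vstack([res.t, np.ones_like(res.t)]).T
            (a, b), *_ = np.linalg.lstsq(A, truth["t"], rcond=None)
            errs.append(np.median(np.abs(res.alpha / a - truth["alpha"]) / truth["alpha"]))
        assert np.median(errs) < 0.15

    def test_unique_optimum_on_noiseless_data_across_inits(self):
        x, _ = simulate_temporal(10, 25, 0.0, seed=5)
        fits = [TemporalExpressionModel(x).fit() for _ in range(3)]
        for r in fits[1:]:
            np.testing.assert_allclose(r.alpha, fits[0].alpha, atol=1e-6)
            np.testing.assert_allclose(r.t, fits[0].t, atol=1e-6)


class TestGroupCompare:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=40)
        labels = np.array([0, 1] * 20)
        _, p = group_compare(values, labels, "kruskal_wallis")
        assert p > 0.05

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=40)
        labels = np.array([0] * 20 + [1] * 20)
        ps = []
        for shift in (0.0, 1.0, 3.0):
            values = base + shift * (labels == 1)
            ps.append(group_compare(values, labels, "t_two_sided")[1])
        assert ps[0] > ps[1] > ps[2]

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            group_compare([1, 2, 3, 4], [0, 0, 1, 1], "anova")
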