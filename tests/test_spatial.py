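import numpy as np
import pytest
import scipy.stats

import embryostrat as es
from embryostrat.spatial import (
    AxisSpace,
    align_axes_across_embryos,
    classifier_axis,
    compute_axis_space,
    project_cell_types,
    project_cells,
    random_colinearity_pvalue,
    residual_direction,
)


AXIS_CFG = dict(n_gradient=60, gradient_amp_log2=3.0)  # gradient-dominant embryos


@pytest.fixture(scope="module")
def axis_series():
    data = es.generate_series(es.SeriesConfig(embryos_per_stage=2, **AXIS_CFG), seed=7)
    rpm, _ = es.normalize_pipeline(data.expression)
    info = data.truth.cells.set_index("cell_id")
    return data, rpm, info


def _space_for(data, rpm, info, embryo):
    truth = data.truth.partition(embryo)
    cells = sorted(truth)
    pole = {c: 0 if info.loc[c, "pole"] == "animal" else 1 for c in cells}
    anchor = [c for c in cells if truth[c] in ("B1.16", "B2.16")]
    return cells, pole, compute_axis_space(rpm, cells, pole, anchor_cells=anchor)


class TestAxisSpace:
    def test_axes_orthonormal_after_rotation(self, axis_series):
        data, rpm, info = axis_series
        _, _, space = _space_for(data, rpm, info, "E16.0")
        G = space.axes @ space.axes.T
        np.testing.assert_allclose(G, np.eye(space.n_axes), atol=1e-8)

    def test_eigenvalues_non_increasing_and_nonnegative(self, axis_series):
        data, rpm, info = axis_series
        _, _, space = _space_for(data, rpm, info, "E16.0")
        assert np.all(space.eigenvalues >= -1e-9)
        assert np.all(np.diff(space.eigenvalues) <= 1e-9)

    def test_spectrum_sums_to_total_variance(self, axis_series):
        data, rpm, info = axis_series
        cells, pole, space = _space_for(data, rpm, info, "E16.0")
        logm = es.clip_and_log(rpm.subset(cells=cells, genes=space.gene_ids))
        total = logm.values.var(axis=0, ddof=1).sum()
        assert space.eigenvalues.sum() == pytest.approx(total, rel=1e-8)

    def test_within_pole_covariance_nulled(self, axis_series):
        data, rpm, info = axis_series
        cells, pole, space = _space_for(data, rpm, info, "E16.0")
        coords = project_cells(rpm, cells, space).to_numpy()
        pooled = 0.0
        for p in (0, 1):
            sel = coords[np.array([pole[c] == p for c in cells]), :2]
            pooled += np.cov(sel, rowvar=False)[0, 1] * (len(sel) - 1)
        assert abs(pooled) < 1e-8

    def test_too_few_cells_rejected(self, axis_series):
        data, rpm, info = axis_series
        truth = data.truth.partition("E16.0")
        cells = sorted(truth)[:2]
        with pytest.raises(ValueError, match="cells"):
            compute_axis_space(rpm, cells, {c: 0 for c in cells}, n_axes=2)


class TestRecovery:
    def test_axis1_tracks_planted_ap_ordering(self, axis_series):
        data, rpm, info = axis_series
        for e in ("E16.0", "E16.1"):
            cells, pole, space = _space_for(data, rpm, info, e)
            coords = project_cells(rpm, cells, space)
            ap = info.loc[cells, "ap"].to_numpy()
            r = scipy.stats.pearsonr(coords["axis1"], ap)[0]
            assert abs(r) > 0.95

    def test_axis2_separates_poles_perfectly(self, axis_series):
        data, rpm, info = axis_series
        for e in ("E16.0", "E16.1"):
            cells, pole, space = _space_for(data, rpm, info, e)
            coords = project_cells(rpm, cells, space)
            a2 = coords["axis2"].to_numpy()
            g0 = a2[[pole[c] == 0 for c in cells]]
            g1 = a2[[pole[c] == 1 for c in cells]]
            assert g0.min() > g1.max() or g0.max() < g1.min()

    def test_same_truth_embryos_agree(self, axis_series):
        data, rpm, info = axis_series
        spaces = [_space_for(data, rpm, info, e)[2] for e in ("E16.0", "E16.1")]
        aligned, report = align_axes_across_embryos(spaces)
        assert (report["cos"].abs() > 0.9).all()


class TestProjection:
    def test_center_maps_to_origin_and_linearity(self, axis_series):
        data, rpm, info = axis_series
        cells, _, space = _space_for(data, rpm, info, "E16.0")
        logm = es.clip_and_log(rpm.subset(cells=cells, genes=space.gene_ids))
        center_coord = (space.center - space.center) @ space.axes.T
        np.testing.assert_allclose(center_coord, 0)
        x = logm.values[0] - space.center
        y = logm.values[1] - space.center
        lhs = (2 * x + 3 * y) @ space.axes.T
        rhs = 2 * (x @ space.axes.T) + 3 * (y @ space.axes.T)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_type_projection_is_projection_of_mean(self, axis_series):
        import pandas as pd

        data, rpm, info = axis_series
        cells, _, space = _space_for(data, rpm, info, "E16.0")
        logm = es.clip_and_log(rpm.subset(cells=cells, genes=space.gene_ids))
        truth = data.truth.partition("E16.0")
        labels = sorted(set(truth.values()))
        profiles = pd.DataFrame(
            [logm.values[[c in [k for k in cells if truth[k] == lab] for c in cells]].mean(axis=0)
             for lab in labels],
            index=labels, columns=space.gene_ids,
        )
        type_coords = project_cell_types(profiles, space)
        cell_coords = project_cells(rpm, cells, space)
        for lab in labels:
            members = [c for c in cells if truth[c] == lab]
            np.testing.assert_allclose(
                type_coords.loc[lab], cell_coords.loc[members].mean(axis=0), atol=1e-8
            )

    def test_flat_profile_flagged_unmappable(self, axis_series):
        import pandas as pd

        data, rpm, info = axis_series
        _, _, space = _space_for(data, rpm, info, "E16.0")
        profiles = pd.DataFrame(
            [np.zeros(len(space.gene_ids)), np.random.default_rng(0).normal(3, 1, len(space.gene_ids))],
            index=["silent", "active"], columns=space.gene_ids,
        )
        with pytest.warns(UserWarning, match="unmappable"):
            out = project_cell_types(profiles, space)
        assert out.loc["silent"].isna().all()
        assert out.loc["active"].notna().all()

    def test_missing_gene_rejected(self, axis_series):
        data, rpm, info = axis_series
        cells, _, space = _space_for(data, rpm, info, "E16.0")
        smaller = rpm.subset(genes=rpm.gene_ids[:10])
        with pytest.raises(KeyError):
            project_cells(smaller, cells, space)


class TestClassifierAxis:
    def test_identical_sets_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            classifier_axis(np.ones((2, 4)), np.ones((3, 4)))

    def test_separates_planted_groups_with_margin(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.3, (6, 10)) + np.r_[np.full(5, 3.0), np.zeros(5)]
        b = rng.normal(0, 0.3, (6, 10)) + np.r_[np.zeros(5), np.full(5, 3.0)]
        axis = classifier_axis(a, b)
        pa, pb = a @ axis, b @ axis
        assert pa.min() > pb.max() + 1.0

    def test_residual_direction_orthogonal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        axis = np.zeros(6)
        axis[0] = 1.0
        v = residual_direction(X, axis)
        assert abs(v @ axis) < 1e-8
        assert np.linalg.norm(v) == pytest.approx(1.0)


class TestAlignment:
    def test_self_colinearity_is_one(self, axis_series):
        data, rpm, info = axis_series
        _, _, space = _space_for(data, rpm, info, "E16.0")
        _, report = align_axes_across_embryos([space, space])
        np.testing.assert_allclose(report["cos"], 1.0, atol=1e-12)

    def test_sign_flip_harmonized(self, axis_series):
        data, rpm, info = axis_series
        _, _, space = _space_for(data, rpm, info, "E16.0")
        flipped = AxisSpace(
            -space.axes, space.eigenvalues, space.axis_variances,
            space.gene_ids, space.center, {},
        )
        aligned, report = align_axes_across_embryos([space, flipped])
        np.testing.assert_allclose(aligned[1].axes, space.axes)
        np.testing.assert_allclose(report["cos"], 1.0, atol=1e-12)

    def test_null_pvalue_matches_monte_carlo(self):
        d, cos_obs = 4, 0.5
        rng = np.random.default_rng(0)
        v = rng.normal(size=(50000, d))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        w = rng.normal(size=(50000, d))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        mc = float(np.mean(np.abs(np.sum(v * w, axis=1)) >= cos_obs))
        closed = random_colinearity_pvalue(cos_obs, d)
        assert closed == pytest.approx(mc, rel=0.5)  # within 2x as sampling allows
        # high dimension: |cos| concentrates near zero
        assert random_colinearity_pvalue(0.3, 595) < 1e-10
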