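"""Expression-variability statistics and the temporal onset model.

Four analyses quantify how precisely a stereotyped embryo controls gene
expression:

* within- versus across-embryo coefficient of variation (is a gene's spread
  inside one embryo smaller than across embryos of the same stage?);
* marker-gene precision: for each marker, the fraction of cells with
  detectable expression and the level among expressing cells, separately in
  marker-positive and marker-negative cell types;
* coordination of gene upregulation: do all newly induced genes of a cell
  type advance together, embryo by embryo, and is that advancement shared
  across cell types (a common per-embryo developmental clock)?  Significance
  by embryo-label randomization;
* a piecewise-linear temporal model x_ij = alpha_i * max(t_j - t0_i, 0),
  with two parameters per gene (rate alpha_i, onset t0_i) and one per cell
  (capture time t_j), fitted by alternating least squares.  The likelihood
  is invariant under affine time reparameterization; the gauge is fixed by
  mean(t) = 0 and mean(alpha) = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .matrix import CellAnnotation, ExpressionMatrix, clip_and_log, group_by_embryo

__all__ = [
    "cv_within_vs_across",
    "MarkerReport",
    "find_marker_genes",
    "coordination_analysis",
    "TemporalExpressionModel",
    "TemporalModelResults",
    "group_compare",
]


# ---------------------------------------------------------------------------
# CV analysis
# ---------------------------------------------------------------------------

def cv_within_vs_across(
    m: ExpressionMatrix,
    ann: Sequence[CellAnnotation],
    min_max_expr: float = 16.0,
    n_samplings: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-embryo gene CVs against a same-stage random-sampling reference.

    For each embryo, genes with maximal expression > ``min_max_expr`` RPM in
    that embryo get a CV over its cells; the across-embryo reference is the
    mean CV over ``n_samplings`` random draws of equally many cells from all
    embryos of the stage.  Returns one row per (embryo, gene) with the
    within/across ratio; a ratio below 1 means the embryo is internally more
    uniform than the stage as a whole.
    """
    stages = {a.stage for a in ann}
    if len(stages) != 1:
        raise ValueError("cells must come from one stage")
    embryos = group_by_embryo(ann)
    if len(embryos) < 2:
        raise ValueError("need at least 2 embryos of the stage")
    rng = np.random.default_rng(seed)
    pool = [a.cell_id for a in ann]
    pool_idx = m.cell_index(pool)
    rows = []
    for e, cells in embryos.items():
        vals = m.values[m.cell_index(cells), :]
        keep = np.flatnonzero(vals.max(axis=0) > min_max_expr)
        if keep.size == 0:
            continue
        mu = vals[:, keep].mean(axis=0)
        sd = vals[:, keep].std(axis=0, ddof=1)
        cv_within = np.where(mu > 0, sd / mu, 0.0)
        cv_ref = np.zeros(keep.size)
        for _ in range(n_samplings):
            draw = rng.choice(pool_idx, size=len(cells), replace=False)
            sv = m.values[draw][:, keep]
            smu = sv.mean(axis=0)
            ssd = sv.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                cv_ref += np.where(smu > 0, ssd / smu, 0.0)
        cv_ref /= n_samplings
        for j, gi in enumerate(keep):
            ratio = cv_within[j] / cv_ref[j] if cv_ref[j] > 0 else np.nan
            rows.append((e, m.gene_ids[gi], cv_within[j], cv_ref[j], ratio))
    return pd.DataFrame(rows, columns=["embryo_id", "gene_id", "cv_within", "cv_across", "ratio"])


# ---------------------------------------------------------------------------
# Marker precision
# ---------------------------------------------------------------------------

@dataclass
class MarkerReport:
    """Per-marker positive/negative type sets, expressing fractions, levels."""

    table: pd.DataFrame

    @property
    def marker_genes(self) -> list[str]:
        return self.table["gene_id"].tolist()


def find_marker_genes(
    m: ExpressionMatrix,
    assignments: Mapping[str, str],
    min_max: float = 4.0,
    fold: float = 4.0,
    detect_rpm: float = 0.0,
    clip_floor: float = 1.0,
) -> MarkerReport:
    """Markers: genes with a >= ``fold`` gap between high- and low-expressing
    cell types (rank-gap split on clipped type means, max type mean >
    ``min_max`` RPM).

    For each marker the report gives the fraction of cells with detectable
    expression (> ``detect_rpm``) and the median level among expressing
    cells, separately for marker-positive and marker-negative types —
    separating Boolean (on/off fraction) from level control.
    """
    from .maternal import rank_gap_split

    if m.unit_tag != "rpm":
        raise ValueError(f"find_marker_genes expects rpm input, got {m.unit_tag!r}")
    cells = [c for c in m.cell_ids if c in assignments]
    sub = m.subset(cells=cells)
    labels = sorted(set(assignments[c] for c in cells))
    if len(labels) < 2:
        raise ValueError("need at least 2 cell types")
    type_means = np.stack([
        sub.values[sub.cell_index([c for c in cells if assignments[c] == lab]), :].mean(axis=0)
        for lab in labels
    ])
    clipped = np.maximum(type_means, clip_floor)
    candidate = (type_means.max(axis=0) > min_max) & (
        clipped.max(axis=0) / clipped.min(axis=0) >= fold
    )
    rows = []
    for gi in np.flatnonzero(candidate):
        log_means = np.log2(clipped[:, gi])
        split = rank_gap_split(log_means, labels, gene_id=sub.gene_ids[gi])
        pos_types = sorted(split.high_cells)
        neg_types = sorted(split.low_cells)
        pos_cells = [c for c in cells if assignments[c] in split.high_cells]
        neg_cells = [c for c in cells if assignments[c] in split.low_cells]
        pv = sub.values[sub.cell_index(pos_cells), gi]
        nv = sub.values[sub.cell_index(neg_cells), gi]
        pos_expr = pv[pv > detect_rpm]
        neg_expr = nv[nv > detect_rpm]
        rows.append(
            dict(
                gene_id=sub.gene_ids[gi],
                positive_types=",".join(pos_types),
                negative_types=",".join(neg_types),
                frac_pos=len(pos_expr) / len(pv) if len(pv) else np.nan,
                frac_neg=len(neg_expr) / len(nv) if len(nv) else np.nan,
                median_pos=float(np.median(pos_expr)) if len(pos_expr) else np.nan,
                median_neg=float(np.median(neg_expr)) if len(neg_expr) else np.nan,
            )
        )
    return MarkerReport(pd.DataFrame(rows, columns=[
        "gene_id", "positive_types", "negative_types",
        "frac_pos", "frac_neg", "median_pos", "median_neg",
    ]))


# ---------------------------------------------------------------------------
# Coordination of upregulation
# ---------------------------------------------------------------------------

def _rescaled_levels(
    logv: np.ndarray, mother_idx: np.ndarray, daughter_idx: np.ndarray
) -> np.ndarray:
    """Per-gene affine rescale: mother mean -> 0, daughter mean -> 1."""
    m0 = logv[mother_idx, :].mean(axis=0)
    m1 = logv[daughter_idx, :].mean(axis=0)
    return (logv - m0[None, :]) / (m1 - m0)[None, :]


def coordination_analysis(
    m: ExpressionMatrix,
    ann: Sequence[CellAnnotation],
    mother_cells: Sequence[str] | Mapping[str, Sequence[str]],
    daughters: Mapping[str, Sequence[str]],
    min_max: float = 4.0,
    fold: float = 4.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ordering of cells/embryos by coordinated upregulation, with a
    randomization test of between-type coordination.

    For each daughter type, genes upregulated > ``fold``-fold from its
    mother type (max > ``min_max`` RPM) are rescaled per gene so the mother
    mean is 0 and the daughter mean 1; cells sort by their summed rescaled
    level.  ``mother_cells`` is either one shared mother cell list or a
    mapping daughter type -> its mother's cells.  Per-embryo scores (mean
    over a daughter type's cells of the summed levels) are correlated
    between type pairs; the null permutes embryo labels (exact enumeration
    when feasible, otherwise ``n_perm`` draws), two-sided.
    """
    if m.unit_tag != "rpm":
        raise ValueError(f"coordination_analysis expects rpm input, got {m.unit_tag!r}")
    rng = np.random.default_rng(seed)
    emb_of = {a.cell_id: a.embryo_id for a in ann}
    if not isinstance(mother_cells, Mapping):
        mother_cells = {dtype: list(mother_cells) for dtype in daughters}
    cell_rows: list[pd.DataFrame] = []
    scores: dict[str, pd.Series] = {}
    for dtype, dcells in daughters.items():
        mcells = list(mother_cells[dtype])
        involved = mcells + list(dcells)
        logm = clip_and_log(m.subset(cells=involved))
        mi = logm.cell_index(mcells)
        di = logm.cell_index(list(dcells))
        max_ok = m.subset(cells=involved).values.max(axis=0) > min_max
        up = (logm.values[di, :].mean(axis=0) - logm.values[mi, :].mean(axis=0)) > np.log2(fold)
        keep = np.flatnonzero(max_ok & up)
        if keep.size == 0:
            warnings.warn(f"no upregulated genes for daughter type {dtype!r}")
            continue
        resc = _rescaled_levels(logm.values[:, keep], mi, di)
        summed = resc.sum(axis=1) / keep.size
        dset = set(dcells)
        df = pd.DataFrame(
            {
                "cell_id": logm.cell_ids,
                "daughter_type": dtype,
                "role": ["daughter" if c in dset else "mother" for c in logm.cell_ids],
                "summed_level": summed,
                "embryo_id": [emb_of[c] for c in logm.cell_ids],
            }
        ).sort_values("summed_level")
        cell_rows.append(df)
        dsub = df[df.role == "daughter"]
        scores[dtype] = dsub.groupby("embryo_id")["summed_level"].mean()
    cell_table = pd.concat(cell_rows, ignore_index=True) if cell_rows else pd.DataFrame()

    pairs = []
    types = sorted(scores)
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            a, b = scores[types[i]], scores[types[j]]
            shared = sorted(set(a.index) & set(b.index))
            if len(shared) < 3:
                continue
            x = a[shared].to_numpy()
            y = b[shared].to_numpy()
            r_obs = float(np.corrcoef(x, y)[0, 1])
            p = _permutation_pvalue(x, y, r_obs, n_perm, rng)
            pairs.append({"type_a": types[i], "type_b": types[j], "n_embryos": len(shared),
                          "r": r_obs, "p": p})
    return cell_table, pd.DataFrame(pairs)


def _permutation_pvalue(
    x: np.ndarray, y: np.ndarray, r_obs: float, n_perm: int, rng: np.random.Generator
) -> float:
    """Two-sided embryo-label permutation p; exact enumeration when cheap."""
    import itertools
    import math

    n = len(x)
    if math.factorial(n) <= max(n_perm, 1):
        perms = list(itertools.permutations(range(n)))
        rs = np.array([np.corrcoef(x, y[list(p)])[0, 1] for p in perms])
        return float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))
    count = 0
    for _ in range(n_perm):
        r = np.corrcoef(x, y[rng.permutation(n)])[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Temporal model
# ---------------------------------------------------------------------------

class TemporalExpressionModel:
    """Piecewise-linear onset model of expression timing.

    ``x`` is a cells x genes matrix of expression pre-normalized to mean 0
    in the mother cell type and 1 in the grand-daughter cell type.  The
    model is x_ij = alpha_i * max(t_j - t0_i, 0) with per-gene rate alpha_i
    >= 0 and onset t0_i, and per-cell capture time t_j.  ``fit`` minimizes
    the summed squared residuals by alternating optimization: given times,
    each gene's (alpha, t0) is solved by a 1-D scan over onset candidates
    with closed-form alpha; given gene parameters, each cell time is solved
    exactly on the piecewise-quadratic objective.
    """

    def __init__(self, x: np.ndarray, cell_ids: Sequence[str] | None = None,
                 gene_ids: Sequence[str] | None = None):
        self.x = np.asarray(x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("x must be cells x genes")
        n, g = self.x.shape
        self.cell_ids = list(cell_ids) if cell_ids is not None else [f"c{i}" for i in range(n)]
        self.gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(g)]

    def fit(self, max_rounds: int = 200, tol: float = 1e-6) -> "TemporalModelResults":
        x = self.x
        n, g = x.shape
        # initial times: per-cell mean expression is a monotone proxy of time
        t = x.mean(axis=1)
        t = (t - t.mean()) / (t.std() + 1e-12)
        sse_prev = None
        alpha = np.ones(g)
        t0 = np.zeros(g)
        converged = False
        for _ in range(max_rounds):
            alpha, t0 = _fit_genes(x, t)
            t = _fit_times(x, alpha, t0, t)
            resid = x - _predict(t, alpha, t0)
            sse = float(np.sum(resid**2))
            if sse_prev is not None and sse_prev - sse <= tol * max(sse_prev, 1e-12):
                converged = True
                break
            sse_prev = sse
        # gauge: mean(t) = 0, mean(alpha) = 1 (affine time reparameterization)
        a = alpha.mean()
        if a > 0:
            t_mean = t.mean()
            t = (t - t_mean) * a
            t0 = (t0 - t_mean) * a
            alpha = alpha / a
        resid = x - _predict(t, alpha, t0)
        return TemporalModelResults(self, alpha, t0, t, resid, converged)


def _predict(t: np.ndarray, alpha: np.ndarray, t0: np.ndarray) -> np.ndarray:
    return alpha[None, :] * np.maximum(t[:, None] - t0[None, :], 0.0)


def _fit_genes(x: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (alpha, t0): scan the active-set segments defined by the cell
    times; within each segment (alpha, t0) has a closed form (line fit on the
    active cells, onset at the line's root, clamped into the segment)."""
    n, g = x.shape
    d = np.unique(t)
    # t0 segments: (-inf, d0), [d0, d1), ..., [d_{m-1}, d_m), [d_m, inf)
    seg_lo = np.concatenate([[-np.inf], d])
    seg_hi = np.concatenate([d, [np.inf]])
    eps = 1e-12
    alpha = np.zeros(g)
    t0 = np.zeros(g)
    for gi in range(g):
        xi = x[:, gi]
        total_sq = float(np.sum(xi**2))
        best = (total_sq, 0.0, float(d[-1]))  # all-inactive fallback
        for lo, hi in zip(seg_lo, seg_hi):
            active = t > lo if np.isfinite(lo) else np.ones(n, dtype=bool)
            if not active.any():
                continue
            ta, xa = t[active], xi[active]
            cand_t0 = None
            if len(ta) >= 2 and np.ptp(ta) > 0:
                a_slope, b = np.polyfit(ta, xa, 1)
                if a_slope > 0:
                    cand_t0 = -b / a_slope
            if cand_t0 is None:
                cand_t0 = (lo + hi) / 2 if np.isfinite(lo) and np.isfinite(hi) else (
                    hi - 1.0 if np.isfinite(hi) else lo + 1.0
                )
            c = min(max(cand_t0, lo if np.isfinite(lo) else cand_t0), hi - eps if np.isfinite(hi) else cand_t0)
            dt = np.maximum(t - c, 0.0)
            denom = float(dt @ dt)
            if denom == 0:
                continue
            a = max(float(xi @ dt) / denom, 0.0)
            sse = total_sq - 2 * a * float(xi @ dt) + a * a * denom
            if sse < best[0] - 1e-15:
                best = (sse, a, float(c))
        alpha[gi], t0[gi] = best[1], best[2]
    return alpha, t0


def _fit_times(x: np.ndarray, alpha: np.ndarray, t0: np.ndarray, t_prev: np.ndarray) -> np.ndarray:
    """Per-cell time: exact minimum of the piecewise-quadratic objective."""
    n, g = x.shape
    breaks = np.sort(np.unique(t0))
    bounds = np.concatenate([[-np.inf], breaks, [np.inf]])
    t_new = t_prev.copy()
    for j in range(n):
        xj = x[j]
        best_val, best_t = np.inf, t_prev[j]
        for si in range(len(bounds) - 1):
            lo, hi = bounds[si], bounds[si + 1]
            # on [lo, hi] the active genes are those with onset at or before lo
            active = (t0 <= lo + 1e-12) if np.isfinite(lo) else np.zeros(g, dtype=bool)
            a2 = float(np.sum(alpha[active] ** 2))
            if a2 == 0:
                # objective flat in t on this segment; pick a finite point
                cand = hi if np.isfinite(hi) else (lo if np.isfinite(lo) else 0.0)
            else:
                num = float(np.sum(alpha[active] * (xj[active] + alpha[active] * t0[active])))
                cand = min(max(num / a2, lo), hi)
            val = float(np.sum((xj - alpha * np.maximum(cand - t0, 0.0)) ** 2))
            if val < best_val - 1e-15:
                best_val, best_t = val, float(cand)
        t_new[j] = best_t
    return t_new


class TemporalModelResults:
    """Fitted rates, onsets, cell times and residuals of the onset model."""

    def __init__(self, model, alpha, t0, t, residuals, converged):
        self.model = model
        self.alpha = alpha
        self.t0 = t0
        self.t = t
        self.residuals = residuals
        self.converged = converged
        if not converged:
            warnings.warn("temporal model did not converge; returning best iterate")

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))

    def gene_residuals(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.mean(self.residuals**2, axis=0)), index=self.model.gene_ids, name="rmse"
        )

    def predict(self) -> np.ndarray:
        return _predict(self.t, self.alpha, self.t0)

    def summary(self) -> str:
        return "\n".join(
            [
                "Piecewise-linear expression-timing fit",
                f"  cells: {len(self.t)}   genes: {len(self.alpha)}   converged: {self.converged}",
                f"  total SSE: {self.sse:.4g}   median gene RMSE: {self.gene_residuals().median():.4g}",
                f"  gauge: mean(t)={self.t.mean():+.2e}, mean(alpha)={self.alpha.mean():.6f}",
            ]
        )


# ---------------------------------------------------------------------------
# Generic group comparison
# ---------------------------------------------------------------------------

def group_compare(
    values: Sequence[float], labels: Sequence, test: str = "kruskal_wallis"
) -> tuple[float, float]:
    """Two-sided group comparison: Kruskal-Wallis or two-sample t-test."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == l] for l in np.unique(labels)]
    if test == "kruskal_wallis":
        stat, p = scipy.stats.kruskal(*groups)
    elif test == "t_two_sided":
        if len(groups) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        stat, p = scipy.stats.ttest_ind(groups[0], groups[1])
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(p)
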