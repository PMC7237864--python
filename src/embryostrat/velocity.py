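"""Constant-rate RNA velocity from spliced/unspliced count pairs.

Unspliced (intronic) reads report ongoing transcription; at degradation
steady state u ~ gamma * s, so the imbalance v = u - gamma * s signs current
up- or down-regulation of each gene in each cell.  The normalized
degradation rate gamma is fitted per gene as the through-origin slope of u
on s over the cells in the top decile of spliced expression, and velocities
are scaled by 1/gamma to extrapolate future spliced abundance
(s_ext = s + v/gamma = u/gamma).  Neither genes nor cells are pooled.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .spatial import AxisSpace, project_cells

__all__ = [
    "estimate_gamma",
    "compute_velocity",
    "VelocityModel",
    "VelocityResults",
    "project_velocity",
]


def estimate_gamma(
    u: np.ndarray, s: np.ndarray, decile: float = 0.9, min_cells: int = 3
) -> float | None:
    """Normalized degradation rate: through-origin slope of u on s over the
    top decile of spliced expression (ties at the boundary included).

    Returns None (gene skipped) when fewer than ``min_cells`` cells express
    the gene.  The slope is clipped at zero.
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    nonzero = s > 0
    if nonzero.sum() < min_cells:
        return None
    if nonzero.sum() >= 10:
        cut = np.quantile(s[nonzero], decile)
        sel = s >= cut
    else:
        sel = nonzero
    denom = float(np.sum(s[sel] ** 2))
    if denom == 0:
        return None
    return max(float(np.sum(u[sel] * s[sel]) / denom), 0.0)


def compute_velocity(
    u: np.ndarray, s: np.ndarray, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """v = u - gamma*s and the extrapolated spliced level s_ext = u/gamma.

    With gamma = 0 the extrapolation is undefined and s_ext is NaN."""
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    v = u - gamma * s
    if gamma > 0:
        s_ext = u / gamma
    else:
        s_ext = np.full_like(u, np.nan)
    return v, s_ext


class VelocityModel:
    """Constant-rate velocity model over matched spliced/unspliced matrices.

    Parameters
    ----------
    spliced, unspliced
        Two expression matrices with identical cell and gene indexing, on a
        common per-cell scale (RPM or counts normalized the same way).
    """

    def __init__(self, spliced: ExpressionMatrix, unspliced: ExpressionMatrix):
        if spliced.cell_ids != unspliced.cell_ids or spliced.gene_ids != unspliced.gene_ids:
            raise ValueError("spliced and unspliced matrices must share indexing")
        self.spliced = spliced
        self.unspliced = unspliced

    def fit(self, decile: float = 0.9, min_cells: int = 3) -> "VelocityResults":
        S = self.spliced.values
        U = self.unspliced.values
        n_genes = S.shape[1]
        gamma = np.full(n_genes, np.nan)
        skipped = []
        for gi in range(n_genes):
            g = estimate_gamma(U[:, gi], S[:, gi], decile=decile, min_cells=min_cells)
            if g is None:
                skipped.append(self.spliced.gene_ids[gi])
            else:
                gamma[gi] = g
        V = np.where(np.isfinite(gamma)[None, :], U - gamma[None, :] * S, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            S_ext = np.where(gamma[None, :] > 0, U / gamma[None, :], np.nan)
        return VelocityResults(self, gamma, V, S_ext, skipped)


class VelocityResults:
    """Fitted degradation rates, velocities, and spliced extrapolations."""

    def __init__(self, model, gamma, velocity, s_ext, skipped_genes):
        self.model = model
        self.gamma = gamma
        self.velocity = velocity
        self.s_ext = s_ext
        self.skipped_genes = skipped_genes

    def gamma_series(self) -> pd.Series:
        return pd.Series(self.gamma, index=self.model.spliced.gene_ids, name="gamma")

    def identity_audit(self) -> float:
        """Max |v - (u - gamma*s)| over all finite entries (0 by construction)."""
        expected = self.model.unspliced.values - self.gamma[None, :] * self.model.spliced.values
        diff = np.abs(self.velocity - expected)
        return float(np.nanmax(diff)) if np.isfinite(diff).any() else 0.0

    def summary(self) -> str:
        g = self.gamma[np.isfinite(self.gamma)]
        return "\n".join(
            [
                "Constant-rate RNA velocity fit",
                f"  genes fitted: {g.size} / {len(self.gamma)} (skipped: {len(self.skipped_genes)})",
                f"  gamma median [IQR]: {np.median(g):.4g} "
                f"[{np.percentile(g, 25):.4g}, {np.percentile(g, 75):.4g}]",
                f"  identity audit max |v-(u-gamma*s)|: {self.identity_audit():.3g}",
            ]
        )


def project_velocity(
    results: VelocityResults,
    space: AxisSpace,
    cells: Sequence[str] | None = None,
    clip_floor: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Velocity arrows in an embedding: base = projected spliced profile,
    tip = projected extrapolated profile, both on the embedding's gene set
    after the standard clip-at-1 log transform.

    Genes with undefined extrapolation (gamma = 0 or skipped) keep their
    current spliced level at the tip, contributing zero arrow length.
    """
    m_s = results.model.spliced
    cells = list(cells) if cells is not None else list(m_s.cell_ids)
    gi = m_s.gene_index(space.gene_ids)
    ci = m_s.cell_index(cells)
    s_vals = m_s.values[np.ix_(ci, gi)]
    e_vals = results.s_ext[np.ix_(ci, gi)]
    e_vals = np.where(np.isfinite(e_vals), e_vals, s_vals)
    base_m = ExpressionMatrix(s_vals, cells, space.gene_ids, "rpm")
    tip_m = ExpressionMatrix(np.maximum(e_vals, 0.0), cells, space.gene_ids, "rpm")
    base = project_cells(base_m, cells, space)
    tip = project_cells(tip_m, cells, space)
    return base, tip
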