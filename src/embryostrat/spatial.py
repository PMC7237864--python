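"""Recovery of embryonic axes from within-embryo expression variance.

In a stereotyped embryo the dominant directions of expression variation
between the cells of a single embryo recapitulate its anatomical axes.  PCA
of log-transformed profiles (genes with a 4-fold change within the embryo)
yields leading components whose 2-D span contains the anterior-posterior and
animal-vegetal axes; a final in-plane rotation separates them by removing
the expression trends *within* the two embryonic poles (the first consensus
split of the embryo): after rotation, one axis carries the pooled
within-pole trend (anterior-posterior) and the other the pole separation
(animal-vegetal).  Cells, cell types, and later-stage cells can all be
projected into the resulting coordinate system, and finer axes can be built
from sister-type classifier directions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .matrix import ExpressionMatrix, GeneSet, clip_and_log

__all__ = [
    "AxisSpace",
    "compute_axis_space",
    "project_cells",
    "project_cell_types",
    "classifier_axis",
    "residual_direction",
    "align_axes_across_embryos",
    "random_colinearity_pvalue",
]


@dataclass
class AxisSpace:
    """Orthonormal gene-loading axes with eigenvalue scales for projection.

    ``axes`` rows are unit gene-loading vectors (the rotated leading pair
    first); ``eigenvalues`` is the full non-increasing PCA spectrum;
    ``axis_variances`` are the projection variances along the final axes
    (rotation can reorder variance between the leading pair).
    """

    axes: np.ndarray  # n_axes x n_genes, orthonormal rows
    eigenvalues: np.ndarray  # PCA spectrum, non-increasing
    axis_variances: np.ndarray
    gene_ids: list[str]
    center: np.ndarray
    rotation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.axes, dtype=float)
        G = A @ A.T
        if not np.allclose(G, np.eye(A.shape[0]), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        self.axes = A
        self.eigenvalues = ev

    @property
    def n_axes(self) -> int:
        return self.axes.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_ids": self.gene_ids,
                "axes": self.axes.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "axis_variances": np.asarray(self.axis_variances).tolist(),
                "center": self.center.tolist(),
                "rotation": self.rotation,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AxisSpace":
        d = json.loads(text)
        return cls(
            np.array(d["axes"]),
            np.array(d["eigenvalues"]),
            np.array(d["axis_variances"]),
            list(d["gene_ids"]),
            np.array(d["center"]),
            d.get("rotation", {}),
        )


def _axis_gene_filter(
    m: ExpressionMatrix, cells: Sequence[str], fold_min: float, clip_floor: float = 1.0
) -> GeneSet:
    sub = m.subset(cells=cells)
    clipped = np.maximum(sub.values, clip_floor)
    keep = clipped.max(axis=0) / clipped.min(axis=0) >= fold_min
    return GeneSet(
        [g for g, k in zip(sub.gene_ids, keep) if k],
        provenance=f">= {fold_min:g}-fold within embryo",
    )


def compute_axis_space(
    m: ExpressionMatrix,
    cells: Sequence[str],
    pole_partition: Mapping[str, int],
    n_axes: int = 2,
    fold_min: float = 4.0,
    anchor_cells: Iterable[str] | None = None,
) -> AxisSpace:
    """Embryonic axes of one embryo by PCA with within-pole derotation.

    ``pole_partition`` maps each cell to 0/1 (the embryo's first consensus
    split, i.e. the two poles).  The two leading principal components are
    rotated in-plane so the pooled within-pole covariance of the two
    coordinates vanishes; the rotated axis with the larger standardized
    between-pole separation becomes axis 2 (the pole axis), the other axis 1.
    Axis 1 is oriented so the ``anchor_cells`` (e.g. the posterior reference
    type) sit at negative coordinates; axis 2 so pole 0 is positive.
    """
    cells = list(cells)
    if len(cells) <= n_axes:
        raise ValueError(f"{len(cells)} cells cannot support {n_axes} axes")
    missing = [c for c in cells if c not in pole_partition]
    if missing:
        raise ValueError(f"pole partition missing cells: {missing[:3]}")
    genes = _axis_gene_filter(m, cells, fold_min)
    logm = clip_and_log(m.subset(cells=cells, genes=list(genes)))
    X = logm.values
    center = X.mean(axis=0)
    Xc = X - center
    # PCA via SVD
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (len(cells) - 1)
    axes = Vt[:n_axes].copy()
    coords = Xc @ axes.T

    rotation: dict = {}
    if n_axes >= 2:
        pole = np.array([pole_partition[c] for c in cells])
        # pooled within-pole covariance of the leading coordinate pair
        S = np.zeros((2, 2))
        for p in np.unique(pole):
            sel = coords[pole == p, :2]
            if len(sel) > 1:
                S += np.cov(sel, rowvar=False) * (len(sel) - 1)
        evals, evecs = np.linalg.eigh(S)  # rotation diagonalizing S
        R = evecs.T  # rows are the rotated directions
        new_pair = R @ axes[:2]
        new_coords = coords[:, :2] @ R.T
        # standardized between-pole separation decides which axis is the pole axis
        sep = []
        for k in range(2):
            g0 = new_coords[pole == np.unique(pole)[0], k]
            g1 = new_coords[pole == np.unique(pole)[-1], k]
            within = np.sqrt(max(np.var(g0) + np.var(g1), 1e-12))
            sep.append(abs(g0.mean() - g1.mean()) / within)
        pole_axis = int(np.argmax(sep))
        order = [1 - pole_axis, pole_axis]  # axis 1 = trend axis, axis 2 = pole axis
        new_pair = new_pair[order]
        new_coords = new_coords[:, order]
        # orientation: pole 0 positive on axis 2
        p0 = np.unique(pole)[0]
        if new_coords[pole == p0, 1].mean() < 0:
            new_pair[1] *= -1
            new_coords[:, 1] *= -1
        # orientation: anchor cells negative on axis 1
        if anchor_cells is not None:
            idx = [i for i, c in enumerate(cells) if c in set(anchor_cells)]
            if idx and new_coords[idx, 0].mean() > 0:
                new_pair[0] *= -1
                new_coords[:, 0] *= -1
        axes[:2] = new_pair
        coords = np.column_stack([new_coords, coords[:, 2:]])
        rotation = {
            "within_pole_cov_before": float(S[0, 1]),
            "axis_order": order,
        }
    axis_var = coords.var(axis=0, ddof=1)
    return AxisSpace(axes, eigenvalues, axis_var, list(genes), center, rotation)


def project_cells(
    m: ExpressionMatrix, cells: Sequence[str], space: AxisSpace
) -> pd.DataFrame:
    """Project cells (possibly from another stage or embryo) onto the axes.

    coordinate_a = (x_j - center) . axis_a on the space's gene set; all the
    space's genes must be present in the matrix.
    """
    logm = clip_and_log(m.subset(cells=list(cells), genes=space.gene_ids))
    coords = (logm.values - space.center) @ space.axes.T
    return pd.DataFrame(coords, index=list(cells), columns=[f"axis{k+1}" for k in range(space.n_axes)])


def project_cell_types(profiles: pd.DataFrame, space: AxisSpace) -> pd.DataFrame:
    """Project mean log2 type profiles (types x genes) onto the axes.

    Types with zero variance on the space's gene set (transcriptionally
    silent lineages) are flagged unmappable (NaN coordinates).
    """
    missing = [g for g in space.gene_ids if g not in profiles.columns]
    if missing:
        raise KeyError(f"profiles missing genes: {missing[:3]}")
    X = profiles[space.gene_ids].to_numpy(dtype=float)
    coords = (X - space.center) @ space.axes.T
    out = pd.DataFrame(coords, index=profiles.index, columns=[f"axis{k+1}" for k in range(space.n_axes)])
    flat = X.std(axis=1) == 0
    if flat.any():
        warnings.warn(f"types with flat profiles flagged unmappable: {list(profiles.index[flat])}")
        out.iloc[flat, :] = np.nan
    return out


def classifier_axis(profiles_a: np.ndarray, profiles_b: np.ndarray) -> np.ndarray:
    """Unit gene-loading vector separating two sister type sets: the
    normalized difference of their mean profiles."""
    a = np.atleast_2d(np.asarray(profiles_a, dtype=float)).mean(axis=0)
    b = np.atleast_2d(np.asarray(profiles_b, dtype=float)).mean(axis=0)
    diff = a - b
    norm = np.linalg.norm(diff)
    if norm == 0:
        raise ValueError("identical mean profiles: classifier axis undefined")
    return diff / norm


def residual_direction(X: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Direction of most remaining variance after removing a known axis:
    the leading PC of the residuals, orthogonal to ``axis``."""
    X = np.asarray(X, dtype=float)
    axis = np.asarray(axis, dtype=float)
    Xc = X - X.mean(axis=0)
    resid = Xc - np.outer(Xc @ axis, axis)
    _, _, Vt = np.linalg.svd(resid, full_matrices=False)
    v = Vt[0]
    v = v - (v @ axis) * axis  # numerical cleanup
    return v / np.linalg.norm(v)


def random_colinearity_pvalue(cos: float, d: int) -> float:
    """P(|cos| >= observed) for two independent random unit vectors in d
    dimensions: cos^2 follows Beta(1/2, (d-1)/2)."""
    if not 0 <= abs(cos) <= 1:
        raise ValueError("cosine must lie in [-1, 1]")
    if d < 2:
        raise ValueError("need dimension >= 2")
    return float(scipy.stats.beta.sf(cos**2, 0.5, (d - 1) / 2))


def align_axes_across_embryos(
    spaces: Sequence[AxisSpace],
) -> tuple[list[AxisSpace], pd.DataFrame]:
    """Harmonize axis signs across embryos and report pairwise colinearity.

    Different embryos recover the same directions up to occasional sign
    swaps; each space's axes are flipped to correlate positively with the
    first space's, on the shared gene set.  The report lists, per axis and
    embryo pair, the absolute loading cosine and the null probability of
    such colinearity for random unit vectors in the shared dimension.
    """
    if not spaces:
        raise ValueError("no spaces given")
    ref = spaces[0]
    aligned = [ref]
    for sp in spaces[1:]:
        shared = [g for g in ref.gene_ids if g in set(sp.gene_ids)]
        if len(shared) < 2:
            raise ValueError("spaces share fewer than 2 genes")
        ri = [ref.gene_ids.index(g) for g in shared]
        si = [sp.gene_ids.index(g) for g in shared]
        new_axes = sp.axes.copy()
        flips = []
        for k in range(min(ref.n_axes, sp.n_axes)):
            c = float(ref.axes[k, ri] @ sp.axes[k, si])
            if c < 0:
                new_axes[k] *= -1
                flips.append(k)
        aligned.append(
            AxisSpace(
                new_axes, sp.eigenvalues, sp.axis_variances, sp.gene_ids, sp.center,
                {**sp.rotation, "sign_flips": flips},
            )
        )
    rows = []
    for i in range(len(aligned)):
        for j in range(i + 1, len(aligned)):
            a, b = aligned[i], aligned[j]
            shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
            ai = [a.gene_ids.index(g) for g in shared]
            bi = [b.gene_ids.index(g) for g in shared]
            for k in range(min(a.n_axes, b.n_axes)):
                va = a.axes[k, ai]
                vb = b.axes[k, bi]
                cos = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
                rows.append(
                    {
                        "pair": (i, j),
                        "axis": k + 1,
                        "cos": cos,
                        "null_p": random_colinearity_pvalue(cos, len(shared)),
                    }
                )
    return aligned, pd.DataFrame(rows)
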