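"""Core data model and expression transforms.

The central container is :class:`ExpressionMatrix`, a cells x genes matrix of
non-negative expression values tagged with its unit (``raw_counts``, ``rpm``,
``log2rpm`` or ``zscore``).  Every downstream algorithm states which unit it
expects, and the shared transforms here (clipping, log2, per-gene
standardization) move data between units in exactly one way, so that e.g.
"clip at 1 RPM then log2" means the same thing in every module.

On disk, expression tables follow the common supplementary-table layout of
genes x cells (TSV with a header row of cell identifiers) or a MatrixMarket
coordinate triplet with two newline-delimited name files; both are transposed
to cells x genes in memory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "CellAnnotation",
    "GeneSet",
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "clip_and_log",
    "zscore_genes",
]

UNIT_TAGS = ("raw_counts", "rpm", "log2rpm", "zscore")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers and a unit tag.

    Parameters
    ----------
    values
        2-D float array, one row per cell, one column per gene.  Entries must
        be non-negative when the unit is ``raw_counts`` or ``rpm``.
    cell_ids, gene_ids
        Unique string identifiers matching the matrix dimensions.
    unit_tag
        One of ``raw_counts``, ``rpm``, ``log2rpm``, ``zscore``.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    unit_tag: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (cells x genes)")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if self.unit_tag not in UNIT_TAGS:
            raise ValueError(f"unknown unit_tag {self.unit_tag!r}")
        if self.unit_tag in ("raw_counts", "rpm") and np.any(self.values < 0):
            raise ValueError(f"negative entries not allowed for unit {self.unit_tag}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def cell_index(self, cell_ids: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in cell_ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message formatting
            raise KeyError(f"unknown cell id {e.args[0]!r}") from None

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as e:  # pragma: no cover
            raise KeyError(f"unknown gene id {e.args[0]!r}") from None

    def subset(
        self,
        cells: Iterable[str] | None = None,
        genes: Iterable[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return a copy restricted to the given cells and/or genes (order kept)."""
        vals = self.values
        cids = list(self.cell_ids)
        gids = list(self.gene_ids)
        if cells is not None:
            cells = list(cells)
            vals = vals[self.cell_index(cells), :]
            cids = cells
        if genes is not None:
            genes = list(genes)
            vals = vals[:, self.gene_index(genes)]
            gids = genes
        return ExpressionMatrix(vals.copy(), cids, gids, self.unit_tag)

    def with_values(self, values: np.ndarray, unit_tag: str | None = None) -> "ExpressionMatrix":
        return replace(self, values=values, unit_tag=unit_tag or self.unit_tag)

    def gene_vector(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_index([gene_id])[0]]

    def to_frame(self) -> pd.DataFrame:
        """Cells x genes DataFrame view (copy)."""
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (optional dependency)."""
        import anndata

        ad = anndata.AnnData(
            X=self.values.copy(),
            obs=pd.DataFrame(index=self.cell_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )
        ad.uns["unit_tag"] = self.unit_tag
        return ad


@dataclass
class CellAnnotation:
    """Per-cell metadata: embryo of origin and developmental stage.

    ``stage`` is the cell count of the embryo at collection (2, 4, 8, 16, 32,
    44 or 64 for these embryos); ``known_identity`` optionally records an
    anatomically assigned blastomere name used only for evaluation.
    """

    cell_id: str
    embryo_id: str
    stage: int
    known_identity: str | None = None


def group_by_embryo(ann: Sequence[CellAnnotation]) -> dict[str, list[str]]:
    """Map embryo_id -> list of its cell_ids, preserving input order."""
    out: dict[str, list[str]] = {}
    for a in ann:
        out.setdefault(a.embryo_id, []).append(a.cell_id)
    return out


def annotations_for(ann: Sequence[CellAnnotation], cell_ids: Iterable[str]) -> list[CellAnnotation]:
    lookup = {a.cell_id: a for a in ann}
    return [lookup[c] for c in cell_ids]


@dataclass
class GeneSet:
    """A named list of gene identifiers with the rule that selected them."""

    gene_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)

    def __contains__(self, g: str) -> bool:
        return g in set(self.gene_ids)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_expression(path: str, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression table into a cells x genes matrix of raw counts.

    ``tsv``: genes x cells table, header row of cell ids, first column gene
    ids.  ``mtx_triplet``: MatrixMarket file ``<path>`` (genes x cells)
    accompanied by ``<path>.genes.txt`` and ``<path>.cells.txt`` name files.
    """
    if dialect == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        _check_unique(header, "cell")  # pandas would silently rename duplicates
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = df.map(lambda v: isinstance(v, str)).to_numpy()
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-numeric value at gene {df.index[r]!r}, cell {df.columns[c]!r}"
            )
        values = df.to_numpy(dtype=float).T  # disk is genes x cells
        return ExpressionMatrix(values, list(df.columns), list(df.index), "raw_counts")
    if dialect == "mtx_triplet":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_names(path + ".genes.txt")
        cells = _read_names(path + ".cells.txt")
        return ExpressionMatrix(np.asarray(mat, dtype=float).T, cells, genes, "raw_counts")
    raise ValueError(f"unknown dialect {dialect!r}")


def write_expression(m: ExpressionMatrix, path: str, dialect: str = "tsv") -> None:
    """Write a matrix in the genes x cells on-disk layout (inverse of read)."""
    if dialect == "tsv":
        df = pd.DataFrame(m.values.T, index=m.gene_ids, columns=m.cell_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.17g")
        return
    if dialect == "mtx_triplet":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values.T))
        if not path.endswith(".mtx") and os.path.exists(path + ".mtx"):
            path_written = path + ".mtx"
            os.replace(path_written, path)
        _write_names(path + ".genes.txt", m.gene_ids)
        _write_names(path + ".cells.txt", m.cell_ids)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_names(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _write_names(path: str, names: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for n in names:
            fh.write(n + "\n")


def read_annotations(path: str) -> list[CellAnnotation]:
    """Read per-cell metadata TSV (cell_id, embryo_id, stage, known_identity)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "embryo_id": str})
    out = []
    for _, row in df.iterrows():
        known = row.get("known_identity")
        if pd.isna(known):
            known = None
        out.append(CellAnnotation(str(row["cell_id"]), str(row["embryo_id"]), int(row["stage"]), known))
    return out


def write_annotations(ann: Sequence[CellAnnotation], path: str) -> None:
    pd.DataFrame(
        {
            "cell_id": [a.cell_id for a in ann],
            "embryo_id": [a.embryo_id for a in ann],
            "stage": [a.stage for a in ann],
            "known_identity": [a.known_identity for a in ann],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Shared transforms
# ---------------------------------------------------------------------------

def clip_and_log(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Clip RPM values to ``floor`` from below, then take log2.

    Pseudocounts are implemented by clipping, never by adding; with the
    default floor of 1 RPM, zero counts map to exactly 0 on the log scale.
    """
    if m.unit_tag != "rpm":
        raise ValueError(f"clip_and_log expects rpm input, got {m.unit_tag!r}")
    if floor <= 0:
        raise ValueError("floor must be positive")
    return m.with_values(np.log2(np.maximum(m.values, floor)), "log2rpm")


def zscore_genes(
    m: ExpressionMatrix, cell_subset: Sequence[str] | None = None
) -> tuple[ExpressionMatrix, GeneSet]:
    """Standardize each gene to mean 0 / sample variance 1 over a cell subset.

    Returns the standardized matrix restricted to the subset, plus the set of
    genes excluded because their variance over the subset is zero.  Sample
    variance uses the n-1 denominator.
    """
    if m.unit_tag != "log2rpm":
        raise ValueError(f"zscore_genes expects log2rpm input, got {m.unit_tag!r}")
    sub = m if cell_subset is None else m.subset(cells=cell_subset)
    if sub.n_cells < 2:
        raise ValueError("need at least 2 cells to standardize (variance undefined)")
    mu = sub.values.mean(axis=0)
    sd = sub.values.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = GeneSet(
        [g for g, k in zip(sub.gene_ids, keep) if not k],
        provenance="zero variance over subset",
    )
    vals = (sub.values[:, keep] - mu[keep]) / sd[keep]
    out = ExpressionMatrix(vals, sub.cell_ids, [g for g, k in zip(sub.gene_ids, keep) if k], "zscore")
    return out, dropped
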