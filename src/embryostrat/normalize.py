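"""Two-step sequencing-depth normalization.

Deep per-cell libraries are first coarsely scaled so every cell has the same
total read count (reported on the reads-per-million scale), then a fine
per-cell factor is estimated on constitutively expressed genes — genes whose
expression exceeds a floor in *every* cell — by matching log2 read counts to
a reference cell.  The fine factor removes residual depth differences caused
by compositional changes between stages while multiplying each cell by a
single count-independent scalar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GeneSet

__all__ = [
    "NormalizationReport",
    "coarse_normalize",
    "select_constitutive_genes",
    "fine_normalize",
]


@dataclass
class NormalizationReport:
    """Per-cell scale factors and the gene set behind the fine step."""

    coarse_factor: dict[str, float] = field(default_factory=dict)
    fine_factor: dict[str, float] = field(default_factory=dict)
    constitutive_genes: GeneSet | None = None
    reference_cell: str | None = None

    def to_frame(self) -> pd.DataFrame:
        cells = sorted(set(self.coarse_factor) | set(self.fine_factor))
        return pd.DataFrame(
            {
                "cell_id": cells,
                "coarse_factor": [self.coarse_factor.get(c, np.nan) for c in cells],
                "fine_factor": [self.fine_factor.get(c, np.nan) for c in cells],
            }
        )


def coarse_normalize(m: ExpressionMatrix) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Scale each cell to a common total of 10^6 reads (RPM)."""
    if m.unit_tag != "raw_counts":
        raise ValueError(f"coarse_normalize expects raw counts, got {m.unit_tag!r}")
    totals = m.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {m.cell_ids[zero[0]]!r} has zero total count")
    factors = 1e6 / totals
    out = m.with_values(m.values * factors[:, None], "rpm")
    report = NormalizationReport(coarse_factor=dict(zip(m.cell_ids, factors.tolist())))
    return out, report


def select_constitutive_genes(m: ExpressionMatrix, min_expr: float = 64.0) -> GeneSet:
    """Genes expressed above ``min_expr`` RPM in every cell (strict >)."""
    if m.unit_tag != "rpm":
        raise ValueError(f"select_constitutive_genes expects rpm, got {m.unit_tag!r}")
    keep = m.values.min(axis=0) > min_expr
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    if not genes:
        warnings.warn("no constitutive genes found; fine normalization will be skipped")
    return GeneSet(genes, provenance=f"min expression > {min_expr:g} RPM in all cells")


def default_reference_cell(m: ExpressionMatrix) -> str:
    """Cell whose total is the median total (anchor for pairwise matching)."""
    totals = m.values.sum(axis=1)
    order = np.argsort(totals, kind="stable")
    return m.cell_ids[order[len(order) // 2]]


def fine_normalize(
    m: ExpressionMatrix,
    constitutive: GeneSet,
    reference: str | None = None,
    method: str = "median",
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Remove residual depth offsets by matching constitutive genes pairwise.

    Each cell is multiplied by ``2**(-offset)`` where ``offset`` is the median
    (or, with ``method='lsq'``, the mean) over constitutive genes of
    ``log2(cell) - log2(reference)``.  Afterwards the median log2 ratio of
    constitutive genes against the reference is 0 for every cell.  The median
    objective is robust to a minority of genuinely differential genes.
    """
    if m.unit_tag != "rpm":
        raise ValueError(f"fine_normalize expects rpm, got {m.unit_tag!r}")
    if len(constitutive) == 0:
        warnings.warn("empty constitutive gene set; returning input unchanged")
        return m.with_values(m.values.copy()), NormalizationReport(
            fine_factor={c: 1.0 for c in m.cell_ids}, constitutive_genes=constitutive
        )
    if reference is None:
        reference = default_reference_cell(m)
    if reference not in m.cell_ids:
        raise ValueError(f"reference cell {reference!r} not in matrix")
    gi = m.gene_index(list(constitutive))
    logv = np.log2(np.maximum(m.values[:, gi], 1e-300))
    ref_row = logv[m.cell_index([reference])[0]]
    delta = logv - ref_row[None, :]
    if method == "median":
        offsets = np.median(delta, axis=1)
    elif method == "lsq":
        offsets = delta.mean(axis=1)
    else:
        raise ValueError(f"unknown fine method {method!r}")
    factors = 2.0 ** (-offsets)
    out = m.with_values(m.values * factors[:, None], "rpm")
    report = NormalizationReport(
        fine_factor=dict(zip(m.cell_ids, factors.tolist())),
        constitutive_genes=constitutive,
        reference_cell=reference,
    )
    return out, report


def normalize_pipeline(
    m: ExpressionMatrix,
    min_constitutive_rpm: float = 64.0,
    fine_method: str = "median",
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Coarse then fine normalization; returns the RPM matrix and merged report."""
    rpm, rep_c = coarse_normalize(m)
    constitutive = select_constitutive_genes(rpm, min_constitutive_rpm)
    if len(constitutive) == 0:
        rep_c.constitutive_genes = constitutive
        return rpm, rep_c
    fine, rep_f = fine_normalize(rpm, constitutive, method=fine_method)
    rep_f.coarse_factor = rep_c.coarse_factor
    return fine, rep_f
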