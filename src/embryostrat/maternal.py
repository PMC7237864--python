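"""Detection of asymmetrically inherited maternal transcripts.

Before zygotic genome activation, expression differences between cells of one
embryo can only arise from selective inheritance or degradation of maternal
mRNA.  Genes carrying such asymmetry split the cells of a stage into a
high- and a low-expressing category at a sharp gap in the rank-ordered
expression values, and — because embryos develop stereotypically — they do so
by singling out the *same* number of cells in every embryo and the same
cell set across genes.  The module implements that rank-gap bipartition, the
even-sampling filter, the co-segregation enrichment screen, and the exact
combinatorial match probabilities that quantify how unlikely an identical
cell set across independent classifier genes is under random sampling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .matrix import CellAnnotation, ExpressionMatrix, GeneSet, clip_and_log, group_by_embryo

__all__ = [
    "Bipartition",
    "MaternalFactorReport",
    "rank_gap_split",
    "find_asymmetric_genes",
    "consensus_singled_cells",
    "cosegregation_enrichment",
    "n_combinations",
    "subset_match_probability",
]


@dataclass
class Bipartition:
    """A two-category split of cells at the largest rank gap of one gene."""

    high_cells: frozenset[str]
    low_cells: frozenset[str]
    gap: float
    gene_id: str = ""
    tie: bool = False

    def __post_init__(self) -> None:
        if self.high_cells & self.low_cells:
            raise ValueError("high and low cell sets overlap")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")


@dataclass
class MaternalFactorReport:
    """Classifier genes, the consensus singled-cell set, and enrichment hits."""

    classifier_genes: GeneSet
    singled_cells: frozenset[str]
    enriched_genes: GeneSet
    per_embryo_counts: dict[str, int] = field(default_factory=dict)
    rejected_genes: list[str] = field(default_factory=list)


def rank_gap_split(values: dict[str, float] | Sequence[float], cell_ids: Sequence[str] | None = None,
                   gene_id: str = "") -> Bipartition:
    """Split cells at the single largest difference between consecutive ranks.

    ``values`` are per-cell log2 expression levels, either as a mapping
    cell_id -> value or as a vector paired with ``cell_ids``.  Ties for the
    largest gap are broken toward the split yielding the smaller high set.
    """
    if isinstance(values, dict):
        cell_ids = list(values.keys())
        vec = np.array([values[c] for c in cell_ids], dtype=float)
    else:
        vec = np.asarray(values, dtype=float)
        if cell_ids is None:
            cell_ids = [str(i) for i in range(len(vec))]
    if len(vec) < 2:
        raise ValueError("need at least 2 cells to split")
    if np.ptp(vec) == 0:
        raise ValueError("constant expression vector cannot be split")
    order = np.argsort(vec, kind="stable")
    sorted_v = vec[order]
    diffs = np.diff(sorted_v)
    best = diffs.max()
    # ties broken toward the smaller high set, i.e. the latest gap position
    candidates = np.flatnonzero(diffs == best)
    idx = int(candidates[-1])
    tie = len(candidates) > 1
    low = frozenset(cell_ids[i] for i in order[: idx + 1])
    high = frozenset(cell_ids[i] for i in order[idx + 1 :])
    return Bipartition(high, low, float(best), gene_id=gene_id, tie=tie)


def _even_sampling(
    split: Bipartition, embryos: dict[str, list[str]], stage: int
) -> bool:
    """True when the singled-out (minority) category samples embryos evenly.

    Asymmetric inheritance is reproducible across embryos: every embryo must
    contribute its share of the singled-out cells.  Counts are rescaled by
    embryo completeness (observed cells / stage) so an embryo with a dropped
    cell is not penalized; the rescaled minority counts must be positive in
    every embryo and spread by at most 1.  This rejects single-outlier
    splits (one embryo singled, the rest empty) that a pure spread rule
    would admit.
    """
    minority = min(split.high_cells, split.low_cells, key=len)
    scaled = []
    for cells in embryos.values():
        completeness = len(cells) / stage
        count = len(minority & set(cells))
        if count == 0:
            return False
        scaled.append(count / completeness)
    return (max(scaled) - min(scaled)) <= 1.0 + 1e-9


def find_asymmetric_genes(
    m: ExpressionMatrix,
    ann: Sequence[CellAnnotation],
    max_expr_min: float = 16.0,
    fold_min: float = 4.0,
    clip_floor: float = 1.0,
) -> list[Bipartition]:
    """Screen all genes of one stage for an even, sharp two-category split.

    Candidate genes need maximal expression above ``max_expr_min`` RPM in at
    least one cell and at least ``fold_min``-fold difference between cells
    (after clipping at ``clip_floor`` RPM).  Each candidate is split at its
    largest rank gap; the split is retained only if it samples individual
    embryos evenly.
    """
    if m.unit_tag != "rpm":
        raise ValueError(f"find_asymmetric_genes expects rpm input, got {m.unit_tag!r}")
    stages = {a.stage for a in ann}
    if len(stages) != 1:
        raise ValueError(f"cells must come from embryos of one stage, got {sorted(stages)}")
    stage = stages.pop()
    embryos = group_by_embryo(ann)
    sub = m.subset(cells=[a.cell_id for a in ann])
    logm = clip_and_log(sub, floor=clip_floor)
    clipped = np.maximum(sub.values, clip_floor)
    maxed = sub.values.max(axis=0) > max_expr_min
    fold = clipped.max(axis=0) / clipped.min(axis=0)
    candidates = np.flatnonzero(maxed & (fold >= fold_min))
    out: list[Bipartition] = []
    for gi in candidates:
        split = rank_gap_split(logm.values[:, gi], logm.cell_ids, gene_id=logm.gene_ids[gi])
        if _even_sampling(split, embryos, stage):
            out.append(split)
    return out


def consensus_singled_cells(
    splits: Sequence[Bipartition], ann: Sequence[CellAnnotation]
) -> MaternalFactorReport:
    """Keep the largest group of genes that single out an identical cell set.

    Genes whose high set differs from the consensus are rejected, mirroring
    the requirement that independent classifier genes agree exactly.
    """
    if not splits:
        return MaternalFactorReport(GeneSet([], "consensus classifiers"), frozenset(), GeneSet([], "enriched"))
    groups: dict[frozenset[str], list[str]] = {}
    for s in splits:
        groups.setdefault(s.high_cells, []).append(s.gene_id)
    consensus = max(groups, key=lambda k: (len(groups[k]), sorted(groups[k])))
    classifier = sorted(groups[consensus])
    rejected = sorted(g for k, gs in groups.items() if k != consensus for g in gs)
    per_embryo = {
        e: len(consensus & set(cells)) for e, cells in group_by_embryo(ann).items()
    }
    return MaternalFactorReport(
        classifier_genes=GeneSet(classifier, "consensus classifiers"),
        singled_cells=consensus,
        enriched_genes=GeneSet([], "not computed"),
        per_embryo_counts=per_embryo,
        rejected_genes=rejected,
    )


def cosegregation_enrichment(
    m: ExpressionMatrix,
    singled: Iterable[str],
    ann: Sequence[CellAnnotation],
    clip_floor: float = 1.0,
) -> GeneSet:
    """Genes enriched in the singled-out cells of *every* embryo.

    Enrichment per embryo is the ratio of mean clipped-log2 expression in the
    singled cells over all other cells of that embryo; a gene qualifies only
    with ratio > 1 in every embryo that contains singled cells.
    """
    if m.unit_tag != "rpm":
        raise ValueError(f"cosegregation_enrichment expects rpm input, got {m.unit_tag!r}")
    singled = set(singled)
    embryos = group_by_embryo(ann)
    spanned = [e for e, cells in embryos.items() if singled & set(cells)]
    if len(spanned) < 2:
        raise ValueError("singled cells must span at least 2 embryos")
    logm = clip_and_log(m.subset(cells=[a.cell_id for a in ann]), floor=clip_floor)
    enriched = np.ones(logm.n_genes, dtype=bool)
    for e, cells in embryos.items():
        cells = set(cells)
        hi = sorted(cells & singled)
        lo = sorted(cells - singled)
        if not hi:
            warnings.warn(f"embryo {e!r} has no singled cell; skipped")
            continue
        if not lo:
            warnings.warn(f"embryo {e!r} has only singled cells; skipped")
            continue
        mean_hi = logm.values[logm.cell_index(hi), :].mean(axis=0)
        mean_lo = logm.values[logm.cell_index(lo), :].mean(axis=0)
        enriched &= mean_hi > mean_lo
    genes = [g for g, k in zip(logm.gene_ids, enriched) if k]
    return GeneSet(genes, provenance="enriched in singled cells in every embryo")


# ---------------------------------------------------------------------------
# Exact combinatorics
# ---------------------------------------------------------------------------

def n_combinations(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k) as an arbitrary-precision integer."""
    if k < 0 or k > n:
        raise ValueError(f"require 0 <= k <= n, got n={n}, k={k}")
    return math.comb(n, k)


def subset_match_probability(n: int, sizes: Iterable[int]) -> float:
    """Probability that a uniform random subset of a size in ``sizes`` equals
    a fixed subset of that size: sum over k of 1 / C(n, k).

    Quantifies how unlikely it is for independent classifier genes to single
    out exactly the same k (or k') cells out of n by chance.
    """
    total = Fraction(0)
    for k in set(sizes):
        total += Fraction(1, n_combinations(n, k))
    return float(total)
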