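"""SCECTION: recursive cell-type discovery by 2-metaprofile NMF consensus.

The embryo's cells are recursively bipartitioned.  At each node, genes with a
16-fold expression difference within the current cell subset are selected,
expression is clipped at 1 RPM, log2-transformed and standardized per gene,
and 50 independent two-metaprofile non-negative matrix factorizations are
run.  Each run assigns every cell to the metaprofile with the larger
coefficient; averaging the runs' co-assignment indicators yields a consensus
matrix.  The subset is split along the consensus only when the mean
within-cluster consensus exceeds a threshold (default 0.75); recursion stops
on poor consensus, on an empty differential gene set, or on subsets too small
to split.  Cross-embryo type matching and a chi-square classifier-gene
validation complete the module.

NMF needs non-negative input while standardization produces negatives; each
gene is therefore shifted by its minimum over the subset after z-scoring — a
rank-preserving, per-gene offset.  A flag switches to factorizing clipped-log
values without z-scoring instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

from sklearn.decomposition import NMF

from .matrix import (
    CellAnnotation,
    ExpressionMatrix,
    GeneSet,
    clip_and_log,
    group_by_embryo,
    zscore_genes,
)

__all__ = [
    "ConsensusMatrix",
    "CellTypePartition",
    "Scection",
    "ScectionResults",
    "filter_split_genes",
    "nmf_consensus_split",
    "consensus_nmf",
    "scection",
    "match_cell_types_across_embryos",
    "validate_classifier_genes",
]


@dataclass
class ConsensusMatrix:
    """Cells x cells average co-assignment over repeated clustering runs."""

    values: np.ndarray
    cell_ids: list[str]
    run_count: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T):
            raise ValueError("consensus matrix must be symmetric")
        if np.any(v < 0) or np.any(v > 1 + 1e-12):
            raise ValueError("consensus entries must lie in [0, 1]")
        self.values = v


@dataclass
class SplitRecord:
    """Provenance of one recursive split (or refusal to split)."""

    path: str
    cells: list[str]
    genes: GeneSet
    consensus_score: float
    accepted: bool
    stop_reason: str | None = None


@dataclass
class CellTypePartition:
    """Recursive assignment of cells to hierarchical type labels.

    Labels are slash-joined split paths ("0/1/0"); a label's prefix is its
    parent split.  Cells of an unsplit embryo all carry the root label "".
    """

    assignment: dict[str, str]
    splits: list[SplitRecord] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def cells_of(self, label: str) -> list[str]:
        return [c for c, l in self.assignment.items() if l == label]

    def n_types(self) -> int:
        return len(set(self.assignment.values()))


def filter_split_genes(
    m: ExpressionMatrix,
    cells: Sequence[str],
    max_expr_min: float = 4.0,
    fold_min: float = 16.0,
    clip_floor: float = 1.0,
) -> GeneSet:
    """Genes able to drive a split: max > 4 RPM in the subset and >= 16-fold
    difference within the subset after clipping at 1 RPM."""
    if m.unit_tag != "rpm":
        raise ValueError(f"filter_split_genes expects rpm input, got {m.unit_tag!r}")
    if len(cells) < 2:
        raise ValueError("need at least 2 cells")
    sub = m.subset(cells=cells)
    clipped = np.maximum(sub.values, clip_floor)
    keep = (sub.values.max(axis=0) > max_expr_min) & (
        clipped.max(axis=0) / clipped.min(axis=0) >= fold_min
    )
    return GeneSet(
        [g for g, k in zip(sub.gene_ids, keep) if k],
        provenance=f"max > {max_expr_min:g} RPM and >= {fold_min:g}-fold in subset",
    )


def _prepare_split_matrix(
    m: ExpressionMatrix, cells: Sequence[str], genes: GeneSet, zscore: bool = True
) -> np.ndarray:
    """Clip / log2 / (optionally) z-score then shift non-negative per gene."""
    logm = clip_and_log(m.subset(cells=cells, genes=list(genes)))
    if zscore:
        z, _ = zscore_genes(logm)
        vals = z.values
    else:
        vals = logm.values
    return vals - vals.min(axis=0, keepdims=True)


def consensus_nmf(
    values: np.ndarray,
    cell_ids: Sequence[str],
    k: int = 2,
    runs: int = 100,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    beta_loss: str = "kullback-leibler",
) -> tuple[ConsensusMatrix, np.ndarray]:
    """Average connectivity matrix over repeated k-metaprofile NMF runs.

    Each run factorizes the non-negative cells x genes matrix by
    multiplicative updates with random initialization (per-run seed = base
    seed + run index) and assigns each cell to the metaprofile with the
    largest coefficient.  The default objective is the generalized
    Kullback-Leibler divergence of the classic consensus-NMF formulation,
    which on block-structured expression data converges to the block
    factorization from essentially any initialization; the Euclidean
    (Frobenius) objective is available via ``beta_loss`` but is prone to
    local optima that split the dominant block.  Runs that leave a
    metaprofile empty are re-initialized with a fresh seed; after ``10*runs``
    total attempts the factorization is declared degenerate.  Returns the
    consensus matrix and the final k-cluster labels read out by average-
    linkage clustering of (1 - consensus).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < k:
        raise ValueError(f"cannot split {n} cells into {k} clusters")
    if np.any(values < 0):
        raise ValueError("NMF input must be non-negative")
    connectivity = np.zeros((n, n))
    completed = 0
    attempts = 0
    next_seed = int(seed)
    while completed < runs:
        if attempts >= 10 * runs:
            raise RuntimeError(
                f"NMF consensus failed: {attempts} attempts for {runs} non-degenerate runs"
            )
        attempts += 1
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss=beta_loss,
            max_iter=max_iter,
            tol=tol,
            random_state=next_seed % (2**31),
        )
        next_seed += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # max_iter convergence warnings
            w = model.fit_transform(values)
        labels = np.argmax(w, axis=1)
        if len(np.unique(labels)) < k:
            continue  # degenerate run: re-initialize
        connectivity += labels[:, None] == labels[None, :]
        completed += 1
    consensus = connectivity / runs
    np.fill_diagonal(consensus, 1.0)
    cm = ConsensusMatrix(consensus, list(cell_ids), runs)
    dist = ssd.squareform(1.0 - consensus, checks=False)
    link = sch.linkage(dist, method="average")
    final = sch.fcluster(link, t=k, criterion="maxclust") - 1
    return cm, final


def _within_cluster_consensus(consensus: np.ndarray, labels: np.ndarray) -> float:
    """Mean consensus entry over within-cluster pairs (off-diagonal)."""
    total = 0.0
    count = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        block = consensus[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        total += block[iu].sum()
        count += len(iu[0])
    return total / count if count else 0.0


def nmf_consensus_split(
    m: ExpressionMatrix,
    cells: Sequence[str],
    genes: GeneSet,
    runs: int = 50,
    seed: int = 0,
    zscore: bool = True,
) -> tuple[ConsensusMatrix, dict[str, int], float]:
    """One SCECTION split: consensus 2-metaprofile NMF on a prepared subset.

    Returns the consensus matrix, the cell -> {0, 1} assignment and the
    consensus score (mean within-cluster consensus of the final 2-cluster
    call).  Cluster 0 is the cluster containing the lexicographically
    smallest cell id, making labels independent of input order.
    """
    if len(cells) < 3:
        raise ValueError("need at least 3 cells to attempt a consensus split")
    if len(genes) < 1:
        raise ValueError("need at least one split gene")
    values = _prepare_split_matrix(m, cells, genes, zscore=zscore)
    cm, labels = consensus_nmf(values, cells, k=2, runs=runs, seed=seed)
    score = _within_cluster_consensus(cm.values, labels)
    anchor = min(range(len(cells)), key=lambda i: cells[i])
    if labels[anchor] != 0:
        labels = 1 - labels
    return cm, dict(zip(cells, labels.tolist())), float(score)


def scection(
    m: ExpressionMatrix,
    cells: Sequence[str],
    consensus_threshold: float = 0.75,
    runs: int = 50,
    seed: int = 0,
    min_split_size: int = 3,
    zscore: bool = True,
    max_expr_min: float = 4.0,
    fold_min: float = 16.0,
) -> CellTypePartition:
    """Recursive consensus-NMF bipartitioning of one embryo's cells."""
    assignment: dict[str, str] = {}
    records: list[SplitRecord] = []

    def recurse(subset: list[str], path: str) -> None:
        subset = sorted(subset)
        if len(subset) < min_split_size:
            _leaf(subset, path, "subset below minimum split size")
            return
        genes = filter_split_genes(m, subset, max_expr_min=max_expr_min, fold_min=fold_min)
        if len(genes) == 0:
            _leaf(subset, path, "no differential gene")
            return
        node_seed = _node_seed(seed, path)
        cm, labels, score = nmf_consensus_split(
            m, subset, genes, runs=runs, seed=node_seed, zscore=zscore
        )
        if score <= consensus_threshold:
            records.append(SplitRecord(path, subset, genes, score, False, "consensus below threshold"))
            for c in subset:
                assignment[c] = path
            return
        records.append(SplitRecord(path, subset, genes, score, True))
        side0 = [c for c in subset if labels[c] == 0]
        side1 = [c for c in subset if labels[c] == 1]
        recurse(side0, _child(path, "0"))
        recurse(side1, _child(path, "1"))

    def _leaf(subset: list[str], path: str, reason: str) -> None:
        records.append(SplitRecord(path, subset, GeneSet([], "leaf"), float("nan"), False, reason))
        for c in subset:
            assignment[c] = path

    recurse(list(cells), "")
    return CellTypePartition(assignment, records)


def _child(path: str, bit: str) -> str:
    return bit if path == "" else f"{path}/{bit}"


def _node_seed(base: int, path: str) -> int:
    """Stable per-node seed: mix the base seed with the split path."""
    h = int(base) & 0x7FFFFFFF
    for ch in path:
        h = (h * 1000003 + ord(ch) + 1) & 0x7FFFFFFF
    return h


# ---------------------------------------------------------------------------
# Model / Results wrapper
# ---------------------------------------------------------------------------

class Scection:
    """Recursive NMF-consensus cell-type model for one embryo.

    Parameters
    ----------
    matrix
        RPM expression matrix containing (at least) the embryo's cells.
    cells
        The embryo's cell ids; defaults to all cells of the matrix.
    consensus_threshold, runs, min_split_size
        Stopping rule and consensus parameters of the recursion.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        cells: Sequence[str] | None = None,
        consensus_threshold: float = 0.75,
        runs: int = 50,
        min_split_size: int = 3,
        zscore: bool = True,
    ):
        self.matrix = matrix
        self.cells = list(cells) if cells is not None else list(matrix.cell_ids)
        self.consensus_threshold = consensus_threshold
        self.runs = runs
        self.min_split_size = min_split_size
        self.zscore = zscore

    def fit(self, seed: int = 0) -> "ScectionResults":
        partition = scection(
            self.matrix,
            self.cells,
            consensus_threshold=self.consensus_threshold,
            runs=self.runs,
            seed=seed,
            min_split_size=self.min_split_size,
            zscore=self.zscore,
        )
        return ScectionResults(self, partition, seed)


class ScectionResults:
    """Fitted SCECTION partition with per-split provenance."""

    def __init__(self, model: Scection, partition: CellTypePartition, seed: int):
        self.model = model
        self.partition = partition
        self.seed = seed

    @property
    def n_types(self) -> int:
        return self.partition.n_types()

    def type_sizes(self) -> dict[str, int]:
        return {lab: len(self.partition.cells_of(lab)) for lab in self.partition.labels}

    def summary(self) -> str:
        lines = [
            "SCECTION cell-type partition",
            f"  cells: {len(self.model.cells)}   types: {self.n_types}   seed: {self.seed}",
            f"  consensus threshold: {self.model.consensus_threshold}   runs per split: {self.model.runs}",
            "  splits:",
        ]
        for rec in self.partition.splits:
            path = rec.path or "(root)"
            if rec.accepted:
                lines.append(
                    f"    {path}: split {len(rec.cells)} cells on {len(rec.genes)} genes, "
                    f"consensus {rec.consensus_score:.3f}"
                )
            else:
                why = rec.stop_reason or "stopped"
                score = "" if np.isnan(rec.consensus_score) else f" (consensus {rec.consensus_score:.3f})"
                lines.append(f"    {path}: leaf of {len(rec.cells)} cells — {why}{score}")
        lines.append("  leaf sizes: " + ", ".join(
            f"{lab or '(root)'}={n}" for lab, n in sorted(self.type_sizes().items())
        ))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Cross-embryo matching
# ---------------------------------------------------------------------------

def _type_profiles(
    m: ExpressionMatrix, partition: CellTypePartition, cells: Sequence[str]
) -> dict[str, np.ndarray]:
    """Mean clipped-log2 profile per leaf type of one embryo."""
    logm = clip_and_log(m.subset(cells=cells))
    out = {}
    for lab in partition.labels:
        members = [c for c in partition.cells_of(lab) if c in set(cells)]
        out[lab] = logm.values[logm.cell_index(members), :].mean(axis=0)
    return out


def match_cell_types_across_embryos(
    partitions: dict[str, CellTypePartition],
    m: ExpressionMatrix,
    ann: Sequence[CellAnnotation],
    genes: GeneSet | None = None,
):
    """Match per-embryo cell types into canonical types across embryos.

    Profiles are computed on the classification-associated genes — by
    default the union of the split genes recorded in the partitions'
    provenance (all genes only as a last resort) — then standardized
    gene-wise within each embryo (removing embryo-specific trends).  All
    (embryo, type) profiles are clustered by average linkage on Euclidean
    distance and the tree is cut at the largest per-embryo type count.
    Types supported by only a single embryo are merged back into their
    sibling type from the last split (or the closest type of that embryo),
    and matching repeats until every canonical type is seen in at least two
    embryos.

    Returns ``(mapping, table)`` where ``mapping[(embryo, type)] ->``
    canonical label and ``table`` is a DataFrame of per-embryo cell counts
    per canonical type.
    """
    import pandas as pd

    if genes is None:
        union: set[str] = set()
        for p in partitions.values():
            for rec in p.splits:
                union |= set(rec.genes)
        if union:
            genes = GeneSet(sorted(union), provenance="union of split genes")
        else:
            warnings.warn("no split-gene provenance; matching on all genes")
    if genes is not None and len(genes):
        m = m.subset(genes=list(genes))

    embryos = group_by_embryo(ann)
    if len(partitions) == 1:
        warnings.warn("single embryo: identity type mapping")
        (e, part), = partitions.items()
        mapping = {(e, lab): f"T{i}" for i, lab in enumerate(part.labels)}
        table = pd.DataFrame(
            {e: {mapping[(e, lab)]: len(part.cells_of(lab)) for lab in part.labels}}
        ).fillna(0).astype(int)
        return mapping, table

    # working copy of per-embryo partitions (labels may be merged below)
    work = {e: dict(p.assignment) for e, p in partitions.items()}

    for _ in range(64):  # merge loop; bounded
        keys: list[tuple[str, str]] = []
        profiles: list[np.ndarray] = []
        for e, assign in work.items():
            cells = embryos[e]
            labs = sorted(set(assign.values()))
            logm = clip_and_log(m.subset(cells=cells))
            prof = np.stack([
                logm.values[logm.cell_index([c for c in cells if assign[c] == lab]), :].mean(axis=0)
                for lab in labs
            ])
            # standardize each gene across this embryo's type profiles
            mu = prof.mean(axis=0)
            sd = prof.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            prof = (prof - mu) / sd
            for lab, row in zip(labs, prof):
                keys.append((e, lab))
                profiles.append(row)
        X = np.stack(profiles)
        k = max(len(set(a.values())) for a in work.values())
        if len(keys) <= k or k == 1:
            clusters = np.zeros(len(keys), dtype=int)
        else:
            link = sch.linkage(X, method="average", metric="euclidean")
            clusters = sch.fcluster(link, t=k, criterion="maxclust") - 1

        # find canonical clusters supported by a single embryo
        lonely: list[tuple[str, str]] = []
        for cl in np.unique(clusters):
            members = [keys[i] for i in np.flatnonzero(clusters == cl)]
            if len({e for e, _ in members}) == 1 and len(work) > 1:
                lonely.extend(members)
        if not lonely:
            break
        # merge each lonely type into its sibling within the same embryo
        for e, lab in lonely:
            assign = work[e]
            labs = set(assign.values())
            if len(labs) == 1:
                continue
            sibling = _sibling_label(lab, labs)
            for c, l in assign.items():
                if l == lab:
                    assign[c] = sibling
    mapping = {}
    for cl in np.unique(clusters):
        for i in np.flatnonzero(clusters == cl):
            mapping[keys[i]] = f"T{cl}"
    table = pd.DataFrame(0, index=sorted({f"T{c}" for c in clusters}), columns=sorted(work))
    for (e, lab), canon in mapping.items():
        table.loc[canon, e] += sum(1 for l in work[e].values() if l == lab)
    return mapping, table


def _sibling_label(lab: str, labels: set[str]) -> str:
    """Sibling of ``lab`` from its last split; falls back to longest shared prefix."""
    parts = lab.split("/")
    if parts[-1] in ("0", "1"):
        sib_leaf = parts[:-1] + ["1" if parts[-1] == "0" else "0"]
        prefix = "/".join(sib_leaf)
        matches = [l for l in labels if l == prefix or l.startswith(prefix + "/")]
        if matches:
            return min(matches, key=len)
    others = [l for l in labels if l != lab]
    return max(others, key=lambda l: _shared_prefix(l, lab))


def _shared_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a.split("/"), b.split("/")):
        if x != y:
            break
        n += 1
    return n


# ---------------------------------------------------------------------------
# Classifier-gene validation
# ---------------------------------------------------------------------------

def validate_classifier_genes(
    candidates: GeneSet,
    m: ExpressionMatrix,
    reference_cells: set[str],
    ann: Sequence[CellAnnotation] | None = None,
    alpha: float = 0.05,
):
    """Chi-square validation of candidate classifier genes with BH correction.

    Each candidate's rank-gap bipartition over all cells is compared with the
    reference bipartition (e.g. the maternal-factor-high cells) in a 2x2
    contingency table.  Genes whose Benjamini-Hochberg adjusted p-value falls
    below ``alpha`` survive; the direction (association sign) and whether an
    exact-test fallback fired (any expected count < 1) are reported.

    Returns ``(surviving GeneSet, DataFrame of per-gene statistics)``.
    """
    import pandas as pd

    from .maternal import rank_gap_split

    if m.unit_tag != "rpm":
        raise ValueError(f"validate_classifier_genes expects rpm input, got {m.unit_tag!r}")
    logm = clip_and_log(m)
    rows = []
    for g in candidates:
        vec = logm.gene_vector(g)
        try:
            split = rank_gap_split(vec, logm.cell_ids, gene_id=g)
        except ValueError:
            rows.append((g, np.nan, np.nan, "constant", False))
            continue
        in_high = np.array([c in split.high_cells for c in logm.cell_ids])
        in_ref = np.array([c in reference_cells for c in logm.cell_ids])
        table = np.array(
            [
                [np.sum(in_high & in_ref), np.sum(in_high & ~in_ref)],
                [np.sum(~in_high & in_ref), np.sum(~in_high & ~in_ref)],
            ]
        )
        exact = False
        expected = scipy.stats.contingency.expected_freq(table) if table.sum() else None
        if expected is not None and (expected < 1).any():
            exact = True
            _, p = scipy.stats.fisher_exact(table)
            stat = np.nan
        else:
            stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
        direction = "association" if table[0, 0] * table[1, 1] >= table[0, 1] * table[1, 0] else "anti"
        rows.append((g, stat, p, direction, exact))
    df = pd.DataFrame(rows, columns=["gene_id", "chi2", "p", "direction", "exact_fallback"])
    valid = df["p"].notna()
    df["p_adj"] = np.nan
    if valid.any():
        df.loc[valid, "p_adj"] = scipy.stats.false_discovery_control(df.loc[valid, "p"], method="bh")
    survivors = df.loc[df["p_adj"] < alpha, "gene_id"].tolist()
    return GeneSet(survivors, provenance=f"chi2+BH p<{alpha:g} vs reference bipartition"), df
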