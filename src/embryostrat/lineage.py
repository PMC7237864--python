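"""Cell-type lineage tree reconstruction under the cell-count doubling rule.

Between consecutive cleavage stages every cell divides exactly once, so the
cells of each mother type must be accounted for by daughter types whose cell
counts sum to twice the mother's.  Mother-daughter relationships are read
from expression: per-stage standardized mean log profiles are compared by
Euclidean distance and each mother greedily accumulates its closest
unclaimed daughter types until its doubling budget is exactly met — a
parsimony argument minimizing expression change through division.  Single
cells are embedded on local mother-to-daughter axes for visualisation of
developmental progression.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import CellAnnotation, ExpressionMatrix, GeneSet, clip_and_log

__all__ = [
    "StageProfiles",
    "LineageTree",
    "stage_profiles",
    "bulk_gene_filter",
    "match_mother_daughter",
    "build_lineage_tree",
    "reconstruct_lineage_tree",
    "embed_on_lineage",
    "neighbor_ordering",
]


@dataclass
class StageProfiles:
    """Per-type standardized mean log2 profiles and cell counts at one stage."""

    stage: int
    profiles: pd.DataFrame  # types x genes, per-gene standardized
    counts: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(self.profiles.index) - set(self.counts)
        if missing:
            raise ValueError(f"missing cell counts for types: {sorted(missing)}")


def bulk_gene_filter(
    bulk: pd.DataFrame,
    mother_stage: int,
    base_stage: int = 4,
    min_rpm: float = 1.0,
    fold: float = 2.0,
) -> GeneSet:
    """Restrict to genes informative about the mother stage using bulk data:
    max > ``min_rpm`` RPM at the two stages and >= ``fold`` change between the
    base (4-cell) stage and the mother stage.

    ``bulk`` is a stages x genes table of RPM values.
    """
    rows = bulk.loc[[base_stage, mother_stage]]
    clipped = rows.clip(lower=1.0)
    keep = (rows.max(axis=0) > min_rpm) & (
        (clipped.loc[mother_stage] / clipped.loc[base_stage]).combine(
            clipped.loc[base_stage] / clipped.loc[mother_stage], max
        )
        >= fold
    )
    return GeneSet(list(rows.columns[keep]), provenance=f"bulk {fold}-fold {base_stage}->{mother_stage}")


def stage_profiles(
    m: ExpressionMatrix,
    assignments: Mapping[str, str],
    ann: Sequence[CellAnnotation],
    stage: int,
    genes: GeneSet | None = None,
) -> StageProfiles:
    """Per-type mean log2 profiles at one stage, gene-standardized across types.

    Standardizing each gene across the stage's type profiles removes
    stage-specific expression trends; genes constant across types are
    dropped.  ``genes`` optionally restricts to a bulk-informed gene set.
    """
    cells = [a.cell_id for a in ann if a.stage == stage and a.cell_id in assignments]
    if not cells:
        raise ValueError(f"no assigned cells at stage {stage}")
    sub = m.subset(cells=cells, genes=list(genes) if genes is not None else None)
    if genes is None:
        warnings.warn("no bulk gene table given; using all genes")
    logm = clip_and_log(sub)
    labels = sorted({assignments[c] for c in cells})
    counts: dict[str, int] = {}
    rows = []
    for lab in labels:
        members = [c for c in cells if assignments[c] == lab]
        if not members:
            raise ValueError(f"type {lab!r} has zero cells")
        counts[lab] = len(members)
        rows.append(logm.values[logm.cell_index(members), :].mean(axis=0))
    prof = np.stack(rows)
    mu = prof.mean(axis=0)
    sd = prof.std(axis=0, ddof=1) if len(labels) > 1 else np.ones(prof.shape[1])
    keep = sd > 0
    prof = (prof[:, keep] - mu[keep]) / sd[keep]
    df = pd.DataFrame(prof, index=labels, columns=[g for g, k in zip(logm.gene_ids, keep) if k])
    return StageProfiles(stage, df, counts)


def match_mother_daughter(
    mothers: StageProfiles, daughters: StageProfiles
) -> list[tuple[str, str]]:
    """Assign every daughter type to a mother under the doubling budget.

    Distances are Euclidean between standardized profiles on the shared gene
    set.  Mothers are processed most-confident-first (smallest distance to
    any daughter); each accumulates its closest unclaimed daughters until the
    claimed cell counts sum to exactly twice its own.  Equidistant choices
    fall back to lexicographic type order and are logged.
    """
    shared = [g for g in mothers.profiles.columns if g in set(daughters.profiles.columns)]
    if not shared:
        raise ValueError("no shared genes between stage profiles")
    total_m = sum(mothers.counts.values())
    total_d = sum(daughters.counts.values())
    if total_d != 2 * total_m:
        raise ValueError(
            f"daughter cells ({total_d}) must be twice mother cells ({total_m})"
        )
    mp = mothers.profiles[shared]
    dp = daughters.profiles[shared]
    dist = pd.DataFrame(
        np.linalg.norm(mp.to_numpy()[:, None, :] - dp.to_numpy()[None, :, :], axis=2),
        index=mp.index,
        columns=dp.index,
    )
    unclaimed = set(dp.index)
    order = sorted(dist.index, key=lambda mo: (dist.loc[mo].min(), mo))
    edges: list[tuple[str, str]] = []
    for mo in order:
        budget = 2 * mothers.counts[mo]
        # daughters by increasing distance, ties broken lexicographically
        ranked = sorted(unclaimed, key=lambda d: (dist.loc[mo, d], d))
        if len({round(dist.loc[mo, d], 12) for d in ranked}) < len(ranked):
            warnings.warn(f"distance ties while matching daughters of {mo!r}")
        for d in ranked:
            if budget == 0:
                break
            need = daughters.counts[d]
            if need <= budget:
                edges.append((mo, d))
                unclaimed.discard(d)
                budget -= need
        if budget != 0:
            raise ValueError(
                f"doubling budget unsatisfiable for mother {mo!r}: "
                f"{budget} cells unaccounted; unclaimed daughters: {sorted(unclaimed)}"
            )
    if unclaimed:
        raise ValueError(f"unmatched daughter types: {sorted(unclaimed)}")
    return edges


@dataclass
class LineageTree:
    """Staged cell-type tree with mother->daughter edges and cell counts."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_node(self, stage: int, label: str, n_cells: int, profile=None) -> None:
        self.graph.add_node((stage, label), stage=stage, label=label, n_cells=n_cells, profile=profile)

    def add_edge(self, mother: tuple[int, str], daughter: tuple[int, str]) -> None:
        if self.graph.nodes[daughter]["stage"] <= self.graph.nodes[mother]["stage"]:
            raise ValueError("stages must strictly increase along edges")
        self.graph.add_edge(mother, daughter)

    def validate(self) -> None:
        """Check the doubling invariant and single-mother property globally."""
        for node in self.graph.nodes:
            kids = list(self.graph.successors(node))
            if kids:
                total = sum(self.graph.nodes[k]["n_cells"] for k in kids)
                if total != 2 * self.graph.nodes[node]["n_cells"]:
                    raise ValueError(
                        f"doubling violated at {node}: daughters sum to {total}, "
                        f"expected {2 * self.graph.nodes[node]['n_cells']}"
                    )
        for node in self.graph.nodes:
            if self.graph.in_degree(node) > 1:
                raise ValueError(f"node {node} has more than one mother")

    def roots(self) -> list[tuple[int, str]]:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    def edge_labels(self) -> set[tuple[str, str]]:
        return {(self.graph.nodes[a]["label"], self.graph.nodes[b]["label"]) for a, b in self.graph.edges}

    # -- serialization ---------------------------------------------------
    def to_newick(self) -> str:
        """Newick string; multiple stage-roots are joined under a virtual root."""

        def fmt(node) -> str:
            stage = self.graph.nodes[node]["stage"]
            label = self.graph.nodes[node]["label"]
            n = self.graph.nodes[node]["n_cells"]
            name = f"'{stage}:{label}:{n}'"
            kids = sorted(self.graph.successors(node))
            if not kids:
                return name
            return "(" + ",".join(fmt(k) for k in kids) + ")" + name

        roots = self.roots()
        if len(roots) == 1:
            return fmt(roots[0]) + ";"
        return "(" + ",".join(fmt(r) for r in roots) + ")'virtual_root';"

    def to_json(self) -> str:
        nodes = [
            {"stage": d["stage"], "label": d["label"], "n_cells": d["n_cells"]}
            for _, d in sorted(self.graph.nodes(data=True))
        ]
        edges = [
            {"mother": list(a), "daughter": list(b)} for a, b in sorted(self.graph.edges)
        ]
        return json.dumps({"nodes": nodes, "edges": edges}, indent=1)


def reconstruct_lineage_tree(
    m: ExpressionMatrix,
    assignments: Mapping[str, str],
    ann: Sequence[CellAnnotation],
    stages: Sequence[int],
    bulk: pd.DataFrame | None = None,
    base_stage: int | None = None,
    min_rpm: float = 1.0,
    fold: float = 2.0,
) -> LineageTree:
    """Full tree reconstruction across consecutive stages.

    For each stage pair, genes are restricted (when a bulk stage x gene
    table is given) to the union of the two stages' developmental filters —
    max > ``min_rpm`` RPM and >= ``fold`` change against the base (4-cell)
    stage — before computing standardized type profiles and matching under
    the doubling budget.  Without a bulk table all genes are used.
    """
    stages = sorted(stages)
    if base_stage is None and bulk is not None:
        base_stage = int(bulk.index.min())
    tree = LineageTree()
    profs: dict[int, StageProfiles] = {}
    for lo, hi in zip(stages, stages[1:]):
        genes = None
        if bulk is not None:
            g_lo = set(bulk_gene_filter(bulk, lo, base_stage, min_rpm, fold))
            g_hi = set(bulk_gene_filter(bulk, hi, base_stage, min_rpm, fold))
            genes = GeneSet(sorted(g_lo | g_hi), provenance=f"bulk union {lo}+{hi}")
        sp_lo = stage_profiles(m, assignments, ann, lo, genes)
        sp_hi = stage_profiles(m, assignments, ann, hi, genes)
        for sp in (sp_lo, sp_hi):
            if sp.stage not in profs:
                profs[sp.stage] = sp
                for lab, n in sp.counts.items():
                    tree.add_node(sp.stage, lab, n)
        for mo, d in match_mother_daughter(sp_lo, sp_hi):
            tree.add_edge((lo, mo), (hi, d))
    tree.validate()
    return tree


def build_lineage_tree(stage_profile_list: Sequence[StageProfiles]) -> LineageTree:
    """Compose mother-daughter matching across all consecutive stage pairs.

    Stages must form a complete doubling series; the resulting tree is
    validated for the doubling invariant at every node.
    """
    ordered = sorted(stage_profile_list, key=lambda s: s.stage)
    tree = LineageTree()
    for sp in ordered:
        for lab, n in sp.counts.items():
            tree.add_node(sp.stage, lab, n)
    for lo, hi in zip(ordered, ordered[1:]):
        if hi.stage != 2 * lo.stage:
            warnings.warn(
                f"stages {lo.stage} -> {hi.stage} are not one cleavage apart; matching anyway"
            )
        for mo, d in match_mother_daughter(lo, hi):
            tree.add_edge((lo.stage, mo), (hi.stage, d))
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Local lineage embedding
# ---------------------------------------------------------------------------

def embed_on_lineage(
    cell_profile: np.ndarray,
    mother_mean: np.ndarray,
    daughter_mean: np.ndarray,
    normalized: bool = False,
) -> float:
    """Progression of a cell from its mother toward its daughter type.

    The scalar projection of (cell - mother) on the unit vector from mother
    to daughter mean; with ``normalized=True`` the daughter mean sits at 1.
    """
    axis = np.asarray(daughter_mean, dtype=float) - np.asarray(mother_mean, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("mother and daughter profiles coincide: zero-length axis")
    proj = float((np.asarray(cell_profile, dtype=float) - mother_mean) @ axis / norm)
    return proj / norm if normalized else proj


def neighbor_ordering(profiles: np.ndarray, cell_ids: Sequence[str] | None = None) -> dict[str, float]:
    """Second local coordinate: nearest-neighbour chain order among cells.

    Starting from the cell farthest from the centroid, repeatedly steps to
    the nearest unvisited cell (Euclidean distance); returns the normalized
    rank along the chain in [0, 1].
    """
    X = np.asarray(profiles, dtype=float)
    n = X.shape[0]
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n)]
    if n == 1:
        return {cell_ids[0]: 0.0}
    centroid = X.mean(axis=0)
    current = int(np.argmax(np.linalg.norm(X - centroid, axis=1)))
    visited = [current]
    remaining = set(range(n)) - {current}
    while remaining:
        dists = {j: np.linalg.norm(X[current] - X[j]) for j in remaining}
        current = min(remaining, key=lambda j: (dists[j], j))
        visited.append(current)
        remaining.discard(current)
    return {cell_ids[j]: rank / (n - 1) for rank, j in enumerate(visited)}
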