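"""Synthetic stereotyped-embryo datasets with planted ground truth.

The generator emulates the statistical structure of early ascidian-style
embryos as seen by deep per-embryo scRNA-seq:

* a fixed, bilaterally symmetric cell-type lineage tree in which every cell
  divides once per stage (cell counts double; at the 16-cell stage the tree
  has 5 types of sizes 4+4+4+2+2);
* a transcriptionally silent germ lineage that inherits a fixed set of
  maternal transcripts, whose concentration scales inversely with cell
  volume (total maternal mRNA number per embryo is constant) and whose
  divisions are volume-asymmetric;
* zygotic marker genes per type that ramp linearly in log2 expression after
  a per-gene onset time, shared "pole" programs for the animal and vegetal
  hemispheres, and smooth anterior-posterior gradient genes;
* spurious low-level marker expression in a fraction of marker-negative
  cells, roughly ten-fold below the on level;
* constitutive and background genes filling the library to realistic totals;
* spliced/unspliced count pairs consistent with a per-gene degradation rate
  (u = gamma * s at steady state, exceeded during induction);
* negative-binomial count noise on top of log-normal biological noise,
  per-cell sequencing-depth factors, and per-embryo developmental timing
  offsets;
* per-cell geometry (volumes, surfaces, apical contact graph) consistent
  with the planted volume asymmetries.

Cells come in bilateral pairs sharing identical expected profiles, so a
zero-noise configuration reproduces the left/right symmetry exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .matrix import CellAnnotation, ExpressionMatrix
from .morpho import CellGeometry

__all__ = [
    "SeriesConfig",
    "TypeNode",
    "EmbryoTruth",
    "SeriesData",
    "generate_series",
    "simulate_temporal",
    "steady_state_counts",
    "adjusted_rand_index",
    "edge_set_f1",
    "truth_metrics",
]

# ---------------------------------------------------------------------------
# The stereotyped lineage tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeNode:
    """One cell type at one stage of the stereotyped lineage."""

    name: str
    stage: int
    n_cells: int
    parent: str | None
    ap: float  # anterior-posterior position in [-1.25, 1.25]
    pole: str | None  # "animal" / "vegetal" from the 8-cell stage on
    carrier: bool = False  # inherits the maternal factors
    silent: bool = False  # transcriptionally silent (germ lineage / pre-ZGA)


# name, stage, n_cells, parent, ap, pole, carrier, silent
_TREE_SPEC = [
    ("root", 2, 2, None, 0.0, None, True, True),
    ("ant4", 4, 2, "root", -1.0, None, False, True),
    ("post4", 4, 2, "root", 1.0, None, True, True),
    ("a8", 8, 2, "ant4", -1.0, "animal", False, False),
    ("A8", 8, 2, "ant4", -0.6, "vegetal", False, False),
    ("b8", 8, 2, "post4", 0.6, "animal", False, False),
    ("B8", 8, 2, "post4", 1.0, "vegetal", True, False),
    ("a16", 16, 4, "a8", -1.0, "animal", False, False),
    ("A16", 16, 4, "A8", -0.6, "vegetal", False, False),
    ("b16", 16, 4, "b8", 0.6, "animal", False, False),
    ("B1.16", 16, 2, "B8", 0.9, "vegetal", False, False),
    ("B2.16", 16, 2, "B8", 1.2, "vegetal", True, True),  # germ precursor
    ("a32", 32, 8, "a16", -1.0, "animal", False, False),
    ("b32", 32, 8, "b16", 0.6, "animal", False, False),
    ("A1.32", 32, 4, "A16", -0.8, "vegetal", False, False),
    ("A2.32", 32, 4, "A16", -0.4, "vegetal", False, False),
    ("B11.32", 32, 2, "B1.16", 0.8, "vegetal", False, False),
    ("B12.32", 32, 2, "B1.16", 1.0, "vegetal", False, False),
    ("germ32", 32, 2, "B2.16", 1.25, "vegetal", True, True),
    ("B22.32", 32, 2, "B2.16", 1.1, "vegetal", False, False),
    ("a1.64", 64, 8, "a32", -1.1, "animal", False, False),
    ("a2.64", 64, 8, "a32", -0.9, "animal", False, False),
    ("b1.64", 64, 8, "b32", 0.5, "animal", False, False),
    ("b2.64", 64, 8, "b32", 0.7, "animal", False, False),
    ("A11.64", 64, 4, "A1.32", -0.9, "vegetal", False, False),
    ("A12.64", 64, 4, "A1.32", -0.7, "vegetal", False, False),
    ("A21.64", 64, 4, "A2.32", -0.5, "vegetal", False, False),
    ("A22.64", 64, 4, "A2.32", -0.3, "vegetal", False, False),
    ("B111.64", 64, 2, "B11.32", 0.75, "vegetal", False, False),
    ("B112.64", 64, 2, "B11.32", 0.85, "vegetal", False, False),
    ("B12.64", 64, 4, "B12.32", 1.0, "vegetal", False, False),
    ("germ64", 64, 2, "germ32", 1.25, "vegetal", True, True),
    ("B21.64", 64, 2, "germ32", 1.15, "vegetal", False, False),
    ("B22.64", 64, 4, "B22.32", 1.05, "vegetal", False, False),
]


def build_tree() -> dict[str, TypeNode]:
    nodes = {n[0]: TypeNode(*n) for n in _TREE_SPEC}
    # doubling invariant: daughters of every non-terminal node sum to 2x
    for name, node in nodes.items():
        kids = [k for k in nodes.values() if k.parent == name]
        if kids:
            assert sum(k.n_cells for k in kids) == 2 * node.n_cells, name
    return nodes


def _stage_index(stage: int) -> float:
    """Developmental time of a stage on a cleavage-count scale (log2 cells)."""
    return math.log2(stage)


def _ancestors(nodes: Mapping[str, TypeNode], name: str) -> list[str]:
    out = []
    cur: str | None = name
    while cur is not None:
        out.append(cur)
        cur = nodes[cur].parent
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SeriesConfig:
    """Study conditions of the synthetic series (defaults are the conditions
    every planted-truth test runs under)."""

    stages: tuple[int, ...] = (16,)
    embryos_per_stage: int = 4
    # gene classes
    n_constitutive: int = 200
    n_background: int = 1500
    n_maternal: int = 10
    markers_per_type: int = 5
    pole_genes: int = 25
    n_gradient: int = 20
    # expression levels (log2 RPM relative to the 1 RPM detection floor)
    marker_log2_fold: float = 4.0
    saturation_ratio: float = 1.5  # markers plateau at fold * ratio
    maternal_rpm: float = 64.0  # carrier concentration at the 4-cell stage
    constitutive_log2_range: tuple[float, float] = (7.0, 9.5)
    background_log2_range: tuple[float, float] = (1.0, 8.0)
    gradient_base_log2: float = 3.5
    gradient_amp_log2: float = 1.5
    # noise model
    spurious_fraction: float = 0.1
    spurious_level_ratio: float = 0.1
    noise_sd_log2: float = 0.5  # regulated genes (markers, pole, gradient, maternal)
    background_noise_sd_log2: float = 0.25  # constitutive / background genes
    embryo_effect_sd_log2: float = 0.2  # per-(embryo, gene) oocyte deposition offset
    nb_dispersion: float = 0.1
    depth_log2_range: tuple[float, float] = (-1.0, 1.0)  # log-uniform [0.5, 2]
    total_reads: int = 3_000_000
    # timing
    timing_window: float = 0.3  # per-embryo offset, uniform, in stage units
    pair_time_jitter: float = 0.03
    ap_jitter: float = 0.05
    # velocity
    gamma_log10_range: tuple[float, float] = (-1.7, -0.3)
    induction_u_boost: float = 2.0
    # geometry
    embryo_volume_um3: float = 5.0e5
    germ_sister_volume_ratio: float = 3.0
    # completeness
    cell_dropout: float = 0.0

    def __post_init__(self) -> None:
        nodes = build_tree()
        for s in self.stages:
            present = [n for n in nodes.values() if n.stage == s]
            if not present:
                raise ValueError(f"unsupported stage {s}; choose from 2,4,8,16,32,64")
            if any(n.n_cells % 2 for n in present):
                raise ValueError("odd planted type size violates bilateral symmetry")


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass
class EmbryoTruth:
    """Planted ground truth of a generated series."""

    nodes: dict[str, TypeNode]
    genes: pd.DataFrame  # gene_id, kind, node, pole, fold, alpha, t0, gamma, ...
    cells: pd.DataFrame  # cell_id, embryo_id, stage, type, pair, ap, pole, time, volume, depth
    config: SeriesConfig
    seed: int

    def partition(self, embryo_id: str) -> dict[str, str]:
        """cell_id -> planted type label for one embryo."""
        sub = self.cells[self.cells.embryo_id == embryo_id]
        return dict(zip(sub.cell_id, sub.type))

    def lineage_edges(self) -> set[tuple[str, str]]:
        """Planted mother->daughter type edges between consecutive configured stages."""
        stages = sorted(set(self.config.stages))
        edges = set()
        for s0, s1 in zip(stages, stages[1:]):
            for node in self.nodes.values():
                if node.stage == s1 and node.parent is not None:
                    if self.nodes[node.parent].stage == s0:
                        edges.add((node.parent, node.name))
        return edges

    def carrier_cells(self, stage: int | None = None) -> frozenset[str]:
        sub = self.cells
        if stage is not None:
            sub = sub[sub.stage == stage]
        carriers = {n.name for n in self.nodes.values() if n.carrier}
        return frozenset(sub[sub.type.isin(carriers)].cell_id)

    def maternal_genes(self) -> list[str]:
        return self.genes.loc[self.genes.kind == "maternal", "gene_id"].tolist()

    def type_counts(self, stage: int) -> dict[str, int]:
        return {n.name: n.n_cells for n in self.nodes.values() if n.stage == stage}


@dataclass
class SeriesData:
    """A generated dataset: counts, spliced/unspliced, metadata, geometry, truth."""

    expression: ExpressionMatrix  # raw (spliced) counts
    unspliced: ExpressionMatrix
    annotations: list[CellAnnotation]
    geometry: CellGeometry
    truth: EmbryoTruth

    @property
    def spliced(self) -> ExpressionMatrix:
        return self.expression


# ---------------------------------------------------------------------------
# Gene planting
# ---------------------------------------------------------------------------

def _plant_genes(cfg: SeriesConfig, nodes: Mapping[str, TypeNode], rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    gamma_lo, gamma_hi = cfg.gamma_log10_range

    def gamma() -> float:
        return float(10 ** rng.uniform(gamma_lo, gamma_hi))

    for i in range(cfg.n_constitutive):
        rows.append(dict(gene_id=f"const{i:03d}", kind="constitutive", node=None, pole=None,
                         base_log2=float(rng.uniform(*cfg.constitutive_log2_range)),
                         fold=0.0, alpha=np.nan, t0=np.nan, amp=0.0, gamma=gamma()))
    for i in range(cfg.n_background):
        rows.append(dict(gene_id=f"bg{i:04d}", kind="background", node=None, pole=None,
                         base_log2=float(rng.uniform(*cfg.background_log2_range)),
                         fold=0.0, alpha=np.nan, t0=np.nan, amp=0.0, gamma=gamma()))
    for i in range(cfg.n_maternal):
        rows.append(dict(gene_id=f"mat{i:02d}", kind="maternal", node=None, pole=None,
                         base_log2=float(rng.uniform(-0.5, 0.5)),  # per-gene wobble (log2)
                         fold=0.0, alpha=np.nan, t0=np.nan, amp=0.0, gamma=gamma()))
    marker_nodes = [n for n in nodes.values() if n.stage >= 8 and not n.silent]
    for node in marker_nodes:
        for i in range(cfg.markers_per_type):
            t_on = _stage_index(node.stage)
            t0 = t_on - 1 + float(rng.uniform(0.0, 0.25))
            alpha = cfg.marker_log2_fold / (t_on - t0)
            rows.append(dict(gene_id=f"mk_{node.name}_{i}", kind="marker", node=node.name,
                             pole=None, base_log2=0.0, fold=cfg.marker_log2_fold,
                             alpha=alpha, t0=t0, amp=0.0, gamma=gamma()))
    for pole in ("animal", "vegetal"):
        for i in range(cfg.pole_genes):
            t0 = 3 - 1 + float(rng.uniform(0.0, 0.25))  # zygotic from the 8-cell stage
            alpha = cfg.marker_log2_fold / (3 - t0)
            rows.append(dict(gene_id=f"pole_{pole[:4]}_{i}", kind="pole", node=None,
                             pole=pole, base_log2=0.0, fold=cfg.marker_log2_fold,
                             alpha=alpha, t0=t0, amp=0.0, gamma=gamma()))
    for i in range(cfg.n_gradient):
        amp = cfg.gradient_amp_log2 * (1 if i % 2 == 0 else -1)
        # zygotic: graded expression appears with genome activation (8-cell)
        rows.append(dict(gene_id=f"grad{i:02d}", kind="gradient", node=None, pole=None,
                         base_log2=cfg.gradient_base_log2, fold=0.0,
                         alpha=np.nan, t0=3.0, amp=amp, gamma=gamma()))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cell planting
# ---------------------------------------------------------------------------

def _plant_cells(cfg: SeriesConfig, nodes: Mapping[str, TypeNode], rng: np.random.Generator) -> pd.DataFrame:
    volumes = _cell_volume_per_type(cfg, nodes)
    rows = []
    for stage in cfg.stages:
        t_stage = _stage_index(stage)
        for e in range(cfg.embryos_per_stage):
            embryo_id = f"E{stage}.{e}"
            offset = float(rng.uniform(-cfg.timing_window / 2, cfg.timing_window / 2))
            for node in sorted((n for n in nodes.values() if n.stage == stage), key=lambda n: n.name):
                for p in range(node.n_cells // 2):
                    t_pair = t_stage + offset + float(rng.normal(0, cfg.pair_time_jitter))
                    ap_pair = node.ap + float(rng.normal(0, cfg.ap_jitter))
                    for side in ("L", "R"):
                        rows.append(dict(
                            cell_id=f"{embryo_id}|{node.name}|{p}{side}",
                            embryo_id=embryo_id, stage=stage, type=node.name,
                            pair=f"{embryo_id}|{node.name}|{p}", side=side,
                            ap=ap_pair, pole=node.pole, time=t_pair,
                            offset=offset, volume=volumes[node.name],
                            depth=float(2 ** rng.uniform(*cfg.depth_log2_range)),
                        ))
    df = pd.DataFrame(rows)
    if cfg.cell_dropout > 0:
        keep = rng.random(len(df)) >= cfg.cell_dropout
        df = df[keep].reset_index(drop=True)
    return df


def _cell_volume_per_type(cfg: SeriesConfig, nodes: Mapping[str, TypeNode]) -> dict[str, float]:
    """Per-cell volume by type: equal cleavage except the volume-asymmetric
    germ divisions (carrier daughter smaller by the configured ratio)."""
    r = cfg.germ_sister_volume_ratio
    vol: dict[str, float] = {}
    for node in nodes.values():
        if node.parent is None:
            vol[node.name] = cfg.embryo_volume_um3 / node.n_cells
    # walk stages in order
    for stage in (4, 8, 16, 32, 64):
        for node in nodes.values():
            if node.stage != stage:
                continue
            parent = nodes[node.parent]
            siblings = [k for k in nodes.values() if k.parent == parent.name]
            vp = vol[parent.name]
            if (
                len(siblings) == 2
                and any(s.carrier for s in siblings)
                and not all(s.carrier for s in siblings)
                and parent.carrier
                and parent.stage >= 8
            ):
                # volume-asymmetric germ division
                if node.carrier:
                    vol[node.name] = vp / (1 + r)
                else:
                    vol[node.name] = vp * r / (1 + r)
            else:
                vol[node.name] = vp / 2
    return vol


# ---------------------------------------------------------------------------
# Expected expression
# ---------------------------------------------------------------------------

def _expected_rpm(
    cfg: SeriesConfig,
    nodes: Mapping[str, TypeNode],
    genes: pd.DataFrame,
    cells: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noiseless expected RPM per cell x gene (spurious events drawn here)."""
    n_c, n_g = len(cells), len(genes)
    out = np.zeros((n_c, n_g))
    anc = {name: set(_ancestors(nodes, name)) for name in nodes}
    ctype = cells["type"].to_numpy()
    silent = np.array([nodes[t].silent for t in ctype])
    t_j = cells["time"].to_numpy()
    ap = cells["ap"].to_numpy()
    pole = cells["pole"].to_numpy(dtype=object)
    vol = cells["volume"].to_numpy()
    cap = cfg.marker_log2_fold * cfg.saturation_ratio

    # maternal mass bookkeeping: concentration = (M / n_carriers) / volume,
    # with M fixed so the 4-cell carrier concentration equals cfg.maternal_rpm
    v4 = cfg.embryo_volume_um3 / 4
    carrier_types = {n.name for n in nodes.values() if n.carrier}
    is_carrier = np.array([t in carrier_types for t in ctype])
    # carriers per embryo-stage share the maternal pool
    n_carr = cells.groupby(["embryo_id"])["type"].transform(
        lambda s: s.isin(carrier_types).sum()
    ).to_numpy()

    for gi, g in enumerate(genes.itertuples(index=False)):
        if g.kind in ("constitutive", "background"):
            out[:, gi] = 2.0 ** g.base_log2
        elif g.kind == "maternal":
            m_total = cfg.maternal_rpm * (2 ** g.base_log2) * 2 * v4  # per-embryo mass
            with np.errstate(divide="ignore"):
                conc = np.where(is_carrier & (n_carr > 0), m_total / np.maximum(n_carr, 1) / vol, 0.0)
            out[:, gi] = conc
        elif g.kind in ("marker", "pole"):
            if g.kind == "marker":
                on = np.array([g.node in anc[t] for t in ctype]) & ~silent
            else:
                on = (pole == g.pole) & ~silent
            level = np.clip(g.alpha * (t_j - g.t0), 0.0, cap)
            vals = np.where(on & (level > 0), 2.0 ** np.where(on, level, 0.0), 0.0)
            # spurious low-level expression in a fraction of negative cells
            if cfg.spurious_fraction > 0:
                neg = ~on & ~silent
                hit = neg & (rng.random(n_c) < cfg.spurious_fraction)
                vals = np.where(hit, cfg.spurious_level_ratio * 2.0 ** cfg.marker_log2_fold, vals)
            out[:, gi] = vals
        elif g.kind == "gradient":
            # maternally graded along AP: present in every cell from the egg on
            level = np.clip(g.base_log2 + g.amp * ap, 0.0, None)
            out[:, gi] = 2.0 ** level
        else:  # pragma: no cover
            raise ValueError(g.kind)

    # rescale background genes so an average cell totals ~1e6 RPM
    bg = (genes["kind"] == "background").to_numpy()
    other_total = out[:, ~bg].sum(axis=1).mean()
    bg_total = out[:, bg].sum(axis=1).mean()
    if bg_total > 0 and other_total < 1e6:
        out[:, bg] *= (1e6 - other_total) / bg_total
    return out


def _draw_counts(
    mean_rpm: np.ndarray,
    depth: np.ndarray,
    gene_sd: np.ndarray,
    cfg: SeriesConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Counts from expected RPM: log-normal biological noise (per-gene SD,
    regulated genes noisier than housekeeping ones) then NB sampling.

    With all noise sources switched off the expected counts are returned
    deterministically (noiseless limit)."""
    mean = mean_rpm.copy()
    if np.any(gene_sd > 0):
        mean = mean * 2.0 ** (rng.standard_normal(mean.shape) * gene_sd[None, :])
    lam = mean / 1e6 * (cfg.total_reads * depth)[:, None]
    if cfg.nb_dispersion == 0 and not np.any(gene_sd > 0):
        return lam
    if cfg.nb_dispersion == 0:
        return rng.poisson(lam).astype(float)
    # NB with variance lam + dispersion * lam^2
    n = 1.0 / cfg.nb_dispersion
    p = n / (n + np.maximum(lam, 1e-300))
    counts = np.where(lam > 0, rng.negative_binomial(n, np.clip(p, 1e-12, 1.0)), 0.0)
    return counts.astype(float)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _plant_geometry(cfg: SeriesConfig, nodes: Mapping[str, TypeNode], cells: pd.DataFrame,
                    rng: np.random.Generator) -> CellGeometry:
    volume, surface, apical, perimeter = {}, {}, {}, {}
    contacts: dict[tuple[str, str], float] = {}
    frac = {"animal": 0.40, "vegetal": 0.30, None: 0.35}
    for e, sub in cells.groupby("embryo_id"):
        ordered = sub.sort_values(["ap", "type", "cell_id"])
        ids = ordered.cell_id.tolist()
        for row in ordered.itertuples(index=False):
            v = row.volume
            s = 1.2 * 4.836 * v ** (2 / 3)  # sphere area x shape factor
            node = nodes[row.type]
            f = 0.15 if node.silent and node.stage >= 16 else frac.get(row.pole, 0.35)
            f = max(0.0, min(1.0 / 1.2, f + float(rng.normal(0, 0.02))))
            volume[row.cell_id] = v
            surface[row.cell_id] = s
            apical[row.cell_id] = f * s
            perimeter[row.cell_id] = 2 * math.sqrt(math.pi * max(f * s, 0.0))
        # apical contact ring ordered along the anterior-posterior axis
        for i, c in enumerate(ids):
            nxt = ids[(i + 1) % len(ids)]
            a, b = (c, nxt) if c < nxt else (nxt, c)
            contacts[(a, b)] = float(rng.uniform(5.0, 15.0))
    return CellGeometry(volume, surface, apical, perimeter, contacts)


# ---------------------------------------------------------------------------
# Top-level generation
# ---------------------------------------------------------------------------

def generate_series(config: SeriesConfig | None = None, seed: int = 0) -> SeriesData:
    """Generate a full synthetic series under the configured study conditions.

    Deterministic given (config, seed): repeated calls yield identical data.
    """
    cfg = config or SeriesConfig()
    rng = np.random.default_rng(seed)
    nodes = build_tree()
    genes = _plant_genes(cfg, nodes, rng)
    cells = _plant_cells(cfg, nodes, rng)
    mean_rpm = _expected_rpm(cfg, nodes, genes, cells, rng)

    # per-embryo, per-gene offsets: oocytes differ in deposited mRNA amounts,
    # making within-embryo expression tighter than across embryos
    if cfg.embryo_effect_sd_log2 > 0:
        for e in sorted(cells.embryo_id.unique()):
            rows = (cells.embryo_id == e).to_numpy()
            offs = 2.0 ** rng.normal(0.0, cfg.embryo_effect_sd_log2, size=mean_rpm.shape[1])
            mean_rpm[rows, :] *= offs[None, :]

    depth = cells["depth"].to_numpy()
    gene_sd = np.where(
        genes["kind"].isin(["constitutive", "background"]).to_numpy(),
        cfg.background_noise_sd_log2,
        cfg.noise_sd_log2,
    )
    spliced_counts = _draw_counts(mean_rpm, depth, gene_sd, cfg, rng)

    # unspliced: u = gamma * s at steady state, boosted during induction
    gamma = genes["gamma"].to_numpy()
    u_rpm = mean_rpm * gamma[None, :]
    t_j = cells["time"].to_numpy()
    anc = {name: set(_ancestors(nodes, name)) for name in nodes}
    for gi, g in enumerate(genes.itertuples(index=False)):
        if g.kind not in ("marker", "pole") or not np.isfinite(g.t0):
            continue
        ramp_end = g.t0 + cfg.marker_log2_fold * cfg.saturation_ratio / g.alpha
        inducing = (t_j >= g.t0) & (t_j <= ramp_end)
        if g.kind == "marker":
            on = np.array([g.node in anc[t] for t in cells["type"]])
        else:
            on = (cells["pole"] == g.pole).to_numpy()
        u_rpm[inducing & on, gi] *= cfg.induction_u_boost
    unspliced_counts = _draw_counts(u_rpm, depth, gene_sd, cfg, rng)

    cell_ids = cells.cell_id.tolist()
    gene_ids = genes.gene_id.tolist()
    expression = ExpressionMatrix(spliced_counts, cell_ids, gene_ids, "raw_counts")
    unspliced = ExpressionMatrix(unspliced_counts, cell_ids, gene_ids, "raw_counts")
    ann = [
        CellAnnotation(r.cell_id, r.embryo_id, int(r.stage), r.type)
        for r in cells.itertuples(index=False)
    ]
    geometry = _plant_geometry(cfg, nodes, cells, rng)
    truth = EmbryoTruth(nodes, genes, cells, cfg, seed)
    return SeriesData(expression, unspliced, ann, geometry, truth)


def pseudo_bulk(data: SeriesData) -> pd.DataFrame:
    """Stage x gene table of mean RPM over all cells of each stage.

    Emulates bulk mRNA-seq of staged embryo pools; used by the lineage
    module's developmental gene filter.
    """
    from .normalize import coarse_normalize

    rpm, _ = coarse_normalize(data.expression)
    stage_of = {a.cell_id: a.stage for a in data.annotations}
    df = rpm.to_frame()
    df["__stage"] = [stage_of[c] for c in rpm.cell_ids]
    out = df.groupby("__stage").mean()
    out.index.name = "stage"
    return out


# ---------------------------------------------------------------------------
# Focused simulators for parameter-recovery checks
# ---------------------------------------------------------------------------

def simulate_temporal(
    n_genes: int = 20,
    n_cells: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
    alpha_range: tuple[float, float] = (0.5, 2.0),
    t0_range: tuple[float, float] = (-0.5, 0.5),
    t_range: tuple[float, float] = (-1.0, 1.5),
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Expression from the piecewise-linear onset model x_ij = alpha_i * max(t_j - t0_i, 0).

    Returns the cells x genes matrix plus the planted parameters
    ``{"alpha", "t0", "t"}`` (the model's time units are arbitrary; fits are
    compared up to the affine time gauge)."""
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(*alpha_range, size=n_genes)
    t0 = rng.uniform(*t0_range, size=n_genes)
    t = np.sort(rng.uniform(*t_range, size=n_cells))
    x = alpha[None, :] * np.maximum(t[:, None] - t0[None, :], 0.0)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    return x, {"alpha": alpha, "t0": t0, "t": t}


def steady_state_counts(
    gamma: float,
    n_cells: int = 100,
    noise_cv: float = 0.0,
    seed: int = 0,
    s_log10_range: tuple[float, float] = (0.0, 3.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Spliced/unspliced pairs at degradation steady state u = gamma * s,
    with optional multiplicative noise of the given CV on u."""
    rng = np.random.default_rng(seed)
    s = 10 ** rng.uniform(*s_log10_range, size=n_cells)
    u = gamma * s
    if noise_cv > 0:
        u = u * (1.0 + rng.normal(0.0, noise_cv, size=n_cells))
    return u, s


# ---------------------------------------------------------------------------
# Truth metrics
# ---------------------------------------------------------------------------

def adjusted_rand_index(pred: Mapping[str, str], truth: Mapping[str, str]) -> float:
    """Adjusted Rand index between two labelings of the same cells."""
    from sklearn.metrics import adjusted_rand_score

    cells = sorted(set(pred) & set(truth))
    if not cells:
        raise ValueError("no shared cells between labelings")
    return float(adjusted_rand_score([truth[c] for c in cells], [pred[c] for c in cells]))


def edge_set_f1(pred: Iterable[tuple[str, str]], truth: Iterable[tuple[str, str]]) -> float:
    """F1 between predicted and planted directed edge sets."""
    pred, truth = set(pred), set(truth)
    if not pred and not truth:
        return 1.0
    tp = len(pred & truth)
    prec = tp / len(pred) if pred else 0.0
    rec = tp / len(truth) if truth else 0.0
    return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)


def truth_metrics(
    truth: EmbryoTruth,
    partitions: Mapping[str, Mapping[str, str]] | None = None,
    edges: Iterable[tuple[str, str]] | None = None,
) -> dict[str, float]:
    """Standard comparison scores of module outputs against planted truth."""
    scores: dict[str, float] = {}
    if partitions is not None:
        aris = [
            adjusted_rand_index(part, truth.partition(e))
            for e, part in partitions.items()
        ]
        scores["ari_mean"] = float(np.mean(aris))
        scores["ari_min"] = float(np.min(aris))
    if edges is not None:
        scores["edge_f1"] = edge_set_f1(edges, truth.lineage_edges())
    return scores
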