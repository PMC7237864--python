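"""Geometry-linked expression scores on segmentation-style cell tables.

Consumes per-cell morphometrics (volume, total and apical surface, apical
perimeter) and the pairwise apical contact graph, as produced by membrane
segmentation of light-sheet imaging.  Provides the relative apical surface,
the cadherin contact strength (sum over apical neighbours of the smaller of
the two cells' cadherin levels, weighted by shared boundary length), and the
maternal-transcript dilution formula that infers the volume ratio of sister
cells from mother/sister RNA concentrations under mass conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "CellGeometry",
    "SisterTriple",
    "relative_apical_surface",
    "cadherin_contact_strength",
    "sister_volume_ratio",
    "sister_volume_ratios",
    "strength_surface_association",
    "read_geometry",
    "write_geometry",
]


def _pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-contact not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class CellGeometry:
    """Per-cell morphometrics (µm units) and the apical contact graph.

    ``contacts`` maps unordered cell pairs to the length of their shared
    apical boundary; it is stored symmetrically (l_ij == l_ji, no l_ii).
    """

    volume: dict[str, float]
    surface: dict[str, float]
    apical_surface: dict[str, float]
    apical_perimeter: dict[str, float] = field(default_factory=dict)
    contacts: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, d in (
            ("volume", self.volume),
            ("surface", self.surface),
            ("apical_surface", self.apical_surface),
            ("apical_perimeter", self.apical_perimeter),
        ):
            for c, v in d.items():
                if v < 0:
                    raise ValueError(f"negative {name} for cell {c!r}")
        for c in self.apical_surface:
            if c in self.surface and self.apical_surface[c] > self.surface[c] + 1e-9:
                raise ValueError(f"apical surface exceeds total surface for cell {c!r}")
        fixed = {}
        for (a, b), l in self.contacts.items():
            if l < 0:
                raise ValueError(f"negative contact length for pair ({a!r}, {b!r})")
            fixed[_pair(a, b)] = l
        self.contacts = fixed

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.volume)

    def neighbors(self, cell: str) -> list[str]:
        out = [b if a == cell else a for a, b in self.contacts if cell in (a, b)]
        return sorted(out)

    def contact_length(self, a: str, b: str) -> float:
        return self.contacts.get(_pair(a, b), 0.0)


def relative_apical_surface(
    geom: CellGeometry, cells: Iterable[str] | None = None
) -> dict[str, float]:
    """Apical surface divided by the cell's own total surface (dimensionless,
    in [0, 1]; 0 for a fully internalized cell)."""
    cells = list(cells) if cells is not None else geom.cell_ids
    out = {}
    for c in cells:
        tot = geom.surface[c]
        if tot == 0:
            out[c] = 0.0
        else:
            out[c] = geom.apical_surface[c] / tot
    return out


def group_summary(values: Mapping[str, float], groups: Mapping[str, str]) -> pd.DataFrame:
    """Mean +/- SD of a per-cell quantity by group label."""
    df = pd.DataFrame(
        {"value": pd.Series(values), "group": pd.Series({c: groups[c] for c in values})}
    )
    return df.groupby("group")["value"].agg(["mean", "std", "count"])


def cadherin_contact_strength(
    expression: Mapping[str, float],
    geom: CellGeometry,
    cells: Iterable[str] | None = None,
) -> dict[str, float]:
    """Contact strength score_i = sum_j min(C_i, C_j) * l_ij over apical
    neighbours j, with C the cadherin expression level (RPM scale)."""
    cells = list(cells) if cells is not None else geom.cell_ids
    out = {}
    for c in cells:
        score = 0.0
        for j in geom.neighbors(c):
            if j not in expression:
                raise KeyError(f"cadherin expression missing for neighbour {j!r} of {c!r}")
            score += min(expression[c], expression[j]) * geom.contact_length(c, j)
        out[c] = score
    return out


@dataclass
class SisterTriple:
    """RNA concentrations (RPM) of a mother cell and its two sister daughters."""

    x0: float  # mother
    x1: float  # first sister (volume v1)
    x2: float  # second sister (volume v2)
    gene_id: str = ""


def sister_volume_ratio(t: SisterTriple) -> float:
    """Sister volume ratio v1/v2 = (x0 - x2) / (x1 - x0).

    Valid for a transcript with no zygotic transcription: the maternal RNA
    mass is conserved through division, so concentration changes reflect the
    volume partition alone.  A negative result is inconsistent with mass
    conservation (both sisters diluted, or both concentrated) and raises.
    """
    if t.x1 == t.x0:
        raise ValueError("x1 == x0: symmetric concentrations are uninformative")
    ratio = (t.x0 - t.x2) / (t.x1 - t.x0)
    if ratio < 0:
        raise ValueError(
            f"negative volume ratio ({ratio:.4g}) inconsistent with mass conservation"
        )
    return ratio


def sister_volume_ratios(triples: Sequence[SisterTriple]) -> tuple[dict[str, float], float]:
    """Per-gene sister volume ratios and their median (multi-gene consensus)."""
    per_gene = {t.gene_id or str(i): sister_volume_ratio(t) for i, t in enumerate(triples)}
    return per_gene, float(np.median(list(per_gene.values())))


def strength_surface_association(
    scores: Mapping[str, float],
    ratios: Mapping[str, float],
    cells: Iterable[str] | None = None,
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between contact strength and
    relative apical surface over the given cell group."""
    cells = sorted(set(scores) & set(ratios)) if cells is None else list(cells)
    x = np.array([scores[c] for c in cells], dtype=float)
    y = np.array([ratios[c] for c in cells], dtype=float)
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_geometry(cells_path: str, contacts_path: str | None = None) -> CellGeometry:
    """Read geometry TSVs: per-cell measures and (optionally) contacts."""
    df = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str})
    contacts = {}
    if contacts_path is not None:
        cdf = pd.read_csv(contacts_path, sep="\t", dtype={"cell_i": str, "cell_j": str})
        for _, row in cdf.iterrows():
            contacts[_pair(row["cell_i"], row["cell_j"])] = float(row["length"])
    return CellGeometry(
        volume=dict(zip(df["cell_id"], df["volume"].astype(float))),
        surface=dict(zip(df["cell_id"], df["surface"].astype(float))),
        apical_surface=dict(zip(df["cell_id"], df["apical_surface"].astype(float))),
        apical_perimeter=dict(zip(df["cell_id"], df.get("apical_perimeter", pd.Series(dtype=float)).astype(float)))
        if "apical_perimeter" in df
        else {},
        contacts=contacts,
    )


def write_geometry(geom: CellGeometry, cells_path: str, contacts_path: str | None = None) -> None:
    cells = geom.cell_ids
    pd.DataFrame(
        {
            "cell_id": cells,
            "volume": [geom.volume[c] for c in cells],
            "surface": [geom.surface[c] for c in cells],
            "apical_surface": [geom.apical_surface[c] for c in cells],
            "apical_perimeter": [geom.apical_perimeter.get(c, np.nan) for c in cells],
        }
    ).to_csv(cells_path, sep="\t", index=False)
    if contacts_path is not None:
        rows = [(a, b, l) for (a, b), l in sorted(geom.contacts.items())]
        pd.DataFrame(rows, columns=["cell_i", "cell_j", "length"]).to_csv(
            contacts_path, sep="\t", index=False
        )
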