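"""Structure-activity and structure-binding-affinity landscapes.

The landscape index of a ligand pair relates the change in activity (or
docked binding affinity) to structural similarity s in [0, 1]:

    SALI = |A1 - A2| / (1 - s)        (activity A, e.g. K_i)
    SBAI = |BA1 - BA2| / (1 - s)      (binding affinity BA, kcal/mol)

Both are the same functional; SBAI substitutes the docking-derived
binding affinity when experimental activities are missing.  A pair of
near-identical ligands with a large activity difference (an *activity
cliff*) produces a large index; at s = 1 with differing values the index
is infinite and is carried as an ``inf`` sentinel alongside a finite
capped value used for display (the cap mirrors the truncation used in
surface/contour plots of the index).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from bindscape.ligands import SimilarityMatrix

__all__ = [
    "ActivityRecord",
    "LandscapePair",
    "sali",
    "sbai",
    "pairwise_landscape",
    "detect_cliffs",
    "build_graph",
    "sbai_surface",
    "read_activity_csv",
    "write_pairs_csv",
    "write_graphml",
    "surface_to_csv",
    "DEFAULT_CAP",
    "DEFAULT_EDGE_THRESHOLD",
]

DEFAULT_CAP = 2000.0
DEFAULT_EDGE_THRESHOLD = 0.65


@dataclass
class ActivityRecord:
    """Per-ligand activity or binding affinity value."""

    ligand_id: str
    value: float
    value_kind: str = "binding_affinity"  # activity | binding_affinity

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite value for ligand {self.ligand_id!r}")


@dataclass
class LandscapePair:
    """One unordered ligand pair with its landscape index."""

    id_a: str
    id_b: str
    s: float
    d_val: float
    index: float
    capped_index: float


def _index(v1: float, v2: float, s: float) -> float:
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"similarity s={s} outside [0,1]")
    d = abs(v1 - v2)
    if d == 0.0:
        return 0.0
    if s == 1.0:
        return math.inf
    return d / (1.0 - s)


def sali(a1: float, a2: float, s: float) -> float:
    """Structure-Activity Landscape Index |a1 - a2| / (1 - s).

    Returns 0 when the activities are equal and ``inf`` when s = 1 with
    differing activities.
    """
    return _index(a1, a2, s)


def sbai(ba1: float, ba2: float, s: float) -> float:
    """Structure-Binding Affinity Index: SALI with docked affinities.

    Identical functional form; kept as a separate entry point because
    the two indices live on different value scales (experimental
    activity vs kcal/mol affinity).
    """
    return _index(ba1, ba2, s)


def pairwise_landscape(
    records: Sequence[ActivityRecord],
    sim: SimilarityMatrix,
    cap: float = DEFAULT_CAP,
) -> list[LandscapePair]:
    """All unordered ligand pairs with their landscape indices.

    Every record id must be present in the similarity matrix.  Pair
    order is deterministic (record order, i < j).
    """
    missing = [r.ligand_id for r in records if r.ligand_id not in sim.ids]
    if missing:
        raise ValueError(f"ids missing from similarity matrix: {missing}")
    pairs: list[LandscapePair] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            s = sim.get(a.ligand_id, b.ligand_id)
            idx = _index(a.value, b.value, s)
            pairs.append(
                LandscapePair(
                    id_a=a.ligand_id,
                    id_b=b.ligand_id,
                    s=s,
                    d_val=abs(a.value - b.value),
                    index=idx,
                    capped_index=min(idx, cap),
                )
            )
    return pairs


def detect_cliffs(
    pairs: Sequence[LandscapePair], s_min: float, top_fraction: float = 1.0
) -> list[LandscapePair]:
    """Activity/affinity cliffs: similar pairs with the largest indices.

    Keeps pairs with s >= s_min, ranks by index descending (infinite
    indices first), and returns the top fraction.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError(f"top_fraction must be in (0,1], got {top_fraction}")
    eligible = [p for p in pairs if p.s >= s_min]
    # sentinel-aware: inf sorts first via -index; ties stable by ids
    ranked = sorted(eligible, key=lambda p: (-p.index, p.id_a, p.id_b))
    if not ranked:
        return []
    n_keep = max(1, math.ceil(top_fraction * len(ranked)))
    return ranked[:n_keep]


def build_graph(
    pairs: Sequence[LandscapePair],
    records: Sequence[ActivityRecord],
    s_threshold: float = DEFAULT_EDGE_THRESHOLD,
    node_score: str = "max_index",
) -> nx.Graph:
    """Network-like similarity graph.

    Ligands are nodes; edges connect pairs with s >= s_threshold and
    carry the similarity and landscape index.  Each node's score
    aggregates the capped index over its incident edges (``max_index``
    highlights the worst cliff partner, ``mean_index`` the average);
    isolated nodes are retained with score 0.
    """
    if node_score not in {"max_index", "mean_index"}:
        raise ValueError(f"unknown node_score {node_score!r}")
    g = nx.Graph(s_threshold=s_threshold)
    for r in records:
        g.add_node(r.ligand_id, value=r.value, node_score=0.0)
    for p in pairs:
        if p.s >= s_threshold:
            g.add_edge(p.id_a, p.id_b, s=p.s, index=p.capped_index)
    for node in g.nodes:
        incident = [g.edges[e]["index"] for e in g.edges(node)]
        if incident:
            agg = max(incident) if node_score == "max_index" else float(np.mean(incident))
            g.nodes[node]["node_score"] = agg
    return g


def sbai_surface(
    s_grid: Sequence[float], dba_grid: Sequence[float], cap: float = DEFAULT_CAP
) -> np.ndarray:
    """Index surface over a (similarity, affinity-difference) grid.

    Rows follow ``dba_grid``, columns ``s_grid``; each cell holds
    ``min(|d_BA| / (1 - s), cap)``, symmetric in the sign of d_BA.  The
    grid must stay inside the half-open interval s in [0, 1).
    """
    s = np.asarray(s_grid, dtype=float)
    dba = np.asarray(dba_grid, dtype=float)
    if s.size == 0 or dba.size == 0:
        raise ValueError("grids must be nonempty")
    if np.any(s >= 1.0) or np.any(s < 0.0):
        raise ValueError("s grid must lie in [0,1): s=1 is a pole of the index")
    surf = np.abs(dba)[:, None] / (1.0 - s)[None, :]
    return np.minimum(surf, cap)


# ---------------------------------------------------------------------------
# I/O

def read_activity_csv(path: str | Path) -> list[ActivityRecord]:
    """CSV with columns ligand_id, value and optional value_kind."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "ligand_id" not in cols or "value" not in cols:
        raise ValueError("activity CSV needs columns: ligand_id, value[, value_kind]")
    kind_col = cols.get("value_kind")
    return [
        ActivityRecord(
            ligand_id=str(row[cols["ligand_id"]]),
            value=float(row[cols["value"]]),
            value_kind=str(row[kind_col]) if kind_col else "binding_affinity",
        )
        for _, row in df.iterrows()
    ]


def write_pairs_csv(pairs: Sequence[LandscapePair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id_a", "id_b", "s", "d_val", "index", "capped_index"])
        for p in pairs:
            w.writerow([p.id_a, p.id_b, p.s, p.d_val, p.index, p.capped_index])


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def surface_to_csv(
    surf: np.ndarray, s_grid: Sequence[float], dba_grid: Sequence[float], path: str | Path
) -> None:
    df = pd.DataFrame(surf, index=list(dba_grid), columns=list(s_grid))
    df.index.name = "d_BA\\s"
    df.to_csv(path)
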