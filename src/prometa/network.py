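"""Protein association-network summaries from confidence-scored edge tables.

Edges come from a STRING-style export (two node columns plus a combined
confidence score); only the combined score drives filtering. The summary is
purely structural — connected components, degrees, isolates — no layout and
no inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

#: Conventional "high confidence" combined-score cutoff.
HIGH_CONFIDENCE = 0.700


@dataclass
class EdgeList:
    """Undirected scored edges over a node universe (isolates included).

    Edges are stored with endpoints in lexicographic order; self-loops are
    rejected and scores must lie in [0, 1].
    """

    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    node_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        canonical: dict[tuple[str, str], float] = {}
        for (a, b), score in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"score {score} outside [0, 1] for edge ({a}, {b})")
            key = (a, b) if a <= b else (b, a)
            canonical[key] = max(score, canonical.get(key, 0.0))
        self.edges = canonical
        self.node_universe = set(self.node_universe)
        for a, b in self.edges:
            self.node_universe.update((a, b))

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class NetworkSummary:
    components: list[frozenset[str]]      # largest first
    degrees: dict[str, int]               # every universe node, isolates at 0
    isolates: set[str]

    def top_degree(self) -> Optional[str]:
        """Node with the most associations (alphabetical tie-break)."""
        if not self.degrees:
            return None
        return min(self.degrees, key=lambda s: (-self.degrees[s], s))


def read_edge_table(
    path: str | Path,
    score_scale: str = "milli",
    nodes: Optional[Iterable[str]] = None,
) -> EdgeList:
    """Read a ``node_a<TAB>node_b<TAB>combined_score`` table.

    ``milli`` scale expects integer scores 0–1000 (STRING's export
    convention) and divides by 1000; ``unit`` expects floats in [0, 1].
    Duplicate edges keep the maximum score; self-loops are dropped with a
    warning. ``nodes`` extends the universe with isolates.
    """
    if score_scale not in ("unit", "milli"):
        raise ValueError(f"score_scale must be 'unit' or 'milli', got {score_scale!r}")
    frame = pd.read_csv(path, sep="\t", comment="#")
    if frame.shape[1] < 3:
        raise ValueError(f"{path}: expected at least 3 columns")
    edges: dict[tuple[str, str], float] = {}
    for _, row in frame.iterrows():
        a, b = str(row.iloc[0]).strip(), str(row.iloc[1]).strip()
        raw = float(row.iloc[2])
        if score_scale == "milli":
            if not (0 <= raw <= 1000):
                raise ValueError(f"{path}: milli-scale score {raw} outside 0–1000")
            score = raw / 1000.0
        else:
            if not (0.0 <= raw <= 1.0):
                raise ValueError(f"{path}: unit-scale score {raw} outside [0, 1]")
            score = raw
        if a == b:
            warnings.warn(f"dropping self-loop on {a!r}", stacklevel=2)
            continue
        key = (a, b) if a <= b else (b, a)
        edges[key] = max(score, edges.get(key, 0.0))
    universe = set(nodes) if nodes is not None else set()
    return EdgeList(edges=edges, node_universe=universe)


def filter_edges(edge_list: EdgeList, c: float = HIGH_CONFIDENCE) -> EdgeList:
    """Keep edges with combined score >= c (inclusive); universe unchanged."""
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {c}")
    kept = {edge: s for edge, s in edge_list.edges.items() if s >= c}
    return EdgeList(edges=kept, node_universe=set(edge_list.node_universe))


def summarize(edge_list: EdgeList) -> NetworkSummary:
    """Connected components (size-descending), degrees and isolates."""
    graph = nx.Graph()
    graph.add_nodes_from(edge_list.node_universe)
    graph.add_edges_from(edge_list.edges)
    degrees = {node: int(d) for node, d in graph.degree()}
    isolates = {node for node, d in degrees.items() if d == 0}
    components = [
        frozenset(c)
        for c in nx.connected_components(graph)
        if len(c) > 1 or next(iter(c)) not in isolates
    ]
    components.sort(key=lambda c: (-len(c), min(c)))
    return NetworkSummary(components=components, degrees=degrees, isolates=isolates)
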