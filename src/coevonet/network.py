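"""Co-evolution networks: thresholded graphs over core positions.

An edge joins two core positions when their pairwise correlated-mutation
score is defined and at or above the chosen cutoff (inclusive).  Nodes
are exactly the edge endpoints — a position with no partner above the
cutoff is not part of any network.  Connected components are the
"networks"; sub-networks can be obtained by re-partitioning a component
at a stricter cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cma import CmaMatrix

#: 20-colour categorical palette (hex) for component colouring.
PALETTE = (
    "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c",
    "#98df8a", "#d62728", "#ff9896", "#9467bd", "#c5b0d5",
    "#8c564b", "#c49c94", "#e377c2", "#f7b6d2", "#7f7f7f",
    "#c7c7c7", "#bcbd22", "#dbdb8d", "#17becf", "#9edae5",
)


@dataclass
class CoevoNetwork:
    """A thresholded co-evolution graph.

    ``components`` are ordered by decreasing size, ties broken by the
    smallest member position.
    """

    graph: nx.Graph
    cutoff: float
    method: str

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        return [(i, j, d["weight"]) for i, j, d in self.graph.edges(data=True)]

    @property
    def components(self) -> list[set[int]]:
        comps = [set(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), min(c)))

    def is_empty(self) -> bool:
        return self.graph.number_of_nodes() == 0


@dataclass(frozen=True)
class NetworkComparison:
    """Set overlap between two node sets as precision/recall/F."""

    precision: float
    recall: float
    f_measure: float
    intersection: int


def build_network(matrix: CmaMatrix, cutoff: float) -> CoevoNetwork:
    """Graph of all defined pairs scoring at or above the cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    g = nx.Graph()
    k = len(matrix.positions)
    iu, ju = np.triu_indices(k, k=1)
    s = matrix.scores[iu, ju]
    keep = ~np.isnan(s) & (s >= cutoff)
    for a, b, w in zip(iu[keep], ju[keep], s[keep]):
        g.add_edge(matrix.positions[a], matrix.positions[b], weight=float(w))
    return CoevoNetwork(g, cutoff, matrix.method)


def main_network(network: CoevoNetwork) -> set[int] | None:
    """Largest connected component (tie: smallest minimum position), or None."""
    comps = network.components
    return comps[0] if comps else None


def hub(network: CoevoNetwork, component: set[int]) -> int:
    """Highest-degree node of a component; ties go to the lowest position."""
    if not component:
        raise ValueError("empty component has no hub")
    return min(component, key=lambda n: (-network.graph.degree(n), n))


def f_measure(nodes_a: set[int], nodes_b: set[int]) -> NetworkComparison:
    """Precision/recall/F of node set A against node set B.

    Both sets empty compare as identical (F = 1); exactly one empty as
    fully dissimilar (F = 0).
    """
    a, b = set(nodes_a), set(nodes_b)
    inter = len(a & b)
    if not a and not b:
        return NetworkComparison(1.0, 1.0, 1.0, 0)
    if not a or not b:
        return NetworkComparison(0.0, 0.0, 0.0, 0)
    p = inter / len(a)
    r = inter / len(b)
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return NetworkComparison(p, r, f, inter)


def sub_networks(
    network: CoevoNetwork, component: set[int], cutoff: float
) -> list[set[int]]:
    """Re-partition one component at a stricter cutoff."""
    if cutoff < network.cutoff:
        raise ValueError("sub-network cutoff must be >= the network cutoff")
    sub = network.graph.subgraph(component)
    g = nx.Graph()
    for i, j, d in sub.edges(data=True):
        if d["weight"] >= cutoff:
            g.add_edge(i, j, weight=d["weight"])
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def calibrate_cutoff(matrix: CmaMatrix) -> float:
    """Cutoff midway between the bulk and the top of the score distribution.

    Pairwise scores of an alignment with genuine co-evolving groups are
    strongly bimodal: a large mass of near-background pairs and a small
    tail of coupled pairs.  The midpoint between the median defined score
    (the background bulk) and the maximum separates the two modes without
    reference to any ground truth.
    """
    vals = matrix.defined_scores()
    if vals.size == 0:
        raise ValueError("matrix has no defined scores to calibrate on")
    return float(0.5 * (np.median(vals) + vals.max()))


# -- export ---------------------------------------------------------------


def to_cytoscape_json(
    network: CoevoNetwork, annotations=None
) -> dict:
    """Cytoscape-style elements document (nodes + edges).

    ``annotations`` may be an annotation table; nodes then carry the list
    of keywords annotated at that position.
    """
    kw_map: dict[int, list[str]] = {}
    if annotations is not None:
        for (pos, kw) in annotations.mapping:
            kw_map.setdefault(pos, []).append(kw)
    nodes = [
        {
            "data": {
                "id": str(n),
                "position": n,
                "degree": network.graph.degree(n),
                "keywords": sorted(kw_map.get(n, [])),
            }
        }
        for n in sorted(network.graph.nodes)
    ]
    edges = [
        {
            "data": {
                "source": str(i),
                "target": str(j),
                "weight": round(w, 6),
            }
        }
        for i, j, w in sorted(network.edges)
    ]
    return {
        "format_version": "1.0",
        "data": {"cutoff": network.cutoff, "method": network.method},
        "elements": {"nodes": nodes, "edges": edges},
    }


def write_graph(network: CoevoNetwork, path, fmt: str = "json", annotations=None):
    """Write the network as cytoscape JSON or GraphML."""
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(to_cytoscape_json(network, annotations), fh, indent=1)
    elif fmt == "graphml":
        nx.write_graphml(network.graph, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def colour_map(network: CoevoNetwork) -> pd.DataFrame:
    """Position/colour table usable by any structure viewer.

    One colour per connected component (palette cycles past 20).
    """
    rows = []
    for idx, comp in enumerate(network.components):
        colour = PALETTE[idx % len(PALETTE)]
        for pos in sorted(comp):
            rows.append((pos, idx, colour))
    return pd.DataFrame(rows, columns=["position", "component_index", "hex_colour"])
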