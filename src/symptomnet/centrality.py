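"""Node centrality on the weighted network and force-directed layout.

Strength is the sum of absolute incident edge weights; expected
influence the signed sum (they coincide on all-positive networks).
Closeness and betweenness are shortest-path indices with edge length
1/|w| over nonzero edges: closeness_i = (m-1)/sum_j d(i,j) over
reachable j, betweenness the Brandes count of fractional shortest-path
shares.  Core symptoms are the nodes with the highest strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .core import EDGE_THRESHOLD, NetworkModel, ValidationError

INDEX_NAMES = ("strength", "closeness", "betweenness", "expected_influence")


@dataclass
class CentralityTable:
    """Raw and z-standardized centrality indices, one row per node."""

    table: pd.DataFrame  # index: node; columns: raw indices + z_<index>
    flags: dict = field(default_factory=dict)

    def raw(self, index: str) -> pd.Series:
        return self.table[index]

    def z(self, index: str) -> pd.Series:
        return self.table[f"z_{index}"]


def strength(network: NetworkModel) -> np.ndarray:
    """s_i = sum_j |w_ij|."""
    return np.abs(network.weights).sum(axis=1)


def expected_influence(network: NetworkModel) -> np.ndarray:
    """Signed row sum of edge weights."""
    return network.weights.sum(axis=1)


def _length_graph(network: NetworkModel) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(network.m))
    mask = network.edge_mask()
    for i in range(network.m):
        for j in range(i + 1, network.m):
            if mask[i, j]:
                w = network.weights[i, j]
                G.add_edge(i, j, length=1.0 / abs(w), weight=w, weight_abs=abs(w))
    return G


def shortest_path_metrics(network: NetworkModel) -> tuple[np.ndarray, np.ndarray, bool]:
    """Closeness and betweenness with edge length 1/|w|.

    Returns (closeness, betweenness, fully_connected).  Unreachable
    pairs contribute 0 to a node's closeness denominator and the
    disconnection is flagged via the third return value.
    """
    m = network.m
    L = np.zeros((m, m))
    mask = network.edge_mask()
    L[mask] = 1.0 / np.abs(network.weights[mask])
    D = dijkstra(L, directed=False)
    closeness = np.zeros(m)
    connected = True
    for i in range(m):
        d = np.delete(D[i], i)
        finite = np.isfinite(d)
        if not finite.all():
            connected = False
        total = d[finite].sum()
        closeness[i] = (m - 1) / total if total > 0 else 0.0
    G = _length_graph(network)
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    betweenness = np.array([bc[i] for i in range(m)])
    return closeness, betweenness, connected


def centrality_table(network: NetworkModel) -> CentralityTable:
    """All four indices, raw and z-scored across nodes."""
    s = strength(network)
    ei = expected_influence(network)
    clo, bet, connected = shortest_path_metrics(network)
    df = pd.DataFrame(
        {
            "strength": s,
            "closeness": clo,
            "betweenness": bet,
            "expected_influence": ei,
        },
        index=network.node_names,
    )
    table = CentralityTable(table=df, flags={"disconnected": not connected})
    return standardize(table)


def standardize(table: CentralityTable) -> CentralityTable:
    """z = (x - mean)/sd per index across nodes (sd with n-1 divisor).

    Degenerate indices (sd = 0) yield all-zero z-scores and a flag.
    """
    df = table.table.copy()
    if len(df) < 2:
        raise ValidationError("standardization needs at least 2 nodes")
    degenerate = []
    for idx in INDEX_NAMES:
        x = df[idx].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            df[f"z_{idx}"] = 0.0
            degenerate.append(idx)
        else:
            df[f"z_{idx}"] = (x - x.mean()) / sd
    flags = dict(table.flags)
    if degenerate:
        flags["degenerate_indices"] = degenerate
    return CentralityTable(table=df, flags=flags)


def rank_core_symptoms(table: CentralityTable, symptom_nodes: list | None = None):
    """Symptom nodes ordered by strength, descending.

    The highest-strength symptoms are the network's core symptoms.
    Ties break lexicographically and are flagged in the second return.
    """
    df = table.table
    if symptom_nodes is not None:
        df = df.loc[list(symptom_nodes)]
    s = df["strength"]
    order = sorted(df.index, key=lambda nm: (-s[nm], str(nm)))
    tied = s.duplicated(keep=False).any()
    return order, bool(tied)


@dataclass
class LayoutCoordinates:
    coords: pd.DataFrame  # index: node; columns x, y in [-1, 1]
    seed: int
    iterations: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords[["x", "y"]].to_numpy())):
            raise ValidationError("layout coordinates must be finite")


def fruchterman_reingold(
    network: NetworkModel, seed: int, iterations: int = 500
) -> LayoutCoordinates:
    """Force-directed layout: repulsion on all pairs, attraction along
    edges proportional to |w|; deterministic under a fixed seed and
    rescaled to the [-1,1] square."""
    G = _length_graph(network)
    pos = nx.spring_layout(
        G, weight="weight_abs", seed=int(seed), iterations=int(iterations)
    )
    xy = np.array([pos[i] for i in range(network.m)], dtype=float)
    span = np.abs(xy).max()
    if span > 0:
        xy = xy / span
    coords = pd.DataFrame(xy, index=network.node_names, columns=["x", "y"])
    return LayoutCoordinates(coords=coords, seed=int(seed), iterations=int(iterations))
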