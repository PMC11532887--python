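"""Node centrality on the weighted symptom network.

Strength, harmonic closeness and betweenness, raw and standardised.
Edge "length" for shortest-path indices is ``1/|w|``: stronger
associations mean shorter distances; negative edges contribute magnitude
only.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .ising import IsingNetwork

logger = logging.getLogger(__name__)

__all__ = ["compute_centrality", "core_symptom", "to_graph"]


def to_graph(net: IsingNetwork) -> nx.Graph:
    """networkx view of the network: weight=|w|, length=1/|w| per edge."""
    g = nx.Graph()
    g.add_nodes_from(net.catalog.codes)
    codes = net.catalog.codes
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = net.weights[i, j]
            if w != 0:
                g.add_edge(codes[i], codes[j], weight=abs(w), length=1.0 / abs(w))
    return g


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def compute_centrality(net: IsingNetwork) -> pd.DataFrame:
    """Strength, harmonic closeness and betweenness per node, with z-scores.

    * strength_i = sum_j |w_ij|
    * closeness_i = (1/(p-1)) * sum_{j != i} 1/d_ij with 1/inf = 0
      (harmonic form, well defined on disconnected networks)
    * betweenness: geodesic counting on edge lengths 1/|w|, unnormalised

    Returns a frame with columns code, name, strength, closeness,
    betweenness and standardised rs, rc, rb (z-scores across nodes,
    sample SD).
    """
    p = net.p
    if p < 2:
        raise ValueError("centrality needs at least 2 nodes")
    g = to_graph(net)
    codes = list(net.catalog.codes)

    strength = np.abs(net.weights).sum(axis=1)

    closeness = np.zeros(p)
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i, c in enumerate(codes):
        inv = [1.0 / d for t, d in dist[c].items() if t != c and d > 0]
        closeness[i] = sum(inv) / (p - 1)

    bet = nx.betweenness_centrality(g, weight="length", normalized=False)
    betweenness = np.array([bet[c] for c in codes])

    return pd.DataFrame(
        {
            "code": codes,
            "name": list(net.catalog.names),
            "strength": strength,
            "closeness": closeness,
            "betweenness": betweenness,
            "rs": _zscore(strength),
            "rc": _zscore(closeness),
            "rb": _zscore(betweenness),
        }
    )


def core_symptom(table: pd.DataFrame) -> str:
    """Code of the node with the highest standardised strength.

    Ties are broken by closeness, then betweenness, then catalog order;
    a tie on strength is logged.
    """
    if len(table) == 0:
        raise ValueError("empty centrality table")
    best_rs = table["rs"].max()
    tied = table[table["rs"] == best_rs]
    if len(tied) > 1:
        logger.info(
            "strength tie among %s; breaking by closeness, betweenness, order",
            list(tied["code"]),
        )
        tied = tied.sort_values(
            ["rc", "rb"], ascending=False, kind="stable"
        )
    return str(tied.iloc[0]["code"])
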