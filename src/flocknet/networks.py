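"""SRI-weighted social networks and the four centrality measures.

From dyadic co-arrival counts we build weighted, undirected networks
(weekly, per event, and opposite-sex bipartite sub-graphs) and compute,
per individual: degree, strength (the scaled sum of Simple Ratio
Indices), eigenvector centrality of the SRI-weighted adjacency
(normalized to max 1), and opposite-sex degree from the bipartite
sub-graph.  Networks are never thresholded, but only birds who arrived
in a dyad (degree > 0) are included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .arrivals import DyadCounts

logger = logging.getLogger("flocknet.networks")

__all__ = ["SRIMatrix", "compute_sri", "build_network",
           "compute_centralities", "summarize_event"]


@dataclass
class SRIMatrix:
    """Dyadic Simple Ratio Indices for one window.

    sri maps unordered dyads (a < b) to an association probability in
    [0, 1]; individuals lists everyone with at least one arrival.
    """

    sri: dict = field(default_factory=dict)
    individuals: list = field(default_factory=list)
    window_label: str | None = None

    def get(self, a, b) -> float:
        key = (a, b) if a <= b else (b, a)
        return self.sri.get(key, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, v) for (a, b), v in sorted(self.sri.items())]
        return pd.DataFrame(rows, columns=["individual_a", "individual_b",
                                           "sri"])


def compute_sri(counts: DyadCounts) -> SRIMatrix:
    """SRI_ab = x_ab / (x_ab + y_a + y_b), y_a = n_a - x_ab.

    Equals x / (n_a + n_b - x): joint arrivals over occasions either
    bird arrived.  0/0 (two birds with no arrivals) is defined as 0.
    The denominator's joint-absence term is omitted: the sampling unit
    is an arrival, not a survey scan.
    """
    out = SRIMatrix(individuals=sorted(counts.n),
                    window_label=counts.window_label)
    for (a, b), x in counts.x.items():
        y_a = counts.n.get(a, 0) - x
        y_b = counts.n.get(b, 0) - x
        if y_a < 0 or y_b < 0:
            raise ValueError(
                f"dyad ({a}, {b}): co-arrivals {x} exceed arrivals "
                f"({counts.n.get(a, 0)}, {counts.n.get(b, 0)})"
            )
        denom = x + y_a + y_b
        out.sri[(a, b)] = 0.0 if denom == 0 else x / denom
    return out


def build_network(sri: SRIMatrix, individuals: pd.DataFrame,
                  bipartite: bool = False) -> nx.Graph:
    """Build the weighted network, optionally the opposite-sex sub-graph.

    Edges carry weight=SRI and only positive weights are kept.  In
    bipartite mode same-sex edges are dropped *before* the degree>0
    filter on the sub-graph.  Isolated vertices are removed, so every
    remaining bird arrived in at least one dyad.
    """
    sex = individuals.set_index("individual_id")["sex"].to_dict()
    g = nx.Graph()
    for (a, b), w in sri.sri.items():
        if w <= 0:
            continue
        if bipartite:
            for v in (a, b):
                if v not in sex or pd.isna(sex[v]):
                    raise ValueError(
                        f"individual {v!r} lacks sex metadata required "
                        "for the bipartite sub-graph"
                    )
            if sex[a] == sex[b]:
                continue
        g.add_edge(a, b, weight=float(w))
    nx.set_node_attributes(
        g, {v: int(sex[v]) for v in g.nodes if v in sex and not pd.isna(sex[v])},
        "sex")
    g.remove_nodes_from([v for v in list(g.nodes) if g.degree(v) == 0])
    g.graph["window_label"] = sri.window_label
    return g


def _leading_eigenvector(g: nx.Graph, nodes: list) -> np.ndarray:
    """Dominant eigenvector of the weighted adjacency, max-normalized."""
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    vals, vecs = np.linalg.eigh(a)
    v = vecs[:, int(np.argmax(vals))]
    v = np.abs(v)
    vmax = v.max()
    return v / vmax if vmax > 0 else v


def compute_centralities(network: nx.Graph,
                         bipartite_network: nx.Graph | None = None,
                         strength_definition: str = "scaled") -> pd.DataFrame:
    """Per-individual degree, strength, eigenvector and opposite-sex degree.

    Strength follows the net-association-quality transform
    S_i = d_i * sum_j SRI_ij / N(V) (``strength_definition='scaled'``);
    the plain summed SRI is available with ``'sum'``.  Eigenvector
    centrality is the dominant eigenvector of the full weighted
    adjacency normalized to max 1; on a disconnected network this
    concentrates scores on the dominant component (logged).
    Opposite-sex degree is the bird's degree in the bipartite sub-graph
    (0 if absent from it).
    """
    if strength_definition not in ("scaled", "sum"):
        raise ValueError(f"unknown strength_definition {strength_definition!r}")
    if network.number_of_nodes() == 0:
        raise ValueError("cannot compute centralities of an empty network")
    if not nx.is_connected(network):
        logger.info(
            "network %s is disconnected; eigenvector centrality computed on "
            "the full weighted adjacency (dominant component wins)",
            network.graph.get("window_label"))
    nodes = sorted(network.nodes)
    n_v = len(nodes)
    eig = _leading_eigenvector(network, nodes)
    rows = []
    for k, v in enumerate(nodes):
        d = network.degree(v)
        s_sum = sum(d_["weight"] for *_, d_ in network.edges(v, data=True))
        s = d * s_sum / n_v if strength_definition == "scaled" else s_sum
        osd = (bipartite_network.degree(v)
               if bipartite_network is not None
               and v in bipartite_network else 0)
        rows.append((v, d, s, eig[k], osd))
    out = pd.DataFrame(rows, columns=["individual_id", "degree", "strength",
                                      "eigenvector", "opposite_sex_degree"])
    out["window_label"] = network.graph.get("window_label")
    return out


MEASURES = ["degree", "strength", "eigenvector", "opposite_sex_degree"]


def summarize_event(centrality: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1 denominator) and n per centrality measure."""
    if centrality.empty:
        raise ValueError("empty centrality table")
    rows = []
    for m in MEASURES:
        vals = centrality[m].astype(float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        rows.append((m, float(vals.mean()), sd, int(len(vals))))
    return pd.DataFrame(rows, columns=["measure", "mean", "sd", "n"])
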