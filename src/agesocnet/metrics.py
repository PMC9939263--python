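"""Node-level and network-level metrics for grooming networks.

Node metrics are the four indirect-connectedness measures used in the
analyses — weighted eigenvector centrality, shortest-path betweenness,
closeness, and the (binary) local clustering coefficient — plus degree
and strength.  Global metrics are mean degree, diameter, transitivity
and density.

Conventions:

* Edge weights are grooming rates (affinities).  Shortest-path metrics
  convert them to geodesic lengths via the reciprocal
  (:func:`weight_to_distance`), rescaled per network so the strongest
  edge has unit length; binary networks use unit lengths.  The
  rescaling leaves betweenness untouched (shortest paths are invariant
  to a common distance scale) and bounds closeness in [0, 1], since
  every edge is then at least one unit long.
* Closeness uses the bounded reachable-set formula
  ``((r-1)/(n-1)) * ((r-1) / sum of distances to reachable nodes)``, so
  it is defined on disconnected graphs and is 0 for isolates.
* Diameter is the longest geodesic over *connected* pairs only, hence
  finite on disconnected graphs; an edgeless graph has diameter 0.
* Local clustering and transitivity are binary even on weighted graphs.
* Eigenvector centrality is computed per connected component and the
  whole vector is rescaled so its maximum is 1; isolates score 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

NODE_METRIC_NAMES = (
    "eigenvector",
    "betweenness",
    "closeness",
    "clustering",
    "degree",
    "strength",
)


class DegenerateGraphError(ValueError):
    """Raised for graphs too small for global metrics (fewer than 2 nodes)."""


def weight_to_distance(w: float) -> float:
    """Convert an affinity edge weight to a geodesic length (1/w)."""
    if w <= 0:
        raise ValueError(f"edge weight must be positive, got {w}")
    return 1.0 / w


def _with_distances(g: nx.Graph) -> nx.Graph:
    """Return a copy carrying a 'dist' edge attribute.

    Distances are reciprocal weights rescaled so the strongest edge in
    the network has unit length; on unit-weight graphs this reduces to
    hop lengths.
    """
    h = g.copy()
    weights = [d.get("weight", 1.0) for _, _, d in h.edges(data=True)]
    wmax = max(weights) if weights else 1.0
    for u, v, data in h.edges(data=True):
        w = data.get("weight", 1.0)
        data["dist"] = weight_to_distance(w / wmax)
    return h


def eigenvector_centrality(g: nx.Graph) -> dict:
    """Leading-eigenvector scores of the weighted adjacency.

    Computed per connected component by dense symmetric
    eigendecomposition (component vectors L2-normalised, signs fixed
    nonnegative), then globally rescaled so the maximum score is 1.
    Isolated nodes score 0.
    """
    if g.number_of_nodes() == 0:
        return {}
    scores = {v: 0.0 for v in g.nodes}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) < 2:
            continue
        a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        vals, vecs = scipy.linalg.eigh(a)
        lead = np.abs(vecs[:, -1])
        lead /= np.linalg.norm(lead)
        for v, s in zip(nodes, lead):
            scores[v] = float(s)
    top = max(scores.values())
    if top > 0:
        scores = {v: s / top for v, s in scores.items()}
    return scores


def shortest_path_metrics(g: nx.Graph) -> tuple[dict, dict]:
    """Betweenness and closeness per node.

    Betweenness is raw (unnormalised) shortest-path betweenness with
    fractional attribution among tied geodesics.  Closeness is the
    bounded reachable-set formula (0 for isolates).  Weighted graphs use
    reciprocal-weight distances.
    """
    h = _with_distances(g)
    betweenness = nx.betweenness_centrality(h, normalized=False, weight="dist")
    closeness = nx.closeness_centrality(h, distance="dist", wf_improved=True)
    return betweenness, closeness


def local_clustering(g: nx.Graph) -> dict:
    """Binary local clustering coefficient; nodes of degree < 2 get 0."""
    return nx.clustering(g, weight=None)


def node_metrics(g: nx.Graph) -> pd.DataFrame:
    """All node metrics as a tidy frame, one row per node."""
    eig = eigenvector_centrality(g)
    btw, clo = shortest_path_metrics(g)
    clu = local_clustering(g)
    rows = []
    for v in g.nodes:
        rows.append(
            {
                "node": v,
                "eigenvector": eig[v],
                "betweenness": btw[v],
                "closeness": clo[v],
                "clustering": clu[v],
                "degree": g.degree(v),
                "strength": sum(
                    d.get("weight", 1.0) for _, _, d in g.edges(v, data=True)
                ),
            }
        )
    return pd.DataFrame(rows)


def binary_global_metrics(n: int, edges: np.ndarray) -> dict:
    """Global metrics of an unweighted graph given as an (m, 2) edge array.

    Fast path used by the network ensembles; delegates diameter and
    transitivity to igraph.  Diameter is the longest geodesic within
    components (hops); an edgeless graph has diameter 0.
    """
    import igraph

    if n < 2:
        raise DegenerateGraphError(f"global metrics undefined for n={n}")
    m = int(edges.shape[0])
    if m == 0:
        return {
            "mean_degree": 0.0,
            "diameter": 0.0,
            "transitivity": 0.0,
            "density": 0.0,
        }
    g = igraph.Graph(n=n, edges=edges.tolist())
    return {
        "mean_degree": 2.0 * m / n,
        "diameter": float(g.diameter(unconn=True)),
        "transitivity": float(g.transitivity_undirected(mode="zero")),
        "density": 2.0 * m / (n * (n - 1)),
    }


@dataclass(frozen=True)
class GlobalMetricRecord:
    mean_degree: float
    diameter: float
    transitivity: float
    density: float
    n_nodes: int
    n_edges: int
    proportion_old: float | None = None
    edgeless: bool = False

    def as_dict(self) -> dict:
        return {
            "mean_degree": self.mean_degree,
            "diameter": self.diameter,
            "transitivity": self.transitivity,
            "density": self.density,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "proportion_old": self.proportion_old,
        }


def global_metrics(
    g: nx.Graph, old_threshold: float | None = None
) -> GlobalMetricRecord:
    """Global metrics of a (possibly weighted) networkx graph.

    Weighted graphs measure the diameter over summed reciprocal-weight
    distances; binary graphs over hops.  Transitivity is binary in both
    cases.  If ``old_threshold`` is given and nodes carry an ``age``
    attribute, the proportion of nodes strictly older than the threshold
    is reported.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise DegenerateGraphError(f"global metrics undefined for n={n}")
    m = g.number_of_edges()
    weighted = any("weight" in d for _, _, d in g.edges(data=True))
    if m == 0:
        diameter = 0.0
        transitivity = 0.0
    else:
        import igraph

        nodes = list(g.nodes)
        index = {v: k for k, v in enumerate(nodes)}
        el = [(index[u], index[v]) for u, v in g.edges]
        ig = igraph.Graph(n=n, edges=el)
        if weighted:
            weights = [d.get("weight", 1.0) for _, _, d in g.edges(data=True)]
            wmax = max(weights)
            dists = [weight_to_distance(w / wmax) for w in weights]
            diameter = float(ig.diameter(weights=dists, unconn=True))
        else:
            diameter = float(ig.diameter(unconn=True))
        transitivity = float(ig.transitivity_undirected(mode="zero"))
    prop_old = None
    if old_threshold is not None:
        ages = [d.get("age") for _, d in g.nodes(data=True)]
        if all(a is not None for a in ages):
            prop_old = float(np.mean([a > old_threshold for a in ages]))
    return GlobalMetricRecord(
        mean_degree=2.0 * m / n,
        diameter=diameter,
        transitivity=transitivity,
        density=2.0 * m / (n * (n - 1)),
        n_nodes=n,
        n_edges=m,
        proportion_old=prop_old,
        edgeless=(m == 0),
    )
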