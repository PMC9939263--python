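"""Reading and writing grooming networks.

Networks travel as a pair of plain CSV files — an undirected weighted
edge list (``id_a,id_b,weight``) and a node attribute table
(``id,age,rank,matriline,group,year``) — or as GraphML.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

EDGE_COLUMNS = ["id_a", "id_b", "weight"]
NODE_COLUMNS = ["id", "age", "rank", "matriline", "group", "year"]


def to_graph(edges: pd.DataFrame, nodes: pd.DataFrame) -> nx.Graph:
    """Build an undirected weighted graph from edge and node tables."""
    g = nx.Graph()
    for _, row in nodes.iterrows():
        attrs = {c: row[c] for c in nodes.columns if c != "id"}
        g.add_node(row["id"], **attrs)
    for _, row in edges.iterrows():
        w = float(row["weight"])
        if w <= 0:
            raise ValueError(
                f"edge ({row['id_a']}, {row['id_b']}) has nonpositive weight {w}"
            )
        g.add_edge(row["id_a"], row["id_b"], weight=w)
    if "group" in nodes.columns and len(nodes):
        g.graph["group"] = nodes["group"].iloc[0]
    if "year" in nodes.columns and len(nodes):
        g.graph["year"] = nodes["year"].iloc[0]
    return g


def graph_to_tables(g: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`to_graph`: (edges, nodes) tables."""
    edges = pd.DataFrame(
        [
            {"id_a": u, "id_b": v, "weight": d.get("weight", 1.0)}
            for u, v, d in g.edges(data=True)
        ],
        columns=EDGE_COLUMNS,
    )
    nodes = pd.DataFrame(
        [{"id": v, **d} for v, d in g.nodes(data=True)]
    )
    return edges, nodes


def read_network(edge_path: str | Path, node_path: str | Path) -> nx.Graph:
    return to_graph(pd.read_csv(edge_path), pd.read_csv(node_path))


def write_network(
    g: nx.Graph, edge_path: str | Path, node_path: str | Path
) -> None:
    edges, nodes = graph_to_tables(g)
    edges.to_csv(edge_path, index=False)
    nodes.to_csv(node_path, index=False)


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
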