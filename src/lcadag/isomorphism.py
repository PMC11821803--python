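"""Isomorphism checks between small DAGs (test utility).

Network isomorphism here is always up to inner-vertex labels but fixing the
leaf labels (the taxa are the observable data).  When both DAGs have
pairwise distinct clusters -- which is guaranteed for lca-relevant outputs
-- the canonical labelling v -> C(v) decides isomorphism directly; otherwise
a generic VF2 search (via networkx) is used.  Intended for small instances
in tests and post-condition checks, not for large graphs.
"""

from __future__ import annotations

import networkx as nx

from .dag_core import DAG

__all__ = ["to_networkx", "cluster_isomorphic", "dags_isomorphic"]


def to_networkx(G: DAG) -> "nx.DiGraph":
    g = nx.DiGraph()
    for v in G.vertices:
        g.add_node(v, leaf_label=v if v in G.leaves else None)
    g.add_edges_from(G.edges)
    return g


def _clusters_distinct(G: DAG) -> bool:
    return len({G.cluster_of(v) for v in G.vertices}) == len(G.vertices)


def cluster_isomorphic(G: DAG, H: DAG) -> bool:
    """Isomorphism via the canonical cluster labelling v -> C(v).

    Requires pairwise distinct clusters in both DAGs (raises otherwise).
    Two such DAGs are isomorphic with fixed leaf labels iff they have the
    same cluster system and their edges induce the same cluster pairs.
    """
    if not (_clusters_distinct(G) and _clusters_distinct(H)):
        raise ValueError("canonical cluster labelling needs pairwise distinct clusters")
    if G.leaves != H.leaves:
        return False
    if G.cluster_system().clusters != H.cluster_system().clusters:
        return False
    ge = {(G.cluster_of(u), G.cluster_of(v)) for u, v in G.edges}
    he = {(H.cluster_of(u), H.cluster_of(v)) for u, v in H.edges}
    return ge == he


def dags_isomorphic(G: DAG, H: DAG, fix_leaf_labels: bool = True) -> bool:
    """Generic isomorphism test; leaf labels are fixed by default."""
    if G.leaves != H.leaves and fix_leaf_labels:
        return False
    if len(G.vertices) != len(H.vertices) or len(G.edges) != len(H.edges):
        return False
    if _clusters_distinct(G) and _clusters_distinct(H) and fix_leaf_labels:
        return cluster_isomorphic(G, H)
    if fix_leaf_labels:
        node_match = lambda a, b: a["leaf_label"] == b["leaf_label"]  # noqa: E731
    else:
        node_match = None
    return nx.is_isomorphic(to_networkx(G), to_networkx(H), node_match=node_match)
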