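"""Shared instance corpus and helpers for the test suite.

All test inputs are generated programmatically: named worked examples,
seeded random DAGs and galled trees, Hasse diagrams, trees with injected
redundancy, and vertex-cover gadget instances.
"""

from __future__ import annotations

import random
from itertools import combinations

import pytest

from lcadag import (
    DAG,
    ClusterSystem,
    fixture,
    hasse,
    random_dag,
    random_galled_tree,
    vc_gadget_LCA,
    UndirectedGraph,
)

# ---------------------------------------------------------------------------
# enumeration and generation helpers (importable via the fixtures below)
# ---------------------------------------------------------------------------

FIG1_SYSTEM = ClusterSystem(
    frozenset("xyz"),
    frozenset(
        {
            frozenset("x"),
            frozenset("y"),
            frozenset("z"),
            frozenset("xy"),
            frozenset("xyz"),
        }
    ),
)

THREE_OVERLAP_SYSTEM = ClusterSystem(
    frozenset("abc"),
    frozenset(
        {
            frozenset("a"),
            frozenset("b"),
            frozenset("c"),
            frozenset("ab"),
            frozenset("bc"),
            frozenset("ac"),
            frozenset("abc"),
        }
    ),
)


def enumerate_small_dags(max_n: int = 4):
    """Every DAG on up to ``max_n`` vertices, up to isomorphism and beyond.

    With vertices fixed in a topological order a..?, every labelled edge set
    drawn from the forward pairs yields a DAG, and every DAG on n vertices is
    isomorphic to one of these.
    """
    labels = "abcdefgh"
    for n in range(1, max_n + 1):
        vs = list(labels[:n])
        pairs = [(vs[i], vs[j]) for i in range(n) for j in range(i + 1, n)]
        for r in range(len(pairs) + 1):
            for chosen in combinations(pairs, r):
                yield DAG(vs, chosen)


def tree_with_redundancy(seed: int, n_leaves: int = 5):
    """A tree-reachability DAG with (CL) and a hierarchical cluster system.

    A random binary tree is inflated with subdivision vertices (in-degree 1,
    out-degree 1, hence never unique LCAs) and with shortcut edges; neither
    operation changes reachability between original vertices or the cluster
    system, so the result keeps the (CL) property while failing strong-(CL).
    """
    rng = random.Random(seed)
    tree = random_galled_tree(n_leaves, 0, seed)
    vertices = set(tree.vertices)
    edges = set(tree.edges)
    # subdivide a few random edges
    for i, e in enumerate(sorted(edges)):
        if rng.random() < 0.35:
            u, v = e
            s = f"s{i}"
            vertices.add(s)
            edges.discard(e)
            edges.update({(u, s), (s, v)})
    G = DAG(vertices, edges)
    # add genuine shortcut edges (a bypassed path of length >= 2 must exist)
    candidates = [
        (u, w)
        for u in sorted(G.vertices)
        for w in sorted(G.descendants(u) - {u})
        if (u, w) not in G.edges
        and any(w in G.descendants(c) for c in G.children(u))
    ]
    extra = [e for e in candidates if rng.random() < 0.25]
    if candidates and not extra:
        extra = [rng.choice(candidates)]
    return DAG(vertices, edges | set(extra))


def atlas_vc_instances():
    """Every connected, non-star graph on 4..6 vertices (one per iso class)."""
    from networkx.generators.atlas import graph_atlas_g

    out = []
    for g in graph_atlas_g():
        n = g.number_of_nodes()
        if not 4 <= n <= 6:
            continue
        if g.number_of_edges() < 2:
            continue
        import networkx as nx

        if not nx.is_connected(g):
            continue
        H = UndirectedGraph(
            frozenset(str(v) for v in g.nodes),
            frozenset(frozenset((str(u), str(v))) for u, v in g.edges),
        )
        if H.is_star():
            continue
        out.append(H)
    return out


def build_corpus():
    """The mixed corpus used by the characterization cross-checks."""
    corpus = [
        ("cherry", fixture("cherry")),
        ("pq_dag", fixture("pq_dag")),
        ("hasse_xy", fixture("hasse_xy")),
        ("galled_cor710", fixture("galled_cor710")),
        ("galled_cor710_x4", fixture("galled_cor710_x4")),
        ("chain_hasse_13", fixture("chain_hasse", indices={1, 3})),
        ("chain_hasse_124", fixture("chain_hasse", indices={1, 2, 4})),
        ("hasse_fig1", hasse(FIG1_SYSTEM, relabel=True).dag),
        ("hasse_3overlap", hasse(THREE_OVERLAP_SYSTEM, relabel=True).dag),
    ]
    for n in range(2, 9):
        corpus.append((f"fig6_{n}", fixture("fig6", n=n)))
    for seed in range(12):
        corpus.append((f"rand_{seed}", random_dag(4, 5, 0.35, seed)))
    for seed in range(6):
        corpus.append((f"dense_{seed}", random_dag(3, 4, 0.65, seed)))
    for seed in range(6):
        corpus.append((f"galled_{seed}", random_galled_tree(6, 2, seed)))
    for seed in range(4):
        corpus.append((f"tree_{seed}", random_galled_tree(5, 0, seed)))
    for seed in range(4):
        corpus.append((f"clh_{seed}", tree_with_redundancy(seed)))
    path4 = UndirectedGraph(
        frozenset("1234"),
        frozenset({frozenset("12"), frozenset("23"), frozenset("34")}),
    )
    cycle4 = UndirectedGraph(
        frozenset("1234"),
        frozenset(
            {frozenset("12"), frozenset("23"), frozenset("34"), frozenset("14")}
        ),
    )
    corpus.append(("vc_path4", vc_gadget_LCA(path4)))
    corpus.append(("vc_cycle4", vc_gadget_LCA(cycle4)))
    return corpus


@pytest.fixture(scope="session")
def corpus():
    return build_corpus()


@pytest.fixture(scope="session")
def small_dag_pool():
    return list(enumerate_small_dags(4))
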