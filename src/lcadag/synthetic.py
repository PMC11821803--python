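"""Construction of worked examples, random instances, and hardness gadgets.

Everything here is built programmatically: the named fixtures are the small
DAGs used throughout the package's documentation and tests (a cherry, a
two-source DAG without common ancestors, a family of double-rooted chain
diagrams, two small galled trees, ...); the random generators produce seeded
DAGs and galled trees; and the vertex-cover gadgets encode a Vertex Cover
instance into a network whose root is a k-LCA (k-lca) vertex exactly when a
cover of size k exists -- the construction behind the NP-completeness of
explicit-k queries, used here as an adversarial test generator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, Optional, Set, Tuple

from .dag_core import DAG, ClusterSystem, Label
from .errors import GraphValidationError
from .simplify import hasse

__all__ = [
    "UndirectedGraph",
    "fixture",
    "FIXTURE_NAMES",
    "vc_gadget_LCA",
    "vc_gadget_lca",
    "random_dag",
    "random_galled_tree",
]


@dataclass(frozen=True)
class UndirectedGraph:
    """A simple undirected graph (Vertex Cover instance)."""

    vertices: FrozenSet[Label]
    edges: FrozenSet[FrozenSet[Label]]

    def __post_init__(self):
        object.__setattr__(self, "vertices", frozenset(self.vertices))
        object.__setattr__(
            self, "edges", frozenset(frozenset(e) for e in self.edges)
        )
        for e in self.edges:
            if len(e) != 2:
                raise GraphValidationError(f"undirected edge must join 2 vertices: {sorted(e)}")
            if not e <= self.vertices:
                raise GraphValidationError(f"edge {sorted(e)} has unknown endpoints")

    def is_star(self) -> bool:
        """Connected with a single vertex contained in every edge."""
        if not self.edges or not self.is_connected():
            return False
        center = frozenset.intersection(*self.edges)
        return len(center) >= 1

    def is_connected(self) -> bool:
        if not self.vertices:
            return False
        seen = {next(iter(sorted(self.vertices)))}
        frontier = list(seen)
        adj: Dict[Label, Set[Label]] = {v: set() for v in self.vertices}
        for e in self.edges:
            u, w = sorted(e)
            adj[u].add(w)
            adj[w].add(u)
        while frontier:
            v = frontier.pop()
            for u in adj[v]:
                if u not in seen:
                    seen.add(u)
                    frontier.append(u)
        return seen == self.vertices

    def has_vertex_cover(self, k: int) -> bool:
        """Brute-force: is there a cover of size exactly k (k <= |V|)?

        A cover of size j < k extends to one of size k, so this is
        equivalent to the minimum cover having size at most k.
        """
        if k > len(self.vertices):
            return False
        for cand in combinations(sorted(self.vertices), k):
            w = frozenset(cand)
            if all(e & w for e in self.edges):
                return True
        return False


def _require_gadget_instance(H: UndirectedGraph) -> None:
    if len(H.vertices) < 4:
        raise GraphValidationError("gadget input needs at least 4 vertices")
    if len(H.edges) < 2:
        raise GraphValidationError("gadget input needs at least 2 edges")
    if H.is_star():
        raise GraphValidationError("gadget input must not be a star graph")


def _edge_tag(e: FrozenSet[Label]) -> str:
    return "_".join(sorted(e))


def vc_gadget_LCA(H: UndirectedGraph) -> DAG:
    """Network encoding Vertex Cover via LCA queries at the root.

    The gadget is the relabelled Hasse diagram of the clustering system
    consisting of all singletons, the complements V(H) \\ e of the edges, and
    V(H) itself.  It is a regular, shortcut-free, lca-relevant network whose
    root is a k-LCA (and k-lca) vertex, 1 < k <= |V(H)|, exactly when H has
    a vertex cover of size k.
    """
    _require_gadget_instance(H)
    V = H.vertices
    clusters = {frozenset((x,)) for x in V}
    clusters |= {V - e for e in H.edges}
    clusters.add(V)
    hd = hasse(ClusterSystem(V, frozenset(clusters)), relabel=True)
    rename = {}
    for label, cluster in hd.vertex_cluster.items():
        if cluster == V:
            rename[label] = "rho"
        elif len(cluster) == len(V) - 2 and (V - cluster) in H.edges:
            rename[label] = "r_" + _edge_tag(V - cluster)
    return hd.dag.relabel(rename)


def vc_gadget_lca(H: UndirectedGraph) -> DAG:
    """DAG encoding Vertex Cover via unique-LCA queries at an extra root r*.

    Start from the Hasse diagram of the singletons plus the edge complements
    V(H) \\ e; hang two private leaves under each complement vertex r_e (so
    every r_e is the unique LCA of its private pair); finally add a root r*
    adjacent to all original leaves.  Every vertex except r* is a {1,2}-lca
    vertex, and r* is a k-lca vertex exactly when H has a vertex cover of
    size k (1 < k <= |V(H)|).
    """
    _require_gadget_instance(H)
    V = H.vertices
    clusters = {frozenset((x,)) for x in V}
    clusters |= {V - e for e in H.edges}
    hd = hasse(ClusterSystem(V, frozenset(clusters)), relabel=True)
    rename = {}
    for label, cluster in hd.vertex_cluster.items():
        if len(cluster) >= 2 and (V - cluster) in H.edges:
            rename[label] = "r_" + _edge_tag(V - cluster)
    base = hd.dag.relabel(rename)
    vertices = set(base.vertices)
    edges = set(base.edges)
    for e in H.edges:
        tag = _edge_tag(e)
        re_label = f"r_{tag}"
        for i in (1, 2):
            leaf = f"x{i}_{tag}"
            vertices.add(leaf)
            edges.add((re_label, leaf))
    vertices.add("rstar")
    edges.update(("rstar", x) for x in V)
    return DAG(vertices, edges)


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------


def _cherry() -> DAG:
    return DAG({"w", "x", "y"}, {("w", "x"), ("w", "y")})


def _pq_dag() -> DAG:
    """Two maximal vertices p, q with C(p) = {x,y}, C(q) = {x,z}.

    Here y and z have no common ancestor at all: LCA({y, z}) is empty.
    """
    return DAG(
        {"p", "q", "x", "y", "z"},
        {("p", "x"), ("p", "y"), ("q", "x"), ("q", "z")},
    )


def _hasse_xy() -> DAG:
    """Relabelled Hasse diagram of {{x}, {x,y}}: a single edge r -> x.

    Both vertices carry the cluster {x}, so the cluster map is not injective
    and the DAG is neither phylogenetic nor regular.
    """
    return DAG({"r", "x"}, {("r", "x")})


def _fig6(n: int) -> DAG:
    """Double-rooted chain diagram on x1..xn (n >= 2).

    The Hasse diagram of the chain clustering system
    {{x1,x2}, {x1,x2,x3}, ..., X} plus all singletons, augmented with a
    second root r adjacent to every leaf.  Every LCA set of a query with
    |A| >= 2 equals {r, v_{i-1}} where i is the maximal index present, so
    the DAG is LCA-relevant but not lca-relevant.
    """
    if n < 2:
        raise GraphValidationError("the chain diagram needs n >= 2 leaves")
    leaves = [f"x{i}" for i in range(1, n + 1)]
    chain = [f"v{i}" for i in range(1, n)]
    vertices = set(leaves) | set(chain) | {"r"}
    edges = {("v1", "x1"), ("v1", "x2")}
    for i in range(2, n):
        edges.add((f"v{i}", f"v{i-1}"))
        edges.add((f"v{i}", f"x{i+1}"))
    edges.update(("r", x) for x in leaves)
    return DAG(vertices, edges)


def _galled_cor710() -> DAG:
    """Galled tree whose root is not the unique LCA of any leaf subset.

    Root rho has children u1, u2 with an extra edge (u1, u2); u1 has leaf
    child x1, u2 has leaf children x2 and x3.  Phylogenetic, satisfies (CL),
    but C(rho) = C(u1) = X, so rho is not an LCA of anything.
    """
    return DAG(
        {"rho", "u1", "u2", "x1", "x2", "x3"},
        {
            ("rho", "u1"),
            ("rho", "u2"),
            ("u1", "u2"),
            ("u1", "x1"),
            ("u2", "x2"),
            ("u2", "x3"),
        },
    )


def _galled_cor710_x4() -> DAG:
    """The galled tree above plus a fresh leaf x4 under the root.

    The extra leaf makes the root the unique LCA of e.g. {x1, x4}, so the
    network becomes lca-relevant.
    """
    G = _galled_cor710()
    return DAG(G.vertices | {"x4"}, G.edges | {("rho", "x4")})


def _chain_hasse(indices: Iterable[int]) -> DAG:
    """Hasse diagram witnessing I-lca relevance for an index set with 1 in I.

    For I = {1 = i1 < i2 < ... < il} this is the relabelled Hasse diagram of
    {{j} : 1 <= j <= il} plus {{1..j} : j in {i2..il}}; it is I-lca-relevant.
    """
    iset = sorted(set(int(k) for k in indices))
    if not iset or iset[0] != 1:
        raise GraphValidationError("the index set must contain 1")
    top = iset[-1]
    ground = frozenset(str(j) for j in range(1, top + 1))
    clusters = {frozenset((str(j),)) for j in range(1, top + 1)}
    for j in iset[1:]:
        clusters.add(frozenset(str(i) for i in range(1, j + 1)))
    return hasse(ClusterSystem(ground, frozenset(clusters)), relabel=True).dag


_FIXTURES = {
    "cherry": _cherry,
    "pq_dag": _pq_dag,
    "hasse_xy": _hasse_xy,
    "fig6": _fig6,
    "galled_cor710": _galled_cor710,
    "galled_cor710_x4": _galled_cor710_x4,
    "chain_hasse": _chain_hasse,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str, n: Optional[int] = None, indices: Optional[Iterable[int]] = None) -> DAG:
    """Build a named worked example.

    ``fig6`` takes the leaf count ``n`` (>= 2); ``chain_hasse`` takes the
    index set ``indices`` (containing 1); the remaining fixtures take no
    parameters.
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise GraphValidationError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    if name == "fig6":
        if n is None:
            raise GraphValidationError("fixture 'fig6' requires the parameter n >= 2")
        return builder(n)
    if name == "chain_hasse":
        if indices is None:
            raise GraphValidationError("fixture 'chain_hasse' requires an index set")
        return builder(indices)
    if n is not None or indices is not None:
        raise GraphValidationError(f"fixture {name!r} takes no parameters")
    return builder()


# ---------------------------------------------------------------------------
# random generators (single seeded PRNG stream per call, no global state)
# ---------------------------------------------------------------------------


def random_dag(
    n_inner: int,
    n_leaves: int,
    edge_density: float,
    seed: int,
) -> DAG:
    """A random DAG whose leaf set is exactly x1..x{n_leaves}.

    Inner vertices v1..v{n_inner} are arranged along a fixed topological
    order; each inner vertex receives every later vertex as a child
    independently with probability ``edge_density`` (at least one child is
    forced so that no inner vertex degenerates into a leaf).
    """
    if n_leaves < 1 or n_inner < 0:
        raise GraphValidationError("need n_leaves >= 1 and n_inner >= 0")
    if not 0 < edge_density <= 1:
        raise GraphValidationError("edge_density must lie in (0, 1]")
    rng = random.Random(seed)
    leaves = [f"x{i}" for i in range(1, n_leaves + 1)]
    inner = [f"v{i}" for i in range(1, n_inner + 1)]
    order = inner + leaves
    edges = []
    for i, v in enumerate(inner):
        candidates = order[i + 1 :]
        chosen = [c for c in candidates if rng.random() < edge_density]
        if not chosen:
            chosen = [rng.choice(candidates)]
        edges.extend((v, c) for c in chosen)
    return DAG(order, edges)


def _random_tree(leaves: Iterable[Label], rng: random.Random) -> DAG:
    active = sorted(leaves)
    vertices = set(active)
    edges = set()
    t = 0
    while len(active) > 1:
        t += 1
        parent = f"t{t}"
        rng.shuffle(active)
        a, b = active.pop(), active.pop()
        vertices.add(parent)
        edges.add((parent, a))
        edges.add((parent, b))
        active.append(parent)
        active.sort()
    return DAG(vertices, edges)


def random_galled_tree(n_leaves: int, n_galls: int, seed: int) -> DAG:
    """A random galled tree on x1..x{n_leaves} with ``n_galls`` galls.

    A random binary tree is generated first; each gall replaces the two
    child edges of a distinct tree vertex u by a cycle of two internally
    disjoint directed paths u -> a -> h and u -> b -> h, reattaching one
    former subtree below a and the other below h.  Each tree vertex hosts at
    most one gall, so biconnected components never merge and the result
    satisfies (N3O); this is checked before returning.
    """
    if n_leaves < 1:
        raise GraphValidationError("need n_leaves >= 1")
    if n_galls < 0:
        raise GraphValidationError("need n_galls >= 0")
    if n_galls > max(0, n_leaves - 1):
        raise GraphValidationError(
            f"infeasible parameters: at most {max(0, n_leaves - 1)} galls "
            f"fit on a binary tree with {n_leaves} leaves"
        )
    rng = random.Random(seed)
    tree = _random_tree([f"x{i}" for i in range(1, n_leaves + 1)], rng)
    vertices = set(tree.vertices)
    edges = set(tree.edges)
    usable = sorted(v for v in tree.vertices if len(tree.children(v)) >= 2)
    for g in range(1, n_galls + 1):
        u = usable.pop(rng.randrange(len(usable)))
        c1, c2 = sorted(tree.children(u))
        if rng.random() < 0.5:
            c1, c2 = c2, c1
        a, b, h = f"ga{g}", f"gb{g}", f"gh{g}"
        vertices.update((a, b, h))
        edges.discard((u, c1))
        edges.discard((u, c2))
        edges.update(
            {(u, a), (u, b), (a, h), (b, h), (h, c1), (a, c2)}
        )
    G = DAG(vertices, edges)
    if not G.satisfies_n3o():  # pragma: no cover - construction guarantees N3O
        raise AssertionError("generated galled tree violates (N3O)")
    return G
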