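"""Core data model: labelled DAGs, clusters, shortcuts, and set systems.

A DAG ``G`` on a taxon set ``X`` is a directed acyclic graph whose
out-degree-0 vertices (the *leaves*, ``L(G)``) are identified with ``X``.
Every vertex ``v`` carries its *hardwired cluster* ``C_G(v)``: the set of
leaves reachable from ``v`` by directed paths.  The reachability relation
``v <= u`` ("u is an ancestor of v") is the reflexive partial order induced
by directed paths.

DAGs here are immutable values: every structural edit (shortcut removal,
vertex suppression, relabelling) returns a new :class:`DAG`, so all derived
structure (topological order, reachability, clusters) is computed once and
cached on the instance.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Tuple

from .errors import (
    GraphValidationError,
    InvalidEdgeError,
    NotADAGError,
    UnknownVertexError,
)

__all__ = ["DAG", "ClusterSystem", "build_dag", "sets_overlap"]

Label = str
Edge = Tuple[Label, Label]


def sets_overlap(m: FrozenSet[Label], m2: FrozenSet[Label]) -> bool:
    """Two sets *overlap* if their intersection is nonempty and proper in both."""
    inter = m & m2
    return bool(inter) and inter != m and inter != m2


class DAG:
    """An immutable directed acyclic graph with string vertex labels.

    Vertex identity is the label; two DAGs are equal exactly when they have
    the same vertex set and the same edge set.  Multiple roots and
    disconnected graphs are first class: no implicit super-root is added.
    """

    __slots__ = (
        "_vertices",
        "_edges",
        "_children",
        "_parents",
        "_topo",
        "_leaves",
        "_roots",
        "_desc",
        "_anc",
        "_clusters",
        "_n3o",
        "_hash",
    )

    def __init__(self, vertices: Iterable[Label], edges: Iterable[Edge] = ()):
        vs = frozenset(vertices)
        if not vs:
            raise GraphValidationError("a DAG needs at least one vertex")
        children: Dict[Label, set] = {v: set() for v in vs}
        parents: Dict[Label, set] = {v: set() for v in vs}
        es = set()
        for e in edges:
            u, w = e
            if u == w:
                raise InvalidEdgeError(f"invalid edge: self-loop at {u!r}")
            if u not in vs or w not in vs:
                raise UnknownVertexError(f"unknown vertex in edge ({u!r}, {w!r})")
            es.add((u, w))
            children[u].add(w)
            parents[w].add(u)
        self._vertices = vs
        self._edges = frozenset(es)
        self._children = {v: frozenset(c) for v, c in children.items()}
        self._parents = {v: frozenset(p) for v, p in parents.items()}
        self._topo = self._kahn()
        self._leaves = frozenset(v for v in vs if not self._children[v])
        self._roots = frozenset(v for v in vs if not self._parents[v])
        self._desc: Optional[Dict[Label, FrozenSet[Label]]] = None
        self._anc: Optional[Dict[Label, FrozenSet[Label]]] = None
        self._clusters: Optional[Dict[Label, FrozenSet[Label]]] = None
        self._n3o: Optional[bool] = None
        self._hash: Optional[int] = None

    # -- construction helpers -------------------------------------------------

    def _kahn(self) -> Tuple[Label, ...]:
        """Topological order (ancestors first), lexicographic tie-break.

        The lexicographic heap makes every order-dependent downstream
        computation (notably the processing order of Algorithm 3)
        deterministic.
        """
        indeg = {v: len(self._parents[v]) for v in self._vertices}
        heap = [v for v, d in indeg.items() if d == 0]
        heapq.heapify(heap)
        order = []
        while heap:
            v = heapq.heappop(heap)
            order.append(v)
            for u in self._children[v]:
                indeg[u] -= 1
                if indeg[u] == 0:
                    heapq.heappush(heap, u)
        if len(order) != len(self._vertices):
            raise NotADAGError("not a DAG: the edge set contains a directed cycle")
        return tuple(order)

    # -- basic accessors ------------------------------------------------------

    @property
    def vertices(self) -> FrozenSet[Label]:
        return self._vertices

    @property
    def edges(self) -> FrozenSet[Edge]:
        return self._edges

    @property
    def leaves(self) -> FrozenSet[Label]:
        """L(G): the out-degree-0 vertices (the taxon set X)."""
        return self._leaves

    @property
    def roots(self) -> FrozenSet[Label]:
        """R(G): the in-degree-0 vertices."""
        return self._roots

    @property
    def topological_order(self) -> Tuple[Label, ...]:
        return self._topo

    def children(self, v: Label) -> FrozenSet[Label]:
        self._check_vertex(v)
        return self._children[v]

    def parents(self, v: Label) -> FrozenSet[Label]:
        self._check_vertex(v)
        return self._parents[v]

    def out_degree(self, v: Label) -> int:
        return len(self.children(v))

    def in_degree(self, v: Label) -> int:
        return len(self.parents(v))

    def is_network(self) -> bool:
        """A (rooted) network is a DAG with a single root."""
        return len(self._roots) == 1

    def _check_vertex(self, v: Label) -> None:
        if v not in self._vertices:
            raise UnknownVertexError(f"unknown vertex {v!r}")

    # -- order / reachability -------------------------------------------------

    def _descendant_map(self) -> Dict[Label, FrozenSet[Label]]:
        if self._desc is None:
            desc: Dict[Label, FrozenSet[Label]] = {}
            for v in reversed(self._topo):
                s = {v}
                for u in self._children[v]:
                    s.update(desc[u])
                desc[v] = frozenset(s)
            self._desc = desc
        return self._desc

    def _ancestor_map(self) -> Dict[Label, FrozenSet[Label]]:
        if self._anc is None:
            anc: Dict[Label, FrozenSet[Label]] = {}
            for v in self._topo:
                s = {v}
                for p in self._parents[v]:
                    s.update(anc[p])
                anc[v] = frozenset(s)
            self._anc = anc
        return self._anc

    def descendants(self, v: Label) -> FrozenSet[Label]:
        """All u with u <= v (reflexive)."""
        self._check_vertex(v)
        return self._descendant_map()[v]

    def ancestors(self, v: Label) -> FrozenSet[Label]:
        """All u with v <= u (reflexive)."""
        self._check_vertex(v)
        return self._ancestor_map()[v]

    def is_ancestor(self, u: Label, v: Label) -> bool:
        """True iff v <= u, i.e. there is a directed path (possibly empty) u -> v."""
        self._check_vertex(u)
        self._check_vertex(v)
        return v in self._descendant_map()[u]

    def comparable(self, u: Label, v: Label) -> bool:
        return self.is_ancestor(u, v) or self.is_ancestor(v, u)

    # -- clusters -------------------------------------------------------------

    def _cluster_map(self) -> Dict[Label, FrozenSet[Label]]:
        if self._clusters is None:
            leaves = self._leaves
            clusters: Dict[Label, FrozenSet[Label]] = {}
            # reverse topological order: children before parents; the cluster
            # of an inner vertex is the union of its children's clusters
            for v in reversed(self._topo):
                if v in leaves:
                    clusters[v] = frozenset((v,))
                else:
                    s: set = set()
                    for u in self._children[v]:
                        s.update(clusters[u])
                    clusters[v] = frozenset(s)
            self._clusters = clusters
        return self._clusters

    def cluster_of(self, v: Label) -> FrozenSet[Label]:
        """C_G(v): the descendant leaves of v."""
        self._check_vertex(v)
        return self._cluster_map()[v]

    def cluster_system(self) -> "ClusterSystem":
        """The set system C_G = {C_G(v) : v in V(G)} on L(G); always grounded."""
        return ClusterSystem(self._leaves, frozenset(self._cluster_map().values()))

    def satisfies_n3o(self) -> bool:
        """True iff no three clusters of G pairwise overlap (cached)."""
        if self._n3o is None:
            self._n3o = self.cluster_system().satisfies_n3o()
        return self._n3o

    # -- shortcuts ------------------------------------------------------------

    def shortcuts(self) -> FrozenSet[Edge]:
        """All edges (u, w) bypassed by a directed u->w path of length >= 2."""
        desc = self._descendant_map()
        out = set()
        for u, w in self._edges:
            for c in self._children[u]:
                if c != w and w in desc[c]:
                    out.add((u, w))
                    break
        return frozenset(out)

    def remove_shortcuts(self) -> "DAG":
        """G^-: delete every shortcut.

        The result is shortcut-free, independent of any deletion order, and
        preserves reachability and all clusters.
        """
        sc = self.shortcuts()
        if not sc:
            return self
        return DAG(self._vertices, self._edges - sc)

    # -- phylogenetic predicate -----------------------------------------------

    def is_phylogenetic(self) -> bool:
        """True iff no vertex has out-degree 1 and in-degree <= 1."""
        return not any(
            len(self._children[v]) == 1 and len(self._parents[v]) <= 1
            for v in self._vertices
        )

    # -- structural edits (return new DAGs) ------------------------------------

    def relabel(self, mapping: Mapping[Label, Label]) -> "DAG":
        """Rename vertices; labels not in ``mapping`` are kept."""
        full = {v: mapping.get(v, v) for v in self._vertices}
        if len(set(full.values())) != len(self._vertices):
            raise GraphValidationError("relabelling must be injective")
        return DAG(full.values(), ((full[u], full[w]) for u, w in self._edges))

    def permute_leaves(self, sigma: Mapping[Label, Label]) -> "DAG":
        """Apply a permutation of the leaf labels (inner labels untouched)."""
        if set(sigma) != set(self._leaves) or set(sigma.values()) != set(self._leaves):
            raise GraphValidationError("sigma must be a permutation of the leaf set")
        return self.relabel(sigma)

    # -- value semantics --------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DAG):
            return NotImplemented
        return self._vertices == other._vertices and self._edges == other._edges

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self._vertices, self._edges))
        return self._hash

    def __repr__(self) -> str:  # pragma: no cover
        return f"DAG(|V|={len(self._vertices)}, |E|={len(self._edges)}, |L|={len(self._leaves)})"


def build_dag(vertex_labels: Iterable[Label], edge_pairs: Iterable[Edge] = ()) -> DAG:
    """Validate and build a :class:`DAG` (acyclicity checked eagerly)."""
    return DAG(vertex_labels, edge_pairs)


@dataclass(frozen=True)
class ClusterSystem:
    """A ground set X together with a family of nonempty subsets of X."""

    ground_set: FrozenSet[Label]
    clusters: FrozenSet[FrozenSet[Label]]

    def __post_init__(self):
        object.__setattr__(self, "ground_set", frozenset(self.ground_set))
        object.__setattr__(
            self, "clusters", frozenset(frozenset(c) for c in self.clusters)
        )
        for c in self.clusters:
            if not c:
                raise GraphValidationError("the empty set is not a valid cluster")
            if not c <= self.ground_set:
                raise GraphValidationError(
                    f"cluster {sorted(c)} is not a subset of the ground set"
                )

    def is_grounded(self) -> bool:
        """All singletons {x}, x in X, are present (and the empty set is not)."""
        return all(frozenset((x,)) in self.clusters for x in self.ground_set)

    def is_clustering_system(self) -> bool:
        """Grounded and contains the full ground set X."""
        return self.is_grounded() and self.ground_set in self.clusters

    def find_overlapping_pair(self) -> Optional[Tuple[FrozenSet[Label], FrozenSet[Label]]]:
        for c1, c2 in combinations(self.clusters, 2):
            if sets_overlap(c1, c2):
                return (c1, c2)
        return None

    def is_hierarchy(self) -> bool:
        """A clustering system without any overlapping pair of clusters."""
        return self.is_clustering_system() and self.find_overlapping_pair() is None

    def find_overlapping_triple(
        self,
    ) -> Optional[Tuple[FrozenSet[Label], FrozenSet[Label], FrozenSet[Label]]]:
        """A witness for the failure of (N3O): three pairwise overlapping clusters."""
        cs = sorted(self.clusters, key=lambda c: (len(c), sorted(c)))
        for c1, c2, c3 in combinations(cs, 3):
            if (
                sets_overlap(c1, c2)
                and sets_overlap(c1, c3)
                and sets_overlap(c2, c3)
            ):
                return (c1, c2, c3)
        return None

    def satisfies_n3o(self) -> bool:
        """(N3O): the family contains no three pairwise overlapping clusters."""
        return self.find_overlapping_triple() is None

    def restrict(self, trace_set: Iterable[Label]) -> "ClusterSystem":
        """Traces C & Y of all clusters on Y, dropping empty traces."""
        y = frozenset(trace_set)
        if not y <= self.ground_set:
            raise GraphValidationError("trace set must be a subset of the ground set")
        traces = frozenset(c & y for c in self.clusters if c & y)
        return ClusterSystem(y, traces)

    def __contains__(self, item) -> bool:
        return frozenset(item) in self.clusters

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)
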