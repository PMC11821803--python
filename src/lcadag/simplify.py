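"""Vertex suppression and simplification of DAGs into LCA-/lca-relevant form.

The suppression operator ``G (-) v`` removes a vertex and joins each of its
parents to each of its children.  Suppressing only inner vertices preserves
the leaf set, the ancestor order among surviving vertices, and every
surviving vertex's cluster; suppressing only non-LCA (non-lca) vertices
additionally preserves all LCA (well-defined lca) answers.  These are the
structural guarantees (S0)-(S5):

    S0  no new clusters,
    S1  same leaf set,
    S2  no new vertices,
    S3  ancestor order preserved on surviving vertices,
    S4  well-defined lca answers preserved,
    S5  LCA sets preserved.

Two simplification algorithms are provided.  ``make_LCA_relevant`` removes,
in one pass over the *input* DAG, every vertex that is not an LCA of its own
cluster; the removal set is the unique minimum one subject to (S0)-(S5).
``make_lca_relevant`` walks the vertices in a fixed deterministic order and
suppresses, *re-evaluating on the current DAG*, every vertex that is not the
unique LCA of its cluster; on inputs with the (CL) or (PCC) property the
removal set coincides with the first algorithm's and the cluster system is
preserved exactly.

On top of these sit the shortcut-erasing transformations ``phi_LCA`` and
``phi_lca`` and the cluster-restriction ``G | Y`` (the Hasse diagram of the
cluster traces on Y), which together satisfy the simplification axioms:
(P1) fixpoints are left alone, (P2) equivariance under leaf relabelling,
(P3) commutation with restriction.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

from .dag_core import DAG, ClusterSystem, Label
from .errors import GraphValidationError, UnknownVertexError
from .lca_engine import in_lca_set, lca_set
from .properties import has_cl

__all__ = [
    "ominus",
    "ominus_set",
    "SimplificationReport",
    "make_LCA_relevant",
    "make_lca_relevant",
    "HasseDiagram",
    "hasse",
    "cluster_label",
    "phi_LCA",
    "phi_lca",
    "cluster_restriction",
    "verify_s_properties",
]

logger = logging.getLogger(__name__)


def ominus(G: DAG, v: Label) -> DAG:
    """Suppress v: delete it and connect each parent of v to each child of v.

    Roots and leaves are simply deleted (they have no parents/children to
    reconnect).  The operator commutes with itself, so iterated application
    to a set of vertices is order-independent.
    """
    if v not in G.vertices:
        raise UnknownVertexError(f"unknown vertex {v!r}")
    if len(G.vertices) < 2:
        raise GraphValidationError("cannot remove the only vertex of a DAG")
    ps, cs = G.parents(v), G.children(v)
    edges = {e for e in G.edges if v not in e}
    edges.update((p, q) for p in ps for q in cs)
    return DAG(G.vertices - {v}, edges)


def ominus_set(G: DAG, W: Iterable[Label]) -> DAG:
    """Iterated suppression G (-) W (well-defined: order does not matter)."""
    ws = frozenset(W)
    unknown = ws - G.vertices
    if unknown:
        raise UnknownVertexError(f"unknown vertices {sorted(unknown)}")
    if ws == G.vertices:
        raise GraphValidationError("cannot remove every vertex of a DAG")
    H = G
    for v in sorted(ws):
        H = ominus(H, v)
    return H


def _query_pool(X: FrozenSet[Label], max_size: int, cap: int) -> list:
    """All leaf subsets with 1 <= |A| <= max_size, or a deterministic sample."""
    xs = sorted(X)
    total = sum(comb(len(xs), k) for k in range(1, max_size + 1))
    if total <= cap:
        pool = []
        for k in range(1, max_size + 1):
            pool.extend(frozenset(c) for c in combinations(xs, k))
        return pool
    rng = random.Random(0)
    pool = set()
    while len(pool) < cap:
        k = rng.randint(1, max_size)
        pool.add(frozenset(rng.sample(xs, k)))
    return sorted(pool, key=lambda s: (len(s), sorted(s)))


def verify_s_properties(
    G: DAG,
    H: DAG,
    *,
    max_query_size: int = 3,
    query_cap: int = 400,
) -> Dict[str, bool]:
    """Check the structural guarantees (S0)-(S5) of H with respect to G.

    S4/S5 are verified over all leaf subsets of size at most
    ``max_query_size`` (or a deterministic sample of ``query_cap`` subsets
    on large leaf sets).
    """
    flags: Dict[str, bool] = {}
    flags["S1"] = H.leaves == G.leaves
    flags["S2"] = H.vertices <= G.vertices
    flags["S3"] = all(
        G.is_ancestor(u, w) == H.is_ancestor(u, w)
        for u in H.vertices
        for w in H.vertices
    )
    flags["S0"] = H.cluster_system().clusters <= G.cluster_system().clusters
    s4 = s5 = True
    for q in _query_pool(G.leaves, max_query_size, query_cap):
        rg = lca_set(G, q)
        rh = lca_set(H, q)
        if rg.members != rh.members:
            s5 = False
        if rg.well_defined and rg.unique != rh.unique:
            s4 = False
        if not s4 and not s5:
            break
    flags["S4"] = s4
    flags["S5"] = s5
    return flags


@dataclass(frozen=True)
class SimplificationReport:
    """Outcome of a simplification run."""

    input: DAG
    output: DAG
    removed: Tuple[Label, ...]
    mode: str
    s_flags: Optional[Mapping[str, bool]] = None
    shortcut_removal_applied: bool = False

    @property
    def removed_set(self) -> FrozenSet[Label]:
        return frozenset(self.removed)


def make_LCA_relevant(G: DAG, *, verify: bool = True) -> SimplificationReport:
    """Suppress every vertex that is not an LCA of any leaf subset.

    The condition ``v not in LCA_G(C_G(v))`` is evaluated entirely on the
    input DAG (valid because LCA sets are preserved throughout the removal).
    The resulting DAG is LCA-relevant, phylogenetic, has exactly the input's
    cluster system, and the removal set is the unique minimum one subject to
    (S0)-(S5).  Connectivity is preserved.
    """
    leaves = G.leaves
    removed = tuple(
        v
        for v in G.topological_order
        if v not in leaves and not in_lca_set(G, v, G.cluster_of(v))
    )
    H = ominus_set(G, removed) if removed else G
    flags = verify_s_properties(G, H) if verify else None
    return SimplificationReport(G, H, removed, "LCA", flags)


def make_lca_relevant(
    G: DAG,
    *,
    verify: bool = True,
    order: Optional[Sequence[Label]] = None,
) -> SimplificationReport:
    """Suppress vertices until every vertex is the unique LCA of some subset.

    Vertices are visited in the input DAG's topological order (ancestors
    first, lexicographic tie-break) unless ``order`` is given; the condition
    ``v != lca(C(v))`` is re-evaluated on the *current* DAG at each step, so
    vertices that become unique LCAs after earlier removals are kept.  The
    ancestors-first default removes superfluous extra roots before their
    descendants, which keeps the preserved cluster set large.  The output is
    lca-relevant, phylogenetic, satisfies (S0)-(S4), and stays connected if
    the input is connected.
    """
    seq = tuple(order) if order is not None else G.topological_order
    if frozenset(seq) != G.vertices or len(seq) != len(G.vertices):
        raise GraphValidationError("order must enumerate every vertex exactly once")
    leaves = G.leaves
    current = G
    removed = []
    for v in seq:
        if v in leaves:
            continue
        if lca_set(current, current.cluster_of(v)).unique != v:
            current = ominus(current, v)
            removed.append(v)
    flags = verify_s_properties(G, current) if verify else None
    return SimplificationReport(G, current, tuple(removed), "lca", flags)


def cluster_label(cluster: Iterable[Label]) -> Label:
    """Canonical string label for a cluster vertex of a Hasse diagram."""
    return "{" + ",".join(sorted(cluster)) + "}"


@dataclass(frozen=True)
class HasseDiagram:
    """Hasse diagram of a set system, as a DAG over cluster labels.

    ``vertex_cluster`` maps each vertex label back to the cluster it stands
    for.  In the relabelled form each singleton vertex {x} is renamed to x,
    so that (for grounded systems) the diagram's own cluster system equals
    the input system.
    """

    dag: DAG
    vertex_cluster: Mapping[Label, FrozenSet[Label]]
    relabeled: bool = False


def hasse(system: ClusterSystem, relabel: bool = False) -> HasseDiagram:
    """Cover digraph of strict inclusion: edge A -> B iff B is covered by A."""
    clusters = system.clusters
    if not clusters:
        raise GraphValidationError("cannot build the Hasse diagram of an empty family")
    if relabel and not system.is_grounded():
        raise GraphValidationError(
            "relabelling requires a grounded system (all singletons present)"
        )

    def name(c: FrozenSet[Label]) -> Label:
        if relabel and len(c) == 1:
            return next(iter(c))
        return cluster_label(c)

    labels = {c: name(c) for c in clusters}
    if len(set(labels.values())) != len(clusters):
        raise GraphValidationError("cluster labels collide")  # pragma: no cover
    edges = []
    for a, b in combinations(clusters, 2):
        if b < a:
            hi, lo = a, b
        elif a < b:
            hi, lo = b, a
        else:
            continue
        if not any(lo < c < hi for c in clusters):
            edges.append((labels[hi], labels[lo]))
    dag = DAG(labels.values(), edges)
    return HasseDiagram(dag, {labels[c]: c for c in clusters}, relabel)


def phi_LCA(G: DAG) -> DAG:
    """Simplification map: suppress all non-LCA vertices, then drop shortcuts.

    The image is the class of shortcut-free LCA-relevant DAGs, on which the
    map is the identity; it is idempotent and preserves the cluster system.
    """
    return make_LCA_relevant(G, verify=False).output.remove_shortcuts()


def phi_lca(G: DAG) -> DAG:
    """Suppress all non-lca vertices of G (one pass), then drop shortcuts.

    On inputs with the (CL) or (PCC) property this coincides with
    :func:`phi_LCA` and yields a DAG isomorphic to the Hasse diagram of the
    input's cluster system.  Without (CL) the simplification axioms are not
    guaranteed (a warning is logged) but the result is still informative.
    """
    if not has_cl(G):
        logger.warning(
            "phi_lca applied to a DAG without the (CL) property: "
            "axioms (P1)-(P3) and cluster preservation are not guaranteed"
        )
    leaves = G.leaves
    removed = [
        v
        for v in G.topological_order
        if v not in leaves and lca_set(G, G.cluster_of(v)).unique != v
    ]
    H = ominus_set(G, removed) if removed else G
    return H.remove_shortcuts()


def cluster_restriction(G: DAG, Y: Iterable[Label]) -> DAG:
    """G | Y: the relabelled Hasse diagram of the nonempty traces C & Y.

    The trace system is grounded on Y, so the result is always a regular
    (hence shortcut-free, lca-relevant, phylogenetic) DAG on Y.
    """
    y = frozenset(Y)
    if not y:
        raise GraphValidationError("the restriction leaf set must be nonempty")
    if not y <= G.leaves:
        raise GraphValidationError(
            f"restriction labels {sorted(y - G.leaves)} are not leaves of G"
        )
    traces = G.cluster_system().restrict(y)
    return hasse(traces, relabel=True).dag
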