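"""Least-common-ancestor queries and k-LCA / k-lca vertex tests.

For a DAG ``G`` on ``X`` and a nonempty ``A`` subset of ``X``, the set
``LCA_G(A)`` comprises the reachability-minimal common ancestors of ``A``.
Unlike in trees, ``LCA_G(A)`` may be empty (no common ancestor) or contain
several incomparable vertices; ``lca_G(A)`` is *well-defined* only when the
set is a singleton.

The central routine :func:`lca_set` is a single topological sweep that
maintains, for each vertex ``v``, the residue ``A \\ C_G(v)``; a vertex
belongs to ``LCA_G(A)`` exactly when its own residue is empty while every
child's residue is nonempty.  It runs in ``O((|V|+|E|) |A|)`` time.  A
definition-faithful brute-force oracle (:func:`lca_bruteforce`) is provided
for testing and never used by the algorithms themselves.

Explicit-k queries ("is v an LCA of some A with |A| = k?") are NP-complete
in general; they are answered by a guarded subset search, with a
polynomial-time fast path for DAGs whose cluster systems contain no three
pairwise overlapping clusters (N3O), which covers trees and galled trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import FrozenSet, Iterable, Optional, Tuple, Union

from .dag_core import DAG, Label
from .errors import InvalidQueryError, UnknownVertexError, WorkBoundExceededError

__all__ = [
    "UNDEFINED",
    "LCAResult",
    "IndexSet",
    "lca_set",
    "lca_bruteforce",
    "unique_lca",
    "in_lca_set",
    "is_some_k_LCA",
    "is_some_k_lca",
    "is_k_LCA",
    "is_k_lca",
    "some_k_interval",
    "DEFAULT_WORK_BOUND",
]

#: Default cap on the number of candidate subsets enumerated by explicit-k
#: queries outside the N3O fast path.
DEFAULT_WORK_BOUND = 10**6


class _Undefined:
    """Typed sentinel for an lca that is not well-defined."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = _Undefined()


@dataclass(frozen=True)
class LCAResult:
    """The set LCA_G(A) together with the well-definedness flag."""

    members: FrozenSet[Label]

    @property
    def well_defined(self) -> bool:
        return len(self.members) == 1

    @property
    def unique(self) -> Union[Label, _Undefined]:
        if self.well_defined:
            return next(iter(self.members))
        return UNDEFINED


@dataclass(frozen=True)
class IndexSet:
    """A set of admissible query sizes for I-LCA / I-lca relevance questions."""

    indices: FrozenSet[int]

    def __post_init__(self):
        object.__setattr__(self, "indices", frozenset(int(k) for k in self.indices))
        if not self.indices:
            raise ValueError("an index set must be nonempty")
        if any(k < 1 for k in self.indices):
            raise ValueError("index sets contain positive integers only")

    @property
    def one_included(self) -> bool:
        return 1 in self.indices

    def __iter__(self):
        return iter(sorted(self.indices))

    def __contains__(self, k: int) -> bool:
        return k in self.indices


def _validated_query(G: DAG, A: Iterable[Label]) -> FrozenSet[Label]:
    q = frozenset(A)
    if not q:
        raise InvalidQueryError("empty query: A must be a nonempty subset of L(G)")
    bad = q - G.leaves
    if bad:
        raise InvalidQueryError(f"non-leaf in query: {sorted(bad)}")
    return q


def lca_set(G: DAG, A: Iterable[Label]) -> LCAResult:
    """Compute LCA_G(A) by a single reverse-topological sweep.

    The residue ``C[v] = A \\ C_G(v)`` is built bottom-up (leaf: ``A \\ {v}``;
    inner vertex: the intersection of the children's residues).  A vertex is
    reported iff its residue is empty and every child residue is nonempty.
    """
    q = _validated_query(G, A)
    if len(q) == 1:
        return LCAResult(q)
    leaves = G.leaves
    residue = {}
    members = []
    for v in reversed(G.topological_order):
        if v in leaves:
            r = q - {v}
        else:
            it = iter(G.children(v))
            r = residue[next(it)]
            for u in it:
                r = r & residue[u]
                if not r:
                    # the intersection can only shrink; keep going is pointless
                    # only for the value, but emptiness here does not yet decide
                    # membership, so simply stop intersecting
                    break
        residue[v] = r
        if not r and all(residue[u] for u in G.children(v)):
            members.append(v)
    return LCAResult(frozenset(members))


def lca_bruteforce(G: DAG, A: Iterable[Label]) -> LCAResult:
    """Definition-faithful oracle: intersect ancestor sets, keep minimal elements.

    Intended for testing only; independent of :func:`lca_set`.
    """
    q = _validated_query(G, A)
    common = None
    for x in q:
        anc = G.ancestors(x)
        common = anc if common is None else common & anc
    assert common is not None
    members = {
        v
        for v in common
        if not any(u != v and G.is_ancestor(v, u) for u in common)
    }
    return LCAResult(frozenset(members))


def unique_lca(G: DAG, A: Iterable[Label]) -> Union[Label, _Undefined]:
    """lca_G(A) when well-defined, else the UNDEFINED sentinel."""
    return lca_set(G, A).unique


def in_lca_set(G: DAG, v: Label, A: Iterable[Label]) -> bool:
    """Membership test v in LCA_G(A) without computing the whole set.

    v belongs to LCA_G(A) iff A is contained in C_G(v) and in no child
    cluster.
    """
    q = _validated_query(G, A)
    if not q <= G.cluster_of(v):
        return False
    return not any(q <= G.cluster_of(u) for u in G.children(v))


def is_some_k_LCA(G: DAG, v: Label) -> bool:
    """True iff v is a k-LCA vertex for *some* k, i.e. v in LCA_G(C_G(v)).

    Equivalently: no child of v carries the same cluster as v.
    """
    if v in G.leaves:
        return True
    cv = G.cluster_of(v)
    return not any(G.cluster_of(u) == cv for u in G.children(v))


def is_some_k_lca(G: DAG, v: Label) -> bool:
    """True iff v is a k-lca vertex for *some* k, i.e. v = lca_G(C_G(v))."""
    if v in G.leaves:
        return True
    return lca_set(G, G.cluster_of(v)).unique == v


def _check_k(G: DAG, v: Label, k: int) -> None:
    if v not in G.vertices:
        raise UnknownVertexError(f"unknown vertex {v!r}")
    if not 1 <= k <= len(G.leaves):
        raise ValueError(f"k={k} out of range 1..{len(G.leaves)}")


def _lca_members_by_clusters(G: DAG, q: FrozenSet[Label]) -> FrozenSet[Label]:
    """LCA_G(q) via the child-cluster criterion; helper for explicit-k search."""
    members = []
    for w in G.vertices:
        if q <= G.cluster_of(w) and not any(
            q <= G.cluster_of(u) for u in G.children(w)
        ):
            members.append(w)
    return frozenset(members)


def is_k_LCA(
    G: DAG,
    v: Label,
    k: int,
    *,
    method: str = "auto",
    work_bound: int = DEFAULT_WORK_BOUND,
) -> bool:
    """Is v in LCA_G(A) for some A of size exactly k?

    ``method`` selects the N3O fast path ("fastpath"), guarded subset
    enumeration ("bruteforce"), or automatic dispatch ("auto": fast path
    whenever G satisfies N3O).  For N3O DAGs the admissible sizes of an
    inner vertex form the full interval 2..|C_G(v)| as soon as the vertex is
    an LCA of anything, so a single cluster comparison decides the query.
    """
    _check_k(G, v, k)
    if k == 1:
        return v in G.leaves
    cv = G.cluster_of(v)
    if k > len(cv):
        return False
    if method == "auto":
        method = "fastpath" if G.satisfies_n3o() else "bruteforce"
    if method == "fastpath":
        if not G.satisfies_n3o():
            raise ValueError("fast path requires an N3O DAG")
        return len(cv) >= 2 and is_some_k_LCA(G, v)
    if method != "bruteforce":
        raise ValueError(f"unknown method {method!r}")
    if comb(len(cv), k) > work_bound:
        raise WorkBoundExceededError(
            f"intractable: work bound exceeded ({comb(len(cv), k)} > {work_bound} "
            f"candidate subsets for |C(v)|={len(cv)}, k={k})"
        )
    child_clusters = [G.cluster_of(u) for u in G.children(v)]
    for tup in combinations(sorted(cv), k):
        q = frozenset(tup)
        if not any(q <= cc for cc in child_clusters):
            return True
    return False


def is_k_lca(
    G: DAG,
    v: Label,
    k: int,
    *,
    method: str = "auto",
    work_bound: int = DEFAULT_WORK_BOUND,
) -> bool:
    """Is v = lca_G(A) for some A of size exactly k?"""
    _check_k(G, v, k)
    if k == 1:
        return v in G.leaves
    cv = G.cluster_of(v)
    if k > len(cv):
        return False
    if method == "auto":
        method = "fastpath" if G.satisfies_n3o() else "bruteforce"
    if method == "fastpath":
        if not G.satisfies_n3o():
            raise ValueError("fast path requires an N3O DAG")
        return is_some_k_lca(G, v)
    if method != "bruteforce":
        raise ValueError(f"unknown method {method!r}")
    if comb(len(cv), k) > work_bound:
        raise WorkBoundExceededError(
            f"intractable: work bound exceeded ({comb(len(cv), k)} > {work_bound} "
            f"candidate subsets for |C(v)|={len(cv)}, k={k})"
        )
    child_clusters = [G.cluster_of(u) for u in G.children(v)]
    for tup in combinations(sorted(cv), k):
        q = frozenset(tup)
        if any(q <= cc for cc in child_clusters):
            continue  # v not even in LCA_G(q)
        if _lca_members_by_clusters(G, q) == frozenset((v,)):
            return True
    return False


def some_k_interval(
    G: DAG,
    v: Label,
    mode: str = "LCA",
    *,
    work_bound: int = DEFAULT_WORK_BOUND,
) -> Optional[Tuple[int, int]]:
    """The interval of admissible query sizes for v, or None.

    If v is a k-LCA (k-lca) vertex for some k at all, the admissible sizes
    form an interval whose right end is |C_G(v)|.  Leaves give (1, 1).
    """
    if v not in G.vertices:
        raise UnknownVertexError(f"unknown vertex {v!r}")
    if mode not in ("LCA", "lca"):
        raise ValueError("mode must be 'LCA' or 'lca'")
    if v in G.leaves:
        return (1, 1)
    some = is_some_k_LCA(G, v) if mode == "LCA" else is_some_k_lca(G, v)
    if not some:
        return None
    hi = len(G.cluster_of(v))
    if G.satisfies_n3o():
        return (2, hi)
    test = is_k_LCA if mode == "LCA" else is_k_lca
    for k in range(2, hi + 1):
        if test(G, v, k, method="bruteforce", work_bound=work_bound):
            return (k, hi)
    # unreachable: v is admissible at k = |C_G(v)| by the 'some' check
    raise AssertionError("interval search failed despite admissibility")
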