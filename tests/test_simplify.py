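"""Vertex suppression, the two simplification algorithms, Hasse diagrams,
and the transformation axioms (fixpoint, equivariance, restriction)."""

from itertools import combinations

import pytest

from lcadag import (
    DAG,
    GraphValidationError,
    UnknownVertexError,
    build_dag,
    cluster_restriction,
    fixture,
    has_cl,
    has_pcc,
    has_strong_cl,
    hasse,
    is_LCA_relevant,
    is_lca_relevant,
    is_regular,
    make_LCA_relevant,
    make_lca_relevant,
    ominus,
    ominus_set,
    phi_LCA,
    phi_lca,
    random_dag,
    random_galled_tree,
)
from lcadag.isomorphism import cluster_isomorphic, dags_isomorphic
from lcadag.simplify import verify_s_properties

from conftest import FIG1_SYSTEM, tree_with_redundancy


class TestOminus:
    def test_path_suppression(self):
        G = build_dag("abc", {("a", "b"), ("b", "c")})
        assert ominus(G, "b").edges == {("a", "c")}

    def test_cherry_root_removal_disconnects(self):
        H = ominus(fixture("cherry"), "w")
        assert H.vertices == {"x", "y"}
        assert H.edges == frozenset()

    def test_unknown_vertex(self):
        with pytest.raises(UnknownVertexError):
            ominus(fixture("cherry"), "zz")

    def test_only_vertex_rejected(self):
        with pytest.raises(GraphValidationError):
            ominus(DAG({"x"}), "x")

    def test_commutes(self):
        for seed in range(25):
            G = random_dag(3, 4, 0.5, seed)
            inner = sorted(G.vertices - G.leaves)
            for u, v in combinations(inner, 2):
                assert ominus(ominus(G, u), v) == ominus(ominus(G, v), u)

    def test_inner_suppression_preserves_order_and_clusters(self):
        for seed in range(20):
            G = random_dag(4, 4, 0.45, seed)
            for v in sorted(G.vertices - G.leaves):
                H = ominus(G, v)
                assert H.leaves == G.leaves
                for a in H.vertices:
                    assert H.cluster_of(a) == G.cluster_of(a)
                    for b in H.vertices:
                        assert H.is_ancestor(a, b) == G.is_ancestor(a, b)


class TestOminusSet:
    def test_empty_set_identity(self):
        G = fixture("cherry")
        assert ominus_set(G, set()) == G

    def test_fig6_remove_all_chain_vertices(self):
        n = 4
        G = fixture("fig6", n=n)
        H = ominus_set(G, {f"v{i}" for i in range(1, n)})
        system = H.cluster_system()
        assert system.clusters == frozenset(
            {frozenset(G.leaves)} | {frozenset((x,)) for x in G.leaves}
        )

    def test_fig6_remove_extra_root_gives_hasse(self):
        G = fixture("fig6", n=4)
        H = ominus_set(G, {"r"})
        expected = hasse(G.cluster_system(), relabel=True).dag
        assert cluster_isomorphic(H, expected)

    def test_removing_everything_rejected(self):
        G = fixture("cherry")
        with pytest.raises(GraphValidationError):
            ominus_set(G, G.vertices)

    def test_s_properties_for_inner_removal(self):
        for seed in range(15):
            G = random_dag(4, 4, 0.45, seed)
            inner = sorted(G.vertices - G.leaves)
            if not inner:
                continue
            W = inner[: len(inner) // 2 + 1]
            H = ominus_set(G, W)
            flags = verify_s_properties(G, H)
            assert flags["S0"] and flags["S1"] and flags["S2"] and flags["S3"]


class TestAlgorithmLCA:
    def test_already_relevant_is_fixed(self):
        G = random_galled_tree(5, 0, 3)
        rep = make_LCA_relevant(G)
        assert rep.removed == ()
        assert rep.output == G

    def test_galled_cor710(self):
        rep = make_LCA_relevant(fixture("galled_cor710"))
        assert rep.removed == ("rho",)
        H = rep.output
        assert H.roots == {"u1"}
        assert H.children("u1") == {"x1", "u2"}
        assert H.children("u2") == {"x2", "x3"}

    def test_fig6_untouched(self):
        rep = make_LCA_relevant(fixture("fig6", n=3))
        assert rep.removed == ()

    def test_contract(self, corpus):
        import networkx as nx

        for name, G in corpus:
            rep = make_LCA_relevant(G)
            H = rep.output
            assert is_LCA_relevant(H).holds, name
            assert H.is_phylogenetic(), name
            assert H.cluster_system().clusters == G.cluster_system().clusters, name
            assert rep.s_flags is not None and all(rep.s_flags.values()), name
            gu = nx.Graph()
            gu.add_nodes_from(G.vertices)
            gu.add_edges_from(G.edges)
            hu = nx.Graph()
            hu.add_nodes_from(H.vertices)
            hu.add_edges_from(H.edges)
            if nx.is_connected(gu):
                assert nx.is_connected(hu), name

    def test_removal_set_minimum_unique(self, corpus):
        # no strictly smaller removal set yields an LCA-relevant DAG with S0-S5
        for name, G in corpus:
            if len(G.vertices) > 10:
                continue
            rep = make_LCA_relevant(G)
            W = rep.removed_set
            if not W:
                continue
            inner = sorted(G.vertices - G.leaves)
            for size in range(len(W)):
                for cand in combinations(inner, size):
                    Wc = frozenset(cand)
                    H = ominus_set(G, Wc)
                    if not is_LCA_relevant(H).holds:
                        continue
                    flags = verify_s_properties(G, H)
                    assert not all(flags.values()), (name, Wc)


class TestAlgorithmlca:
    def test_cherry_untouched(self):
        rep = make_lca_relevant(fixture("cherry"))
        assert rep.removed == ()
        assert rep.output == fixture("cherry")

    def test_fig6_root_first_preserves_clusters(self):
        G = fixture("fig6", n=4)
        rep = make_lca_relevant(G)
        # ancestors-first order processes the extra root before the chain
        assert rep.removed == ("r",)
        assert rep.output.cluster_system().clusters == G.cluster_system().clusters

    def test_fig6_root_last_loses_clusters(self):
        G = fixture("fig6", n=4)
        order = [v for v in G.topological_order if v != "r"] + ["r"]
        rep = make_lca_relevant(G, order=order)
        assert set(rep.removed) == {"v1", "v2", "v3"}
        assert rep.output.cluster_system().clusters < G.cluster_system().clusters

    def test_galled_cor710(self):
        rep = make_lca_relevant(fixture("galled_cor710"))
        assert rep.removed == ("rho",)
        assert is_lca_relevant(rep.output)

    def test_contract(self, corpus):
        import networkx as nx

        for name, G in corpus:
            rep = make_lca_relevant(G)
            H = rep.output
            assert is_lca_relevant(H).holds, name
            assert H.is_phylogenetic(), name
            flags = rep.s_flags
            assert flags["S0"] and flags["S1"] and flags["S2"] and flags["S3"], name
            assert flags["S4"], name
            gu = nx.Graph()
            gu.add_nodes_from(G.vertices)
            gu.add_edges_from(G.edges)
            if nx.is_connected(gu):
                hu = nx.Graph()
                hu.add_nodes_from(H.vertices)
                hu.add_edges_from(H.edges)
                assert nx.is_connected(hu), name

    def test_cl_inputs_match_algorithm_2(self, corpus):
        for name, G in corpus:
            if not (has_cl(G) or has_pcc(G)):
                continue
            rep3 = make_lca_relevant(G, verify=False)
            rep2 = make_LCA_relevant(G, verify=False)
            assert rep3.removed_set == rep2.removed_set, name
            H = rep3.output
            assert H.cluster_system().clusters == G.cluster_system().clusters, name
            expected = hasse(G.cluster_system(), relabel=True).dag
            assert cluster_isomorphic(H.remove_shortcuts(), expected), name


class TestHasse:
    def test_fig1_system_tree(self):
        hd = hasse(FIG1_SYSTEM, relabel=True)
        T = hd.dag
        assert T.is_phylogenetic()
        assert T.cluster_system().clusters == FIG1_SYSTEM.clusters
        assert len(T.roots) == 1
        assert not T.shortcuts()

    def test_xy_single_edge(self):
        from lcadag import ClusterSystem

        system = ClusterSystem(
            frozenset("xy"), frozenset({frozenset("x"), frozenset("xy")})
        )
        hd = hasse(system)
        assert len(hd.dag.edges) == 1
        assert not is_regular(hd.dag.relabel({"{x}": "x", "{x,y}": "r"})).holds

    def test_cherry_system(self):
        from lcadag import ClusterSystem

        system = ClusterSystem(
            frozenset("xy"),
            frozenset({frozenset("x"), frozenset("y"), frozenset("xy")}),
        )
        assert dags_isomorphic(hasse(system, relabel=True).dag, fixture("cherry"))

    def test_strong_cl_iff_hasse_plus_shortcuts(self, corpus):
        # one direction: add random shortcuts to a Hasse diagram
        import random

        for name, G in corpus:
            system = G.cluster_system()
            hd = hasse(system, relabel=True).dag
            rng = random.Random(hash(name) % (2**31))
            extra = set()
            for u in sorted(hd.vertices):
                for w in sorted(hd.descendants(u) - {u}):
                    if (u, w) not in hd.edges and rng.random() < 0.2:
                        if any(w in hd.descendants(c) for c in hd.children(u)):
                            extra.add((u, w))
            augmented = DAG(hd.vertices, hd.edges | extra)
            assert has_strong_cl(augmented).holds, name
        # other direction: strong-CL DAGs reduce to their Hasse diagram
        for name, G in corpus:
            if has_strong_cl(G):
                expected = hasse(G.cluster_system(), relabel=True).dag
                assert cluster_isomorphic(G.remove_shortcuts(), expected), name


class TestPhiTransforms:
    def test_p1_fixpoints(self):
        # shortcut-free LCA-relevant DAGs are left unchanged
        count = 0
        for seed in range(300):
            G = phi_LCA(random_dag(4, 5, 0.4, seed))
            assert not G.shortcuts() and is_LCA_relevant(G).holds
            assert phi_LCA(G) == G
            count += 1
            if count >= 200:
                break

    def test_fig6_fixed_by_phi_LCA(self):
        G = fixture("fig6", n=3)
        assert phi_LCA(G) == G

    def test_idempotent(self, corpus):
        for name, G in corpus:
            H = phi_LCA(G)
            assert phi_LCA(H) == H, name

    def test_p2_equivariance(self):
        import random

        for seed in range(20):
            G = random_dag(4, 5, 0.4, seed)
            rng = random.Random(seed + 1)
            xs = sorted(G.leaves)
            for _ in range(50):
                perm = xs[:]
                rng.shuffle(perm)
                sigma = dict(zip(xs, perm))
                lhs = phi_LCA(G.permute_leaves(sigma))
                rhs = phi_LCA(G).permute_leaves(sigma)
                assert dags_isomorphic(lhs, rhs)

    def test_p3_restriction_commutes(self):
        import random

        rng = random.Random(99)
        for seed in range(500):
            G = random_dag(rng.randint(1, 4), rng.randint(2, 8), 0.4, seed)
            xs = sorted(G.leaves)
            Y = frozenset(rng.sample(xs, rng.randint(1, len(xs))))
            lhs = phi_LCA(cluster_restriction(G, Y))
            rhs = cluster_restriction(phi_LCA(G), Y)
            assert lhs == rhs

    def test_phi_lca_equals_phi_LCA_on_cl_inputs(self):
        G = fixture("galled_cor710")
        assert phi_lca(G) == phi_LCA(G)

    def test_phi_lca_on_fig6_collapses_everything(self):
        G = fixture("fig6", n=3)
        H = phi_lca(G)
        assert H.vertices == G.leaves
        assert H.edges == frozenset()

    def test_phi_lca_p3_counterexample(self):
        # restriction does not commute with phi_lca without (CL)
        G = fixture("fig6", n=3)
        Y = frozenset({"x1", "x2"})
        lhs = phi_lca(cluster_restriction(G, Y))
        rhs = cluster_restriction(phi_lca(G), Y)
        assert lhs != rhs
        assert lhs == fixture("cherry").relabel({"w": "{x1,x2}", "x": "x1", "y": "x2"})
        assert rhs.edges == frozenset()

    def test_hierarchy_collapse_to_tree(self):
        # (CL) inputs with hierarchical cluster systems collapse to the
        # unique phylogenetic tree with the same clusters
        for seed in range(200):
            G = tree_with_redundancy(seed)
            assert has_cl(G)
            assert G.cluster_system().is_hierarchy()
            T = hasse(G.cluster_system(), relabel=True).dag
            a = phi_LCA(G)
            b = phi_lca(G)
            assert cluster_isomorphic(a, T)
            assert cluster_isomorphic(b, T)
            assert a.is_phylogenetic()

    def test_n3o_preserved_by_inner_suppression(self, corpus):
        for name, G in corpus:
            if not G.satisfies_n3o():
                continue
            for v in sorted(G.vertices - G.leaves):
                assert ominus(G, v).satisfies_n3o(), (name, v)


class TestClusterRestriction:
    def test_regular_dag_restriction_to_full_leafset(self):
        G = hasse(FIG1_SYSTEM, relabel=True).dag
        assert cluster_restriction(G, G.leaves) == G

    def test_singleton(self):
        G = fixture("fig6", n=3)
        H = cluster_restriction(G, {"x1"})
        assert H.vertices == {"x1"} and not H.edges

    def test_always_regular(self):
        import random

        rng = random.Random(5)
        for seed in range(30):
            G = random_dag(3, 5, 0.4, seed)
            xs = sorted(G.leaves)
            Y = frozenset(rng.sample(xs, rng.randint(1, len(xs))))
            assert is_regular(cluster_restriction(G, Y)).holds

    def test_errors(self):
        G = fixture("cherry")
        with pytest.raises(GraphValidationError):
            cluster_restriction(G, set())
        with pytest.raises(GraphValidationError):
            cluster_restriction(G, {"w"})
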