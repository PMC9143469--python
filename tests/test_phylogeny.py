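import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from cypminer.nomenclature import pairwise_identity
from cypminer.phylogeny import build_distance_matrix, family_coloring, nj_tree
from cypminer.sequence_io import ProteinRecord

from conftest import make_p450_sequence


def _rec(pid, seq):
    return ProteinRecord(pid, "g1", "c1", 1, 3 * len(seq), "+", seq)


# ---------------------------------------------------------------------------
# additive-tree helpers (test-side oracles)
# ---------------------------------------------------------------------------


def _canon_split(side, n):
    side = frozenset(side)
    comp = frozenset(set(range(n)) - side)
    if len(side) < len(comp):
        return side
    if len(comp) < len(side):
        return comp
    return side if 0 in side else comp


def random_additive_tree(rng, n):
    """Random unrooted binary tree as an edge list with positive lengths;
    returns (edges, leaf names). Nodes 0..n-1 are leaves."""
    edges = {}
    next_node = n
    # start from a 3-star
    center = next_node
    next_node += 1
    for leaf in range(3):
        edges[(leaf, center)] = rng.uniform(0.05, 1.0)
    for leaf in range(3, n):
        (a, b) = list(edges)[rng.integers(len(edges))]
        w = edges.pop((a, b))
        mid = next_node
        next_node += 1
        cut = rng.uniform(0.2, 0.8) * w
        edges[(a, mid)] = cut
        edges[(mid, b)] = w - cut
        edges[(leaf, mid)] = rng.uniform(0.05, 1.0)
    return edges, [f"t{i}" for i in range(n)]


def path_distances(edges, n):
    import networkx as nx

    g = nx.Graph()
    for (a, b), w in edges.items():
        g.add_edge(a, b, weight=w)
    d = np.zeros((n, n))
    for i in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, i)
        for j in range(n):
            d[i, j] = lengths[j]
    return (d + d.T) / 2  # remove float asymmetry from summation order


def tip_distances(tree, labels):
    tips = {t.name: t for t in tree.tips()}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tips[labels[i]].distance(tips[labels[j]])
    return d


def enumerate_topologies(n):
    """All unrooted binary topologies on leaves 0..n-1 as frozensets of
    splits (each split the smaller-side leaf set)."""

    def splits_of(edges):
        import networkx as nx

        g = nx.Graph(list(edges))
        out = set()
        for a, b in edges:
            h = g.copy()
            h.remove_edge(a, b)
            side = {x for x in nx.node_connected_component(h, a) if x < n}
            if 1 < len(side) < n - 1:
                out.add(_canon_split(side, n))
        return frozenset(out)

    trees = [[(0, n), (1, n), (2, n)]]  # 3-star, internal nodes >= n
    next_internal = [n + 1]
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for idx in range(len(edges)):
                a, b = edges[idx]
                mid = next_internal[0]
                new = edges[:idx] + edges[idx + 1 :] + [(a, mid), (mid, b), (leaf, mid)]
                new_trees.append(new)
        next_internal[0] += 1
        trees = new_trees
    # relabel internal nodes consistently is unnecessary for split extraction
    return {splits_of(t) for t in trees}


def tree_splits(tree, labels):
    index = {name: i for i, name in enumerate(labels)}
    n = len(labels)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = {index[t.name] for t in node.tips()}
        if 1 < len(side) < n - 1:
            out.add(_canon_split(side, n))
    return frozenset(out)


# ---------------------------------------------------------------------------


class TestDistanceMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        seq = make_p450_sequence(200)
        dm = build_distance_matrix([_rec(f"p{i}", seq) for i in range(3)])
        assert np.allclose(dm.data, 0.0)

    def test_distance_is_one_minus_identity(self):
        a = "ACDEFGHIKL" * 5
        b = a[:45] + "VVVVV"  # 90% identity, no gaps needed
        dm = build_distance_matrix([_rec("a", a), _rec("b", b), _rec("c", "W" * 50)])
        assert dm["a", "b"] == pytest.approx(0.10)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        recs = [_rec(f"p{i}", "".join(rng.choice(aas, size=40))) for i in range(6)]
        dm = build_distance_matrix(recs)
        for i in range(6):
            for j in range(i + 1, 6):
                pct, _ = pairwise_identity(recs[i].sequence, recs[j].sequence)
                assert dm[recs[i].id, recs[j].id] == pytest.approx(1 - pct / 100, abs=1e-12)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            build_distance_matrix([_rec("a", "MA"), _rec("b", "MA")])


class TestNeighborJoining:
    def test_three_taxa_solves_three_point_equations(self):
        dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float), ids=list("ABC"))
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxa_additive_recovery(self):
        # tree ((A:2,B:3):1,C:4,D:5)
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        dm = DistanceMatrix(d, ids=list("ABCD"))
        tree = nj_tree(dm)
        assert np.allclose(tip_distances(tree, list("ABCD")), d, atol=1e-9)
        assert tree_splits(tree, list("ABCD")) == frozenset({frozenset({0, 1})})

    @pytest.mark.parametrize("n", [5, 7, 10])
    def test_additive_matrices_recovered_exactly(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            edges, labels = random_additive_tree(rng, n)
            d = path_distances(edges, n)
            tree = nj_tree(DistanceMatrix(d, ids=labels))
            assert np.allclose(tip_distances(tree, labels), d, atol=1e-9)

    @pytest.mark.parametrize("n", [5, 6])
    def test_brute_force_topology_check(self, n):
        # the NJ topology is the unique topology fitting the additive input,
        # verified against exhaustive enumeration of all unrooted topologies
        rng = np.random.default_rng(100 + n)
        edges, labels = random_additive_tree(rng, n)
        d = path_distances(edges, n)
        tree = nj_tree(DistanceMatrix(d, ids=labels))
        nj_splits = tree_splits(tree, labels)
        all_topologies = enumerate_topologies(n)
        assert nj_splits in all_topologies
        # source tree splits == NJ splits
        src = {}
        import networkx as nx

        g = nx.Graph()
        for (a, b), w in edges.items():
            g.add_edge(a, b)
        src_splits = set()
        for a, b in list(g.edges):
            h = g.copy()
            h.remove_edge(a, b)
            side = {x for x in nx.node_connected_component(h, a) if x < n}
            if 1 < len(side) < n - 1:
                src_splits.add(_canon_split(side, n))
        assert nj_splits == frozenset(src_splits)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            n = 8
            x = rng.uniform(0.1, 1.0, size=(n, n))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0)
            dm = DistanceMatrix(d, ids=[f"t{i}" for i in range(n)])
            assert nj_tree(dm).compare_rfd(skbio_nj(dm)) == 0.0

    def test_non_symmetric_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)

        class FakeDM:
            data = d
            ids = list("ABC")

        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(FakeDM())

    def test_negative_lengths_clamped_and_counted(self):
        # strongly non-additive matrix forces a negative NJ branch
        d = np.array(
            [[0, 1, 10, 10], [1, 0, 10, 1], [10, 10, 0, 10], [10, 1, 10, 0]], float
        )
        tree = nj_tree(DistanceMatrix(d, ids=list("ABCD")))
        assert all(t.length >= 0 for t in tree.traverse() if t.length is not None)
        assert tree.clamped_negative_branches >= 1


class TestFamilyColoring:
    def test_top_k_families_colored(self, small_sim, small_results):
        records = small_sim["records"]
        p450_ids = {c.protein_id for c in small_results["p450_calls"]}
        recs = [r for r in records if r.id in p450_ids]
        tree = nj_tree(build_distance_matrix(recs))
        ann = family_coloring(tree, small_results["assignments"], k=3)
        top3 = set(ann[ann.color_index >= 0]["family"])
        assert len(top3) == 3
        assert set(ann["leaf_id"]) == {r.id for r in recs}

    def test_missing_assignment_rejected(self, small_sim, small_results):
        records = small_sim["records"]
        p450_ids = sorted(c.protein_id for c in small_results["p450_calls"])[:4]
        recs = [r for r in records if r.id in set(p450_ids)]
        tree = nj_tree(build_distance_matrix(recs))
        with pytest.raises(KeyError):
            family_coloring(tree, small_results["assignments"][:1])

    def test_planted_families_form_clades(self, small_sim, small_results):
        # high-identity plants of each family group together in the NJ tree
        truth = small_sim["truth"]["proteins"]
        keep = [
            pid
            for pid, t in truth.items()
            if t.get("expected_basis") == "subfamily-match"
        ]
        recs = [r for r in small_sim["records"] if r.id in set(keep)]
        tree = nj_tree(build_distance_matrix(recs))
        tipsets = {frozenset(t.name for t in node.tips()) for node in tree.non_tips()}
        alltips = frozenset(r.id for r in recs)
        by_family: dict[str, set] = {}
        for pid in keep:
            by_family.setdefault(truth[pid]["source_family"], set()).add(pid)
        for family, members in by_family.items():
            s = frozenset(members)
            if len(s) < 2:
                continue  # a singleton is trivially its own group
            assert s in tipsets or (alltips - s) in tipsets or s == alltips
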