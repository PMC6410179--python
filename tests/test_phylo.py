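"""Distances, NJ (vs exhaustive least-squares oracle), bootstrap, Newick."""

import math

import numpy as np
import pytest

from famchar import phylo
from famchar.phylo import (
    Alignment,
    DistanceMatrix,
    bootstrap_support,
    find_sister_pairs,
    neighbor_joining,
    p_distance,
    parse_newick,
    poisson_distance,
    poisson_distance_matrix,
    to_newick,
)
from famchar.synthetic_data import simulate_sister_alignment

# ---------------------------------------------------------------------------
# Independent oracle: exhaustive unrooted topologies + least-squares fit
# ---------------------------------------------------------------------------


def enumerate_topologies(n):
    """All unrooted binary topologies on leaves 0..n-1, as edge lists."""
    tops = [([(0, n), (1, n), (2, n)], n + 1)]
    for leaf in range(3, n):
        nxt_tops = []
        for edges, nxt in tops:
            for k in range(len(edges)):
                u, v = edges[k]
                e2 = edges[:k] + edges[k + 1 :] + [(u, nxt), (v, nxt), (leaf, nxt)]
                nxt_tops.append((e2, nxt + 1))
        tops = nxt_tops
    return [edges for edges, _ in tops]


def _adjacency(edges):
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    return adj


def _path_edge_indices(adj, a, b):
    stack = [(a, [])]
    seen = {a}
    while stack:
        node, path = stack.pop()
        if node == b:
            return path
        for nbr, eidx in adj[node]:
            if nbr not in seen:
                seen.add(nbr)
                stack.append((nbr, path + [eidx]))
    raise AssertionError("disconnected topology")


def ls_sse(edges, dmat, n):
    """Least-squares branch-length fit of a topology to a distance matrix."""
    adj = _adjacency(edges)
    rows, d = [], []
    for i in range(n):
        for j in range(i + 1, n):
            indicator = np.zeros(len(edges))
            indicator[_path_edge_indices(adj, i, j)] = 1.0
            rows.append(indicator)
            d.append(dmat[i, j])
    A, d = np.array(rows), np.array(d)
    x, *_ = np.linalg.lstsq(A, d, rcond=None)
    return float(((A @ x - d) ** 2).sum())


def topology_bipartitions(edges, n, names):
    """Canonical internal splits of an edge-list topology (oracle side)."""
    adj = _adjacency(edges)
    out = set()
    for idx, _ in enumerate(edges):
        comp = set()
        u = edges[idx][0]
        stack = [u]
        seen = {u}
        while stack:
            node = stack.pop()
            if node < n:
                comp.add(node)
            for nbr, eidx in adj[node]:
                if eidx != idx and nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        if 2 <= len(comp) <= n - 2:
            side = comp if 0 not in comp else set(range(n)) - comp
            out.add(frozenset(names[i] for i in side))
    return out


def random_additive(rng, n):
    """Random binary topology + U(0.1, 1) branch lengths -> (edges, names, D)."""
    tops = None  # build one random topology by random edge insertion
    edges, nxt = [(0, n), (1, n), (2, n)], n + 1
    for leaf in range(3, n):
        k = int(rng.integers(len(edges)))
        u, v = edges.pop(k)
        edges += [(u, nxt), (v, nxt), (leaf, nxt)]
        nxt += 1
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    adj = _adjacency(edges)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = sum(lengths[e] for e in _path_edge_indices(adj, i, j))
    names = tuple(f"t{i}" for i in range(n))
    return edges, names, D


def tree_splits(tree):
    return set(tree.bipartitions().keys())


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


class TestPDistance:
    def test_identical_rows_zero(self):
        assert p_distance("AAAA", "AAAA") == 0.0

    def test_quarter_difference(self):
        assert p_distance("AAAA", "AAAV") == 0.25

    def test_pairwise_deletion_hand_count(self):
        # 3 comparable sites (gap column dropped), 1 difference
        assert p_distance("A-AA", "AGAV") == pytest.approx(1 / 3)

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance("A-", "-A")


class TestPoissonDistance:
    def test_closed_form(self):
        assert poisson_distance(0.0) == 0.0
        assert poisson_distance(0.5) == pytest.approx(math.log(2), abs=1e-9)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError):
            poisson_distance(1.0)

    @pytest.mark.parametrize("p", [0.0, 0.1, 0.5, 0.9, 0.98])
    def test_correction_only_inflates(self, p):
        assert poisson_distance(p) >= p

    def test_matrix_matches_scalar_route(self):
        aln = Alignment(("a", "b", "c"), ("AAAA", "AAAV", "A-AA"))
        dm = poisson_distance_matrix(aln)
        assert dm.matrix[0, 1] == pytest.approx(poisson_distance(0.25))
        assert dm.matrix[0, 2] == pytest.approx(0.0)

    def test_saturated_pair_rejected(self):
        aln = Alignment(("a", "b", "c"), ("AAAA", "VVVV", "AAAV"))
        with pytest.raises(ValueError, match="saturated"):
            poisson_distance_matrix(aln)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(("a", "b", "c"), np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0.0]]))
        tree = neighbor_joining(dm)
        assert to_newick(tree) == "(a:1,b:1,c:1);"

    def test_four_taxon_additive_exact(self):
        # ((a,b),(c,d)) with leaf lengths 1,2,3,4 and internal edge 5
        la, lb, lc, ld, m = 1.0, 2.0, 3.0, 4.0, 5.0
        D = np.array(
            [
                [0, la + lb, la + m + lc, la + m + ld],
                [la + lb, 0, lb + m + lc, lb + m + ld],
                [la + m + lc, lb + m + lc, 0, lc + ld],
                [la + m + ld, lb + m + ld, lc + ld, 0],
            ]
        )
        names = ("a", "b", "c", "d")
        tree = neighbor_joining(DistanceMatrix(names, D))
        # topology: the single internal split, against the brute-force oracle
        best = min(enumerate_topologies(4), key=lambda e: ls_sse(e, D, 4))
        assert tree_splits(tree) == topology_bipartitions(best, 4, names)
        # exact branch lengths
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths == pytest.approx({"a": la, "b": lb, "c": lc, "d": ld})
        internal = [n for n in tree.root.children if not n.is_leaf]
        assert internal[0].length == pytest.approx(m)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_recovery_matches_exhaustive_oracle(self, n):
        rng = np.random.default_rng(1234 + n)
        for _ in range(5):
            edges, names, D = random_additive(rng, n)
            truth = topology_bipartitions(edges, n, names)
            nj_splits = tree_splits(neighbor_joining(DistanceMatrix(names, D)))
            sse = {i: ls_sse(top, D, n) for i, top in enumerate(enumerate_topologies(n))}
            best = min(sse, key=sse.get)
            oracle = topology_bipartitions(enumerate_topologies(n)[best], n, names)
            assert nj_splits == truth == oracle

    @pytest.mark.parametrize("n", [7, 8])
    def test_additive_recovery_larger(self, n):
        rng = np.random.default_rng(99 + n)
        for _ in range(5):
            edges, names, D = random_additive(rng, n)
            nj_splits = tree_splits(neighbor_joining(DistanceMatrix(names, D)))
            assert nj_splits == topology_bipartitions(edges, n, names)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b", "c"), np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]]))

    def test_matches_scikit_bio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        n = 7
        names = tuple(f"t{i}" for i in range(n))
        x = rng.uniform(0.2, 2.0, size=(n, n))
        D = np.triu(x, 1) + np.triu(x, 1).T
        ours = tree_splits(neighbor_joining(DistanceMatrix(names, D)))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=list(names)))
        all_names = frozenset(names)
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= n - 2:
                theirs.add(all_names - side if "t0" in side else side)
        assert ours == theirs


# ---------------------------------------------------------------------------
# Bootstrap and sister pairs
# ---------------------------------------------------------------------------


def congruent_alignment():
    """Every variable column supports the same split {A,B} | {C,D}."""
    block, const = 30, 30
    rows = (
        "W" * block + "A" * const,
        "W" * block + "A" * const,
        "Y" * block + "A" * const,
        "Y" * block + "A" * const,
    )
    return Alignment(("A", "B", "C", "D"), rows)


class TestBootstrap:
    def test_congruent_alignment_gives_full_support(self):
        tree = bootstrap_support(congruent_alignment(), n_reps=100, seed=3)
        supports = [node.support for node in tree.bipartitions().values()]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_in_range_and_accounting(self):
        aln, _ = simulate_sister_alignment(21, n_background=5, k_pairs=2)
        tree = bootstrap_support(aln, n_reps=50, seed=4)
        assert tree.bootstrap_replicates + tree.skipped_replicates == 50
        for node in tree.bipartitions().values():
            assert 0.0 <= node.support <= 100.0

    def test_fixed_seed_is_byte_identical(self):
        aln, _ = simulate_sister_alignment(22, n_background=5, k_pairs=2)
        t1 = bootstrap_support(aln, n_reps=60, seed=7)
        t2 = bootstrap_support(aln, n_reps=60, seed=7)
        assert to_newick(t1) == to_newick(t2)

    def test_support_converges_when_doubling_replicates(self):
        aln, _ = simulate_sister_alignment(23, n_background=6, k_pairs=2)
        t1 = bootstrap_support(aln, n_reps=300, seed=11)
        t2 = bootstrap_support(aln, n_reps=600, seed=12)
        s1 = {split: node.support for split, node in t1.bipartitions().items()}
        s2 = {split: node.support for split, node in t2.bipartitions().items()}
        assert s1.keys() == s2.keys()
        for split in s1:
            assert abs(s1[split] - s2[split]) < 5.0


class TestSisterPairs:
    def _tree_with_cherry_support(self, support):
        aln = congruent_alignment()
        tree = bootstrap_support(aln, n_reps=10, seed=1)
        for node in tree.bipartitions().values():
            node.support = support
        return tree

    def test_strictly_above_threshold_reported(self):
        tree = self._tree_with_cherry_support(95.0)
        assert find_sister_pairs(tree, 90.0) == [("A", "B"), ("C", "D")]

    def test_exactly_at_threshold_excluded(self):
        tree = self._tree_with_cherry_support(90.0)
        assert find_sister_pairs(tree, 90.0) == []

    def test_planted_duplications_recovered_exactly(self):
        aln, truth_pairs = simulate_sister_alignment(31, n_background=8, k_pairs=3)
        tree = bootstrap_support(aln, n_reps=200, seed=31)
        assert find_sister_pairs(tree, 90.0) == truth_pairs


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


class TestNewick:
    def test_three_leaf_shape(self):
        dm = DistanceMatrix(("a", "b", "c"), np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0.0]]))
        assert to_newick(neighbor_joining(dm)) == "(a:1,b:1,c:1);"

    def test_round_trip_identity(self):
        aln, _ = simulate_sister_alignment(41, n_background=5, k_pairs=2)
        tree = bootstrap_support(aln, n_reps=50, seed=41)
        text = to_newick(tree)
        assert to_newick(parse_newick(text)) == text

    def test_family_style_id_survives_unquoted(self):
        dm = DistanceMatrix(
            ("LEA2-1", "LEA2-2", "DHN-1"), np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0.0]])
        )
        text = to_newick(neighbor_joining(dm))
        assert "LEA2-1:" in text and "'" not in text

    def test_metacharacter_id_quoted(self):
        dm = DistanceMatrix(
            ("a b", "x", "y"), np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0.0]])
        )
        text = to_newick(neighbor_joining(dm))
        assert "'a b'" in text
        assert sorted(parse_newick(text).leaf_names) == ["a b", "x", "y"]

    def test_dendropy_parses_output(self):
        dendropy = pytest.importorskip("dendropy")
        aln, _ = simulate_sister_alignment(42, n_background=5, k_pairs=2)
        tree = bootstrap_support(aln, n_reps=50, seed=42)
        dtree = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        assert {t.label for t in dtree.taxon_namespace} == set(aln.ids)
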