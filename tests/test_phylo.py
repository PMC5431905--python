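"""p-distance, neighbor joining, and column-bootstrap support."""

import itertools

import numpy as np
import pytest

import hoxcomb as hx
from hoxcomb.phylo import Tree, TreeNode, _segment_matrix, _distances_from_matrix

from conftest import make_segment, random_residues


def mutate(segment: hx.AnalysisSegment, rng, k: int) -> hx.AnalysisSegment:
    """Segment with exactly k positions substituted to a different residue."""
    residues = list(segment.residues)
    sites = rng.choice(len(residues), size=k, replace=False)
    for s in sites:
        choices = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != residues[s]]
        residues[s] = choices[int(rng.integers(len(choices)))]
    return hx.AnalysisSegment(hd="".join(residues[:60]), cflank="".join(residues[60:]))


class TestPDistance:
    def test_identical_segments(self):
        seg = make_segment(cflank="NKKSLNDAQWEA")
        assert hx.p_distance(seg, seg) == 0.0

    def test_six_mismatches_of_72(self):
        rng = np.random.default_rng(3)
        a = make_segment(cflank="NKKSLNDAQWEA")
        b = mutate(a, rng, 6)
        assert hx.p_distance(a, b) == pytest.approx(6 / 72)

    def test_x_positions_skipped(self):
        a = hx.AnalysisSegment(hd="A" * 60, cflank="")
        b = hx.AnalysisSegment(hd="X" + "A" * 58 + "C", cflank="")
        # 59 comparable positions, 1 mismatch
        assert hx.p_distance(a, b) == pytest.approx(1 / 59)

    def test_all_x_is_error(self):
        a = hx.AnalysisSegment(hd="X" * 60, cflank="")
        with pytest.raises(hx.DataError):
            hx.p_distance(a, a)

    def test_four_taxon_hand_count(self):
        """Cross-check the matrix helper against per-pair hand counting."""
        rng = np.random.default_rng(5)
        base = make_segment(cflank=random_residues(rng, 12))
        segs = [base, mutate(base, rng, 3), mutate(base, rng, 10), mutate(base, rng, 30)]
        dm = hx.segments_to_distance_matrix(segs, ["a", "b", "c", "d"])
        for i, j in itertools.combinations(range(4), 2):
            hand = sum(
                x != y for x, y in zip(segs[i].residues, segs[j].residues)
            ) / 72
            assert dm.d[i, j] == pytest.approx(hand)


def additive_matrix_from_quartet(ids, lengths):
    """Distances on the 4-taxon tree ((a,b),(c,d)) with named edge lengths:
    la, lb, lc, ld for the leaves and lm for the internal edge."""
    la, lb, lc, ld, lm = lengths
    a, b, c, d = ids
    dist = {
        (a, b): la + lb,
        (a, c): la + lm + lc,
        (a, d): la + lm + ld,
        (b, c): lb + lm + lc,
        (b, d): lb + lm + ld,
        (c, d): lc + ld,
    }
    m = np.zeros((4, 4))
    for (x, y), v in dist.items():
        i, j = ids.index(x), ids.index(y)
        m[i, j] = m[j, i] = v
    return hx.DistanceMatrix(ids=tuple(ids), d=m)


class TestNeighborJoining:
    def test_recovers_quartet_topology_and_lengths(self):
        dm = additive_matrix_from_quartet(
            ["a", "b", "c", "d"], (0.1, 0.2, 0.3, 0.4, 0.25)
        )
        tree = neighbor_joined = hx.neighbor_joining(dm)
        assert tree.splits() == {frozenset({"c", "d"})}
        assert tree.n_edges() == 5
        # leaf branch lengths recovered exactly
        lengths = {l.name: l.length for l in tree.root.leaves()}
        for name, expected in zip("abcd", (0.1, 0.2, 0.3, 0.4)):
            assert lengths[name] == pytest.approx(expected, abs=1e-9)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        tree = hx.neighbor_joining(hx.DistanceMatrix(ids=("a", "b", "c"), d=d))
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"a": 0.1, "b": 0.1, "c": 0.3})
        assert tree.n_edges() == 3

    def test_fewer_than_three_taxa_rejected(self):
        d = np.array([[0, 0.1], [0.1, 0]])
        with pytest.raises(hx.DataError):
            hx.neighbor_joining(hx.DistanceMatrix(ids=("a", "b"), d=d))

    def test_input_order_invariance(self):
        rng = np.random.default_rng(13)
        dm = additive_matrix_from_quartet(
            ["a", "b", "c", "d"], (0.12, 0.21, 0.33, 0.44, 0.3)
        )
        reference = hx.neighbor_joining(dm).splits()
        for _ in range(20):
            perm = rng.permutation(4)
            shuffled = hx.DistanceMatrix(
                ids=tuple(dm.ids[k] for k in perm), d=dm.d[np.ix_(perm, perm)]
            )
            assert hx.neighbor_joining(shuffled).splits() == reference

    def test_exact_on_random_additive_trees(self):
        """NJ is exact on additive distances: random caterpillar-free trees
        up to n=8, matrix generated from the tree, splits recovered."""
        rng = np.random.default_rng(29)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            ids, d, true_splits = random_additive_tree(rng, n)
            tree = hx.neighbor_joining(hx.DistanceMatrix(ids=ids, d=d))
            assert tree.splits() == true_splits

    def test_topology_agrees_with_skbio_on_noisy_matrices(self):
        """Independent-implementation cross-check: on near-additive matrices
        (perturbed, so no Q ties) our NJ and scikit-bio's produce the same
        unrooted topology."""
        import skbio

        rng = np.random.default_rng(31)
        for _ in range(15):
            n = int(rng.integers(5, 9))
            ids, d, _ = random_additive_tree(rng, n)
            noise = rng.uniform(0, 0.01, size=(n, n))
            d = d + (noise + noise.T)  # parenthesised: keeps exact symmetry
            np.fill_diagonal(d, 0.0)
            ours = hx.neighbor_joining(hx.DistanceMatrix(ids=ids, d=d)).splits()
            sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=list(ids)))
            ref = min(ids)
            theirs = set()
            for node in sk_tree.non_tips(include_self=False):
                below = frozenset(t.name for t in node.tips())
                if 1 < len(below) < n - 1:
                    theirs.add(below if ref not in below else frozenset(ids) - below)
            assert ours == theirs

    def test_degenerate_zero_distances_no_crash(self):
        d = np.zeros((4, 4))
        tree = hx.neighbor_joining(hx.DistanceMatrix(ids=("a", "b", "c", "d"), d=d))
        assert tree.leaf_names() == frozenset("abcd")
        assert all(l.length == 0 for l in tree.root.leaves())


def random_additive_tree(rng, n):
    """Random unrooted binary tree over n leaves with exponential branch
    lengths; returns (ids, additive distance matrix, non-trivial splits).
    Built by sequential leaf attachment; distances by brute-force path sums."""
    import networkx as nx  # independent path-length oracle

    g = nx.Graph()
    ids = tuple(f"t{i}" for i in range(n))
    g.add_edge(ids[0], ids[1], w=float(rng.exponential(0.1)) + 1e-3)
    internal = 0
    for leaf in ids[2:]:
        u, v = list(g.edges())[int(rng.integers(g.number_of_edges()))]
        w = g[u][v]["w"]
        internal += 1
        mid = f"i{internal}"
        split = float(rng.uniform(0.2, 0.8)) * w
        g.remove_edge(u, v)
        g.add_edge(u, mid, w=split)
        g.add_edge(mid, v, w=w - split)
        g.add_edge(mid, leaf, w=float(rng.exponential(0.1)) + 1e-3)
    d = np.zeros((n, n))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="w"))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = paths[ids[i]][ids[j]]
    ref = min(ids)
    splits = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(x for x in comp if x in ids)
        if ref in side:
            side = frozenset(ids) - side
        if 1 < len(side) < n - 1:
            splits.add(side)
    return ids, d, splits


class TestBootstrap:
    def make_two_clades(self, rng, n_per_clade=4, within=1, between=30):
        base_a = make_segment(cflank=random_residues(rng, 12))
        base_b = mutate(base_a, rng, between)
        segs, ids = [], []
        for k, base in enumerate((base_a, base_b)):
            for i in range(n_per_clade):
                segs.append(mutate(base, rng, within))
                ids.append(f"clade{'AB'[k]}_{i}")
        return segs, ids

    def test_planted_clade_strongly_supported(self):
        rng = np.random.default_rng(37)
        segs, ids = self.make_two_clades(rng)
        tree = hx.bootstrap_support(segs, ids, n_replicates=100, seed=17)
        supports = {split: node.support for node, split in tree.internal_edges()}
        clade = frozenset(i for i in ids if i.startswith("cladeB"))
        assert supports[clade] >= 0.95

    def test_single_replicate_supports_are_zero_or_one(self):
        rng = np.random.default_rng(43)
        segs, ids = self.make_two_clades(rng)
        tree = hx.bootstrap_support(segs, ids, n_replicates=1, seed=5)
        for node, _ in tree.internal_edges():
            assert node.support in (0.0, 1.0)

    def test_identical_sequences_handled(self):
        seg = make_segment(cflank="NKKSLNDAQWEA")
        tree = hx.bootstrap_support([seg] * 4, ["a", "b", "c", "d"], n_replicates=5, seed=1)
        for node, _ in tree.internal_edges():
            assert node.support is not None

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(47)
        segs, ids = self.make_two_clades(rng)
        t1 = hx.bootstrap_support(segs, ids, n_replicates=25, seed=9)
        t2 = hx.bootstrap_support(segs, ids, n_replicates=25, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_support_monotone_in_between_clade_divergence(self):
        rng = np.random.default_rng(53)
        supports = []
        for between in (2, 10, 40):
            segs, ids = self.make_two_clades(
                np.random.default_rng(59), within=1, between=between
            )
            tree = hx.bootstrap_support(segs, ids, n_replicates=60, seed=3)
            lookup = {split: node.support for node, split in tree.internal_edges()}
            clade = frozenset(i for i in ids if i.startswith("cladeB"))
            supports.append(lookup.get(clade, 0.0))
        assert supports[0] <= supports[1] <= supports[2]
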