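"""Tajima-Nei distances, neighbour joining and clade labelling."""

import math

import numpy as np
import pytest

from numtforge.phylo import (
    BACKGROUND,
    NUMT,
    DistanceMatrix,
    SaturationError,
    TreeNode,
    distance_matrix,
    label_numt_clade,
    neighbor_joining,
    parse_newick,
    tajima_nei,
    tree_distances,
    write_newick,
)

from conftest import mutate, random_dna


def oracle_tajima_nei(a, b):
    """Independent direct evaluation of the 1984 formula."""
    pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    p = sum(x != y for x, y in pairs) / n
    if p == 0:
        return 0.0
    g = {c: 0.0 for c in "ACGT"}
    for x, y in pairs:
        g[x] += 1
        g[y] += 1
    g = {c: v / (2 * n) for c, v in g.items()}
    x_ij = {}
    for x, y in pairs:
        if x != y:
            key = frozenset((x, y))
            x_ij[key] = x_ij.get(key, 0) + 1 / n
    h = sum(v * v / (2 * g[min(k)] * g[max(k)]) for k, v in x_ij.items())
    b_ = 0.5 * (1 - sum(v * v for v in g.values()) + p * p / h)
    return -b_ * math.log(1 - p / b_)


def leaf_path_lengths(tree):
    """Test-local additive metric of a TreeNode tree (independent of package)."""
    dists = {}

    def walk(node, acc):
        acc = dict(acc)
        for k in acc:
            acc[k] += node.length
        if node.is_leaf:
            for other, d in acc.items():
                dists[frozenset((node.name, other))] = d
            acc[node.name] = 0.0
        else:
            acc2 = dict(acc)
            for child in node.children:
                got = walk(child, acc2)
                for k, v in got.items():
                    if k not in acc2:
                        acc2[k] = v
                    else:
                        acc2[k] = min(acc2[k], v)  # unreachable; names unique
            return {k: v + node.length for k, v in acc2.items()}
        return {node.name: node.length}

    # simpler: recompute by brute force over leaf pairs via parent chains
    leaves = tree.leaves()

    def chain(n):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    mat = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            ca, cb = chain(a), chain(b)
            shared = {id(x) for x in ca} & {id(x) for x in cb}
            d = sum(x.length for x in ca if id(x) not in shared)
            d += sum(x.length for x in cb if id(x) not in shared)
            mat[frozenset((a.name, b.name))] = d
    return mat


def random_tree(rng, n_taxa):
    """Random binary topology with branch lengths in [0.5, 4]."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.5, 4)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.5, 4)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        root.add(n)
    return root


class TestTajimaNei:
    def test_identical_sequences(self):
        assert tajima_nei("ACGTACGT", "ACGTACGT") == 0.0

    def test_jukes_cantor_limit_under_equal_frequencies(self):
        # balanced base composition and mismatches spread evenly over all 12
        # directed substitution types -> the 1984 distance collapses to JC
        variants = ["CCGT", "GCGT", "TCGT", "AAGT", "AGGT", "ATGT",
                    "ACAT", "ACCT", "ACTT", "ACGA", "ACGC", "ACGG"]
        a = "ACGT" * 300
        b = "".join(v for v in variants for _ in range(12)) + "ACGT" * 156
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        assert p == 144 / 1200
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert tajima_nei(a, b) == pytest.approx(expected, rel=1e-9)

    def test_matches_independent_formula_evaluation(self, rng):
        a = random_dna(rng, 600)
        b = mutate(rng, a, 0.08)
        assert tajima_nei(a, b) == pytest.approx(oracle_tajima_nei(a, b), rel=1e-12)

    def test_correction_inflates_distance(self, rng):
        a = random_dna(rng, 800)
        b = mutate(rng, a, 0.1)
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        assert tajima_nei(a, b) >= p

    def test_gap_and_n_columns_skipped_pairwise(self):
        assert tajima_nei("ACGTN", "ACGTA") == 0.0
        assert tajima_nei("ACG-A", "ACGTA") == 0.0

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            tajima_nei("AAAACCCCGGGGTTTT", "CCCCGGGGTTTTAAAA")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        got = leaf_path_lengths(tree)
        assert got[frozenset(("a", "b"))] == pytest.approx(5)
        assert got[frozenset(("a", "c"))] == pytest.approx(9)
        assert got[frozenset(("b", "c"))] == pytest.approx(10)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):3,C:4,D:5): additive distances
        d = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        got = leaf_path_lengths(tree)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert got[frozenset((a, b))] == pytest.approx(d[i, j])

    def test_random_additive_matrices_recovered(self, rng):
        for rep in range(25):
            n = int(rng.integers(4, 9))
            true = random_tree(rng, n)
            truth = leaf_path_lengths(true)
            taxa = sorted(x.name for x in true.leaves())
            d = np.zeros((n, n))
            for i, a in enumerate(taxa):
                for j, b in enumerate(taxa):
                    if i != j:
                        d[i, j] = truth[frozenset((a, b))]
            rec = neighbor_joining(DistanceMatrix(taxa, d))
            got = leaf_path_lengths(rec)
            for key, v in truth.items():
                assert got[key] == pytest.approx(v, abs=1e-9)

    def test_taxon_permutation_invariance(self, rng):
        n = 6
        true = random_tree(rng, n)
        truth = leaf_path_lengths(true)
        taxa = sorted(x.name for x in true.leaves())
        d = np.zeros((n, n))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    d[i, j] = truth[frozenset((a, b))]
        perm = list(rng.permutation(n))
        tree_a = neighbor_joining(DistanceMatrix(taxa, d))
        tree_b = neighbor_joining(
            DistanceMatrix([taxa[i] for i in perm], d[np.ix_(perm, perm)])
        )
        assert leaf_path_lengths(tree_a) == pytest.approx(leaf_path_lengths(tree_b))

    def test_agrees_with_scikit_bio(self, rng):
        import io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        n = 7
        true = random_tree(rng, n)
        truth = leaf_path_lengths(true)
        taxa = sorted(x.name for x in true.leaves())
        d = np.zeros((n, n))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    d[i, j] = truth[frozenset((a, b))]
        ours = neighbor_joining(DistanceMatrix(taxa, d))
        theirs = skbio_nj(SkbioDM(d, taxa))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    assert theirs.find(a).distance(theirs.find(b)) == pytest.approx(
                        leaf_path_lengths(ours)[frozenset((a, b))], abs=1e-6
                    )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestCladeLabelling:
    def test_simple_cherry(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        lt = label_numt_clade(t, {"a", "b"})
        labels = {(n.name, n.is_leaf): n.branch_class for n in lt.branches()}
        numt_branches = [n for n in lt.branches() if n.branch_class == NUMT]
        assert len(numt_branches) == 3  # a, b, and their stem

    def test_all_leaves(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        lt = label_numt_clade(t, {"a", "b", "c", "d"})
        assert all(n.branch_class == NUMT for n in lt.branches())

    def test_non_monophyletic_raises(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="monophyletic"):
            label_numt_clade(t, {"a", "c"})

    def test_complement_side_clade(self):
        # {b, c, d} is a clade in the unrooted sense on this rooting
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        lt = label_numt_clade(t, {"b", "c", "d"})
        a_leaf = [n for n in lt.branches() if n.name == "a"][0]
        assert a_leaf.branch_class == BACKGROUND
        assert sum(n.branch_class == NUMT for n in lt.branches()) == 5


class TestNewick:
    def test_round_trip_with_lengths_and_classes(self):
        text = "((a#numt:0.100000,b#numt:0.200000)#numt:0.050000,c:0.300000,d:0.250000);"
        tree = parse_newick(text)
        assert write_newick(tree) == text

    def test_distance_matrix_from_alignment(self, rng):
        a = random_dna(rng, 500)
        seqs = [a, mutate(rng, a, 0.02), mutate(rng, a, 0.05)]
        dm = distance_matrix(["x", "y", "z"], seqs)
        assert dm.d[0, 1] < dm.d[0, 2]
        assert np.allclose(dm.d, dm.d.T)
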