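"""Newick I/O, bipartition algebra, majority-rule and strict consensus."""

from itertools import combinations

import numpy as np
import pytest

import dendropy

from macromap.trees import (SupportTree, TreeError, majority_rule_consensus,
                            read_tree_set, strict_consensus, tree_from_splits,
                            write_tree_set)


def tree(newick: str) -> SupportTree:
    (t,) = read_tree_set(newick)
    return t


def brute_force_splits(t: SupportTree) -> set[frozenset[str]]:
    """All leaf subsets that are a side of some bipartition of the tree.

    A subset S is a split side iff both S and its complement induce
    connected subtrees; equivalently, S appears as the leaf set under
    some internal edge.  Checked by enumerating every subset (<= 2^n)
    and testing it against the clades of the tree rooted anywhere,
    remembering that an unrooted split is a clade in at least one of the
    two orientations.
    """
    leaves = sorted(t.leaf_labels)
    ref = leaves[0]
    clades = set()
    for node in t.root.walk():
        clades.add(frozenset(node.leaves()))
    full = frozenset(leaves)
    out = set()
    for r in range(2, len(leaves) - 1):
        for sub in combinations(leaves, r):
            s = frozenset(sub)
            if s in clades or (full - s) in clades:
                if ref in s:
                    s = full - s
                out.add(s)
    return out


class TestReadWrite:
    def test_basic_parse_with_support(self):
        t = tree("((Pg1,Pg2)95,(AT1,Os1));")
        assert t.leaf_labels == {"Pg1", "Pg2", "AT1", "Os1"}
        assert t.splits() == {frozenset({"Pg1", "Pg2"}): 95.0}
        assert t.classes["Pg1"] == "focal_gymno"
        assert t.classes["Os1"] == "angiosperm"

    def test_unknown_prefix_rejected(self):
        with pytest.raises(TreeError, match="Zz9"):
            tree("((Pg1,Zz9),(AT1,Os1));")

    def test_malformed_newick_rejected(self):
        with pytest.raises(TreeError, match="parse"):
            read_tree_set("((Pg1,Pg2),(AT1,Os1;")

    def test_large_tree_set_round_trips(self, tmp_path):
        rng = np.random.default_rng(0)
        labels = [f"Pg{i}" for i in range(5)] + ["AT1", "Os1"]
        trees = []
        for _ in range(500):
            order = list(rng.permutation(labels))
            nwk = f"(({order[0]},{order[1]})88,({order[2]},{order[3]})77," \
                  f"({order[4]},({order[5]},{order[6]})66)55);"
            trees.append(tree(nwk))
        p = tmp_path / "boot.nwk"
        write_tree_set(trees, p)
        back = read_tree_set(p)
        assert len(back) == 500
        for a, b in zip(trees, back):
            assert a.splits() == b.splits()


class TestConsensus:
    def test_identical_trees_full_support(self):
        t = tree("((AT1,AT2),((Os1,Os2),(Pg1,Pg2)));")
        cons = majority_rule_consensus([t, t, t])
        assert set(cons.splits()) == set(t.splits())
        assert all(v == pytest.approx(100.0) for v in cons.splits().values())

    def test_two_to_one_majority(self):
        ab = tree("((AT1,AT2),(Os1,Os2));")
        ac = tree("((AT1,Os1),(AT2,Os2));")
        cons = majority_rule_consensus([ab, ab, ac])
        assert cons.splits() == {frozenset({"Os1", "Os2"}): pytest.approx(200 / 3)}

    def test_exact_half_excluded_gives_star(self):
        ab = tree("((AT1,AT2),(Os1,Os2));")
        ac = tree("((AT1,Os1),(AT2,Os2));")
        cons = majority_rule_consensus([ab, ac])
        assert cons.splits() == {}

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(TreeError, match="leaf sets"):
            majority_rule_consensus([tree("((AT1,AT2),(Os1,Os2));"),
                                     tree("((AT1,AT2),(Os1,Os3));")])

    def test_strict_consensus_idempotent(self):
        t = tree("((AT1,AT2),((Os1,Os2),(Pg1,Pg2)));")
        assert strict_consensus(t, t).splits().keys() == t.splits().keys()

    def test_strict_consensus_with_star_is_star(self):
        t = tree("((AT1,AT2),(Os1,Os2));")
        star = tree("(AT1,AT2,Os1,Os2);")
        assert strict_consensus(t, star).splits() == {}

    def test_strict_consensus_keeps_shared_split_only(self):
        t1 = tree("((AT1,AT2),Os1,(Os2,Os3));")
        t2 = tree("((AT1,AT2),(Os1,Os2),Os3);")
        cons = strict_consensus(t1, t2)
        # the shared AT1,AT2 | Os1,Os2,Os3 split, normalised away from AT1
        assert set(cons.splits()) == {frozenset({"Os1", "Os2", "Os3"})}

    def test_majority_supports_in_half_open_interval(self):
        rng = np.random.default_rng(1)
        labels = ["AT1", "AT2", "Os1", "Os2", "Pg1", "Pg2"]
        trees = [random_tree(rng, labels) for _ in range(9)]
        cons = majority_rule_consensus(trees)
        for s, sup in cons.splits().items():
            assert 50.0 < sup <= 100.0
            assert any(s in t.splits() for t in trees)


def random_tree(rng: np.random.Generator, labels) -> SupportTree:
    """Random binary topology over the labels, all supports 100."""
    from macromap.simulate import _random_binary
    from macromap.trees import Node, DEFAULT_PREFIX_CLASSES, classify_leaf

    tips = [Node(label=l) for l in labels]
    root = _random_binary(rng, tips)
    for n in root.walk():
        if not n.is_leaf and n is not root:
            n.support = 100.0
    classes = {l: classify_leaf(l, DEFAULT_PREFIX_CLASSES) for l in labels}
    return SupportTree(root, classes)


class TestBruteForceOracles:
    """Consensus and split extraction vs exhaustive subset enumeration."""

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_splits_match_subset_enumeration(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        labels = [f"Pg{i}" for i in range(n_leaves - 2)] + ["AT1", "Os1"]
        for _ in range(10):
            t = random_tree(rng, labels)
            assert set(t.splits()) == brute_force_splits(t)

    @pytest.mark.parametrize("n_leaves", [5, 6, 8])
    def test_majority_consensus_matches_enumeration(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        labels = [f"Pg{i}" for i in range(n_leaves - 2)] + ["AT1", "Os1"]
        trees = [random_tree(rng, labels) for _ in range(7)]
        cons = majority_rule_consensus(trees)
        # oracle: count every subset's occurrence as a split across inputs
        all_sides = [brute_force_splits(t) for t in trees]
        expect = {}
        for s in set().union(*all_sides):
            c = sum(s in sides for sides in all_sides)
            if c > len(trees) / 2:
                expect[s] = 100.0 * c / len(trees)
        got = cons.splits()
        assert set(got) == set(expect)
        for s in expect:
            assert got[s] == pytest.approx(expect[s])

    @pytest.mark.parametrize("n_leaves", [5, 6, 8])
    def test_strict_consensus_matches_enumeration(self, n_leaves):
        rng = np.random.default_rng(200 + n_leaves)
        labels = [f"Pg{i}" for i in range(n_leaves - 2)] + ["AT1", "Os1"]
        t1, t2 = random_tree(rng, labels), random_tree(rng, labels)
        cons = strict_consensus(t1, t2)
        assert set(cons.splits()) == brute_force_splits(t1) & brute_force_splits(t2)

    def test_majority_consensus_agrees_with_dendropy(self):
        """Independent cross-check against dendropy's consensus machinery."""
        rng = np.random.default_rng(7)
        labels = [f"Pg{i}" for i in range(4)] + ["AT1", "Os1"]
        trees = [random_tree(rng, labels) for _ in range(11)]
        cons = majority_rule_consensus(trees)

        tl = dendropy.TreeList.get(
            data="\n".join(t.newick() for t in trees), schema="newick")
        dcons = tl.consensus(min_freq=0.5 + 1e-9)
        dtree = read_tree_set(dcons.as_string(schema="newick",
                                              suppress_rooting=True))[0]
        assert set(cons.splits()) == set(dtree.splits())


class TestTreeFromSplits:
    def test_incompatible_splits_rejected(self):
        leaves = frozenset({"AT1", "Os1", "Pg1", "Pg2", "Pg3"})
        classes = {l: "angiosperm" if l[0] == "A" or l[0] == "O" else "focal_gymno"
                   for l in leaves}
        bad = {frozenset({"Pg1", "Pg2"}): None, frozenset({"Pg2", "Pg3"}): None}
        with pytest.raises(TreeError, match="incompatible"):
            tree_from_splits(leaves, bad, classes)

    def test_round_trip_through_newick(self):
        t = tree("((AT1,AT2)90,((Os1,Os2)80,(Pg1,Pg2)70)60);")
        back = read_tree_set(t.newick())[0]
        assert back.splits() == t.splits()
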