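import numpy as np
import pytest

from ogphylo.distance import DistanceMatrix
from ogphylo.trees import (
    PhyloTree,
    TreeNode,
    bipartitions,
    majority_consensus,
    nj,
    parse_newick,
    upgma,
)


def leaf_distances(tree: PhyloTree) -> DistanceMatrix:
    """Path-length matrix between leaves, for recovery checks."""
    names = sorted(tree.root.leaf_names())
    idx = {n: i for i, n in enumerate(names)}
    k = len(names)
    values = np.zeros((k, k))

    def walk(node, dist_to_leaves):
        if node.is_leaf():
            return {node.name: 0.0}
        below = {}
        groups = []
        for child in node.children:
            sub = walk(child, dist_to_leaves)
            sub = {leaf: d + (child.length or 0.0) for leaf, d in sub.items()}
            groups.append(sub)
            below.update(sub)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for la, da in groups[gi].items():
                    for lb, db in groups[gj].items():
                        values[idx[la], idx[lb]] = values[idx[lb], idx[la]] = da + db
        return below

    walk(tree.root, None)
    return DistanceMatrix(taxa=names, values=values)


def random_ultrametric_tree(rng, n_leaves):
    """Random coalescent-style rooted ultrametric tree."""
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    heights = [0.0] * n_leaves
    h = 0.0
    while len(nodes) > 1:
        h += float(rng.uniform(0.5, 2.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = h - heights[i]
        b.length = h - heights[j]
        parent = TreeNode(children=[a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
        heights = [x for k, x in enumerate(heights) if k not in (i, j)] + [h]
    return PhyloTree(root=nodes[0], rooted=True)


def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.5, 2.0))
        b.length = float(rng.uniform(0.5, 2.0))
        parent = TreeNode(children=[a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    for x in nodes:
        if x.length is None:
            x.length = float(rng.uniform(0.5, 2.0))
    return PhyloTree(root=TreeNode(children=nodes), rooted=False)


class TestUPGMA:
    def test_hand_agglomeration(self):
        m = DistanceMatrix(
            taxa=["A", "B", "C"],
            values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        tree = upgma(m)
        assert tree.to_newick() == "((A:1,B:1):1,C:2);"

    def test_equal_distances_tie_rule(self):
        m = DistanceMatrix(taxa=["C", "A", "B"], values=np.full((3, 3), 2.0) - 2 * np.eye(3))
        tree = upgma(m)
        # lexicographically smallest pair (A, B) merges first
        first = tree.root.children[0]
        assert sorted(first.leaf_names()) == ["A", "B"]

    def test_ultrametric(self, rng):
        for _ in range(10):
            t = random_ultrametric_tree(rng, 8)
            m = leaf_distances(t)
            out = upgma(m)
            depths = []

            def depth(node, acc):
                if node.is_leaf():
                    depths.append(acc + (node.length or 0))
                for c in node.children:
                    depth(c, acc + (node.length or 0))

            depth(out.root, 0.0)
            assert max(depths) - min(depths) < 1e-9

    def test_exact_recovery(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            truth = random_ultrametric_tree(rng, n)
            m = leaf_distances(truth)
            recovered = upgma(m)
            assert bipartitions(recovered) == bipartitions(truth)
            m2 = leaf_distances(recovered)
            assert np.allclose(m.values, m2.values, atol=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            upgma(
                type("M", (), {"taxa": ["A", "B"], "values": np.array([[0, 1], [2, 0]])})
            )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            upgma(
                type(
                    "M", (), {
                        "taxa": ["A", "B"],
                        "values": np.array([[0.0, -1.0], [-1.0, 0.0]]),
                    }
                )
            )


class TestNJ:
    def test_four_taxon_hand_example(self):
        # additive matrix of ((A:1,B:2):1,(C:3,D:4)) with internal edge 1
        m = DistanceMatrix(
            taxa=["A", "B", "C", "D"],
            values=np.array(
                [
                    [0, 3, 5, 6],
                    [3, 0, 6, 7],
                    [5, 6, 0, 7],
                    [6, 7, 7, 0],
                ],
                dtype=float,
            ),
        )
        tree = nj(m)
        splits = bipartitions(tree)
        assert splits == {frozenset({"C", "D"})}
        recomputed = leaf_distances(tree)
        assert np.allclose(recomputed.values, m.values, atol=1e-9)

    def test_three_taxa_closed_form(self):
        m = DistanceMatrix(
            taxa=["A", "B", "C"],
            values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        tree = nj(m)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_exact_recovery_random_additive(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            truth = random_additive_tree(rng, n)
            m = leaf_distances(truth)
            recovered = nj(m)
            assert bipartitions(recovered) == bipartitions(truth)
            assert np.allclose(leaf_distances(recovered).values, m.values, atol=1e-9)

    def test_unrooted_output(self, rng):
        t = nj(leaf_distances(random_additive_tree(rng, 5)))
        assert not t.rooted
        assert len(t.root.children) == 3

    def test_negative_branch_clamped(self):
        # nearly-degenerate matrix can produce a negative internal estimate
        m = DistanceMatrix(
            taxa=["A", "B", "C", "D"],
            values=np.array(
                [
                    [0, 2, 2, 2.1],
                    [2, 0, 2.1, 2],
                    [2, 2.1, 0, 2],
                    [2.1, 2, 2, 0],
                ]
            ),
        )
        tree = nj(m)
        for node in tree.root.traverse_preorder():
            if node.length is not None:
                assert node.length >= 0


class TestPermutationEquivariance:
    def test_upgma_label_permutation(self, rng):
        truth = random_ultrametric_tree(rng, 7)
        m = leaf_distances(truth)
        perm = list(rng.permutation(len(m.taxa)))
        m2 = DistanceMatrix(
            taxa=[m.taxa[p] for p in perm],
            values=m.values[np.ix_(perm, perm)],
        )
        assert bipartitions(upgma(m)) == bipartitions(upgma(m2))


class TestConsensus:
    def test_identical_trees_full_support(self):
        trees = [parse_newick("((A:1,B:1):1,(C:1,D:1):1);") for _ in range(10)]
        cons = majority_consensus(trees)
        assert bipartitions(cons) == bipartitions(trees[0])
        supports = [
            n.support
            for n in cons.root.traverse_preorder()
            if not n.is_leaf() and n is not cons.root
        ]
        assert supports and all(s == 100 for s in supports)

    def test_sixty_percent_split(self):
        t_ab = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t_ac = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        cons = majority_consensus([t_ab] * 6 + [t_ac] * 4)
        # canonical side is the one not containing 'A'
        assert bipartitions(cons) == {frozenset({"C", "D"})}
        node = next(
            n for n in cons.root.traverse_preorder()
            if not n.is_leaf() and n is not cons.root
        )
        assert node.support == 60

    def test_no_majority_gives_star(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        cons = majority_consensus([t1, t2])
        assert bipartitions(cons) == set()
        assert len(cons.root.children) == 4

    def test_taxa_mismatch_errors(self):
        t1 = parse_newick("((A:1,B:1):1,C:1);")
        t2 = parse_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError, match="taxa"):
            majority_consensus([t1, t2])

    def test_single_tree(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        cons = majority_consensus([t])
        assert bipartitions(cons) == bipartitions(t)

    def test_supports_in_half_open_range(self, rng):
        base = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        alt = parse_newick("(((A:1,C:1):1,B:1):1,(D:1,E:1):1);")
        cons = majority_consensus([base] * 7 + [alt] * 3)
        for n in cons.root.traverse_preorder():
            if not n.is_leaf() and n is not cons.root and n.support is not None:
                assert 50 < n.support <= 100
                assert float(n.support).is_integer()
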