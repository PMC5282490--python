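"""Stage II: distances, WPGMA trees, weights and tree distances."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from probmsa.guidetree import (GuideTree, Node, rank_normalize,
                               score_to_distance, tree_distance_matrix, upgma)
from probmsa.testkit import oracles


def test_score_to_distance_arithmetic():
    assert score_to_distance(3.0, 4, 6) == pytest.approx(0.25)
    assert score_to_distance(0.0, 5, 5) == 1.0
    assert score_to_distance(3.99, 4, 9) == pytest.approx(1 - 3.99 / 4)
    with pytest.raises(ValueError, match="zero-length"):
        score_to_distance(1.0, 0, 5)


def test_rank_normalize_three_distinct_values():
    D = np.array([[0, 0.3, 0.9], [0.3, 0, 0.5], [0.9, 0.5, 0]])
    out = rank_normalize(D)
    assert sorted(out[np.triu_indices(3, 1)]) == [0.0, 0.5, 1.0]


def test_rank_normalize_ties_share_mean_rank():
    D = np.full((4, 4), 0.7)
    np.fill_diagonal(D, 0.0)
    out = rank_normalize(D)
    assert np.allclose(out[np.triu_indices(4, 1)], 0.5)


def test_rank_normalize_is_monotone_transform():
    rng = np.random.default_rng(2)
    D = rng.random((5, 5))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    out = rank_normalize(D)
    iu = np.triu_indices(5, 1)
    rho, _ = spearmanr(D[iu], out[iu])
    assert rho == pytest.approx(1.0)


def test_upgma_two_leaves():
    tree = upgma(np.array([[0, 1.0], [1.0, 0]]), ["a", "b"])
    assert tree.root.height == pytest.approx(0.5)
    assert all(c.branch_length == pytest.approx(0.5)
               for c in tree.root.children)


def test_upgma_three_taxa_hand_example():
    D = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
    tree = upgma(D, ["a", "b", "c"])
    assert tree.root.height == pytest.approx(4.0)
    inner = [c for c in tree.root.children if not c.is_leaf][0]
    assert sorted(inner.leaf_ids()) == ["a", "b"]
    assert inner.height == pytest.approx(1.0)
    assert inner.branch_length == pytest.approx(3.0)
    leaf_c = [c for c in tree.root.children if c.is_leaf][0]
    assert leaf_c.branch_length == pytest.approx(4.0)


def _merge_set(tree: GuideTree):
    index = {sid: i for i, sid in enumerate(tree.ids)}
    merges = set()
    for node in tree.root.postorder():
        if node.is_leaf:
            continue
        l, r = node.children
        merges.add(frozenset((frozenset(index[s] for s in l.leaf_ids()),
                              frozenset(index[s] for s in r.leaf_ids()))))
    return merges


@pytest.mark.parametrize("seed", range(6))
def test_upgma_matches_independent_wpgma(seed):
    rng = np.random.default_rng(seed)
    D = rng.random((6, 6))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    tree = upgma(D, list("abcdef"))
    topo, heights = oracles.brute_upgma(D)
    assert _merge_set(tree) == topo
    index = {sid: i for i, sid in enumerate(tree.ids)}
    for node in tree.root.postorder():
        if node.is_leaf:
            continue
        leafset = frozenset(index[s] for s in node.leaf_ids())
        assert node.height == pytest.approx(heights[leafset], abs=1e-12)


@pytest.mark.parametrize("seed", range(4))
def test_upgma_is_ultrametric(seed):
    rng = np.random.default_rng(10 + seed)
    D = rng.random((7, 7))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    tree = upgma(D, list("abcdefg"))
    depths = {}
    def walk(node, depth):
        depth += node.branch_length
        if node.is_leaf:
            depths[node.id] = depth
        for c in node.children:
            walk(c, depth)
    walk(tree.root, -tree.root.branch_length)
    vals = list(depths.values())
    assert max(vals) - min(vals) < 1e-9
    assert tree.root.height >= max(n.height for n in tree.root.postorder()) - 1e-12


def _caterpillar3():
    a = Node(id="a", branch_length=1.0)
    b = Node(id="b", branch_length=1.0)
    ab = Node(children=(a, b), branch_length=0.5)
    c = Node(id="c", branch_length=2.0)
    root = Node(children=(ab, c))
    return GuideTree(root, ["a", "b", "c"])


def test_sequence_weights_hand_computed_caterpillar():
    # a = b = 1 + 0.5/2 = 1.25, c = 2; normalize by 4.5
    w = _caterpillar3().sequence_weights()
    assert w["a"] == pytest.approx(1.25 / 4.5)
    assert w["b"] == pytest.approx(1.25 / 4.5)
    assert w["c"] == pytest.approx(2.0 / 4.5)
    assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)


def test_weights_two_leaves_and_balanced_tree():
    tree = upgma(np.array([[0, 1.0], [1.0, 0]]), ["a", "b"])
    assert tree.sequence_weights() == pytest.approx({"a": 0.5, "b": 0.5})
    # perfectly balanced, equal branch lengths -> uniform
    leaves = [Node(id=s, branch_length=1.0) for s in "abcd"]
    left = Node(children=(leaves[0], leaves[1]), branch_length=1.0)
    right = Node(children=(leaves[2], leaves[3]), branch_length=1.0)
    tree4 = GuideTree(Node(children=(left, right)), list("abcd"))
    assert all(v == pytest.approx(0.25)
               for v in tree4.sequence_weights().values())


def test_zero_branch_lengths_fall_back_to_uniform():
    leaves = [Node(id=s) for s in "abc"]
    root = Node(children=(Node(children=(leaves[0], leaves[1])), leaves[2]))
    w = GuideTree(root, ["a", "b", "c"]).sequence_weights()
    assert all(v == pytest.approx(1 / 3) for v in w.values())


def test_weights_invariant_to_leaf_order():
    rng = np.random.default_rng(3)
    D = rng.random((5, 5))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    ids = list("abcde")
    w1 = upgma(D, ids).sequence_weights()
    perm = [3, 1, 4, 0, 2]
    Dp = D[np.ix_(perm, perm)]
    w2 = upgma(Dp, [ids[i] for i in perm]).sequence_weights()
    for sid in ids:
        assert w1[sid] == pytest.approx(w2[sid], abs=1e-12)


def test_tree_distance_siblings_and_root():
    tree = _caterpillar3()
    assert tree.tree_distance("a", "b") == 3
    assert tree.tree_distance("a", "c") == 5  # whole tree: 2N-1
    assert tree.tree_distance("b", "b") == 1
    assert tree.tree_distance("a", "c") == tree.tree_distance("c", "a")
    with pytest.raises(KeyError, match="unknown leaf"):
        tree.tree_distance("a", "zz")


def test_tree_distance_matches_brute_force_subtree_search():
    # 5-leaf caterpillar
    nodes = {0: Node(id="L0", branch_length=1.0)}
    current = nodes[0]
    for k in range(1, 5):
        leaf = Node(id=f"L{k}", branch_length=1.0)
        current = Node(children=(current, leaf), branch_length=1.0)
    tree = GuideTree(current, [f"L{k}" for k in range(5)])
    # independent parent/size maps for the oracle
    ids = {}
    parent_of = {}
    sizes = {}
    for n in tree.root.postorder():
        ids[id(n)] = len(ids)
    for n in tree.root.postorder():
        sizes[ids[id(n)]] = sum(1 for _ in n.postorder())
        for c in n.children:
            parent_of[ids[id(c)]] = ids[id(n)]
    leaf_key = {n.id: ids[id(n)] for n in tree.root.postorder() if n.is_leaf}
    for x in range(5):
        for y in range(x + 1, 5):
            want = oracles.minimal_subtree_size(
                parent_of, sizes, leaf_key[f"L{x}"], leaf_key[f"L{y}"])
            assert tree.tree_distance(f"L{x}", f"L{y}") == want


def test_tree_distance_monotone_toward_ancestors():
    seqs_tree = _caterpillar3()
    # LCA(a, c) is an ancestor of LCA(a, b)
    assert seqs_tree.tree_distance("a", "b") <= seqs_tree.tree_distance("a", "c")


def test_tree_distance_matrix_diagonal_is_one(small_family):
    _, _, tree = small_family
    M = tree_distance_matrix(tree)
    assert np.all(np.diag(M) == 1)
    assert np.all(M == M.T)


def test_upgma_rejects_asymmetric_input():
    with pytest.raises(ValueError, match="symmetric"):
        upgma(np.array([[0, 1.0], [2.0, 0]]), ["a", "b"])


def test_newick_export_round_trips_through_dendropy():
    import dendropy

    tree = _caterpillar3()
    t = dendropy.Tree.get(data=tree.newick(), schema="newick")
    assert sorted(l.taxon.label for l in t.leaf_node_iter()) == ["a", "b", "c"]
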