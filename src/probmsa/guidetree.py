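"""Stage II: pairwise distances, weighted UPGMA guide tree, sequence weights.

Distances come from stage-I MEA scores via d = 1 - score/min(len); the tree
is built with the WPGMA update (arithmetic mean of the merged clusters'
distances), which is the reading of "weighted UPGMA" adopted here; a
size-weighted (classic UPGMA) update is available behind a flag.  The tree
carries ultrametric heights, per-node subtree sizes (node counts) and
ClustalW-style sequence weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence as Seq, Tuple

import numpy as np
from scipy.stats import rankdata


def score_to_distance(mea_score: float, len_x: int, len_y: int) -> float:
    """d = 1 - score / min(len_x, len_y), clamped to [0, 1]."""
    if len_x < 1 or len_y < 1:
        raise ValueError("zero-length sequence")
    if mea_score < 0:
        raise ValueError("MEA score must be non-negative")
    return float(min(1.0, max(0.0, 1.0 - mea_score / min(len_x, len_y))))


def distance_matrix_from_scores(scores: np.ndarray, lengths: Seq[int]) -> np.ndarray:
    n = scores.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = score_to_distance(scores[i, j],
                                                  lengths[i], lengths[j])
    return D


def validate_distance_matrix(D: np.ndarray) -> None:
    D = np.asarray(D)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(D)):
        raise ValueError("distances must be finite")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("diagonal must be zero")


def rank_normalize(D: np.ndarray) -> np.ndarray:
    """Replace off-diagonal entries by their mean-rank / (count - 1).

    Ties share the mean rank, so an all-equal matrix maps to all 0.5.  The
    output is a monotone (order-isomorphic) transform of the input in [0, 1].
    """
    validate_distance_matrix(D)
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = D[iu]
    if vals.size == 1:
        normed = np.array([0.5])
    else:
        normed = (rankdata(vals, method="average") - 1.0) / (vals.size - 1)
    out = np.zeros_like(np.asarray(D, dtype=float))
    out[iu] = normed
    out = out + out.T
    return out


@dataclass
class Node:
    """Guide-tree node; leaves carry a sequence id."""

    id: Optional[str] = None
    children: Tuple["Node", ...] = ()
    branch_length: float = 0.0
    height: float = 0.0
    parent: Optional["Node"] = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    @property
    def subtree_size(self) -> int:
        """Number of nodes (leaves + internal) in the subtree."""
        return sum(1 for _ in self.postorder())

    def leaf_ids(self) -> List[str]:
        return [n.id for n in self.postorder() if n.is_leaf]

    def newick(self) -> str:
        def rec(n: Node) -> str:
            if n.is_leaf:
                return f"{n.id}:{n.branch_length:.6g}"
            inner = ",".join(rec(c) for c in n.children)
            return f"({inner}):{n.branch_length:.6g}"
        if self.is_leaf:
            return f"{self.id};"
        inner = ",".join(rec(c) for c in self.children)
        return f"({inner});"


class GuideTree:
    """Rooted binary guide tree with weights and node-count tree distances."""

    def __init__(self, root: Node, ids: Seq[str]):
        self.root = root
        self.ids = tuple(ids)
        self._leaves: Dict[str, Node] = {}
        for node in root.postorder():
            for c in node.children:
                c.parent = node
            if node.is_leaf:
                self._leaves[node.id] = node
        if set(self._leaves) != set(ids):
            raise ValueError("tree leaves do not match sequence ids")
        self._sizes: Dict[int, int] = {}
        for node in root.postorder():
            if node.is_leaf:
                self._sizes[id(node)] = 1
            else:
                self._sizes[id(node)] = 1 + sum(self._sizes[id(c)]
                                                for c in node.children)
        self._weights: Optional[Dict[str, float]] = None

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def leaf(self, sid: str) -> Node:
        try:
            return self._leaves[sid]
        except KeyError:
            raise KeyError(f"unknown leaf id {sid!r}") from None

    def subtree_size(self, node: Node) -> int:
        return self._sizes[id(node)]

    def lca(self, x: str, y: str) -> Node:
        a, b = self.leaf(x), self.leaf(y)
        ancestors = set()
        node = a
        while node is not None:
            ancestors.add(id(node))
            node = node.parent
        node = b
        while id(node) not in ancestors:
            node = node.parent
        return node

    def tree_distance(self, x: str, y: str) -> int:
        """Node count of the minimal subtree containing both leaves."""
        if x == y:
            self.leaf(x)
            return 1
        return self.subtree_size(self.lca(x, y))

    def sequence_weights(self) -> Dict[str, float]:
        """ClustalW weights: each branch length split equally over the
        leaves beneath it, summed per leaf, normalized to sum 1.  A tree
        with all-zero branch lengths falls back to uniform weights."""
        if self._weights is not None:
            return self._weights
        raw = {sid: 0.0 for sid in self.ids}
        for node in self.root.postorder():
            if node is self.root:
                continue
            below = node.leaf_ids()
            share = node.branch_length / len(below)
            for sid in below:
                raw[sid] += share
        total = sum(raw.values())
        if total <= 0:
            w = {sid: 1.0 / len(self.ids) for sid in self.ids}
        else:
            w = {sid: v / total for sid, v in raw.items()}
        self._weights = w
        return w

    def merge_order(self):
        """Internal nodes in postorder: the progressive alignment schedule."""
        return [n for n in self.root.postorder() if not n.is_leaf]

    def internal_edges(self) -> List[Node]:
        """Nodes (other than the root) whose parent edge is breakable."""
        return [n for n in self.root.postorder() if n is not self.root]

    def newick(self) -> str:
        return self.root.newick()


def upgma(D: np.ndarray, ids: Seq[str], variant: str = "wpgma") -> GuideTree:
    """Agglomerative guide tree from a distance matrix.

    ``variant='wpgma'`` (default) averages the two merged clusters'
    distances; ``'upgma'`` weights by cluster leaf counts.  Ties on the
    minimal distance break to the lowest (row, col) cluster-index pair,
    making the construction deterministic.  Heights are ultrametric
    (cluster height = d/2); branch lengths are height differences.
    """
    validate_distance_matrix(D)
    n = len(ids)
    if D.shape[0] != n:
        raise ValueError("ids do not match distance matrix")
    if n == 1:
        return GuideTree(Node(id=ids[0]), ids)
    if variant not in ("wpgma", "upgma"):
        raise ValueError(f"unknown variant {variant!r}")
    nodes: List[Node] = [Node(id=s) for s in ids]
    sizes = [1] * n
    dist = np.asarray(D, dtype=float).copy()
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                d = dist[active[ai], active[aj]]
                if best is None or d < best[0] - 1e-15:
                    best = (d, ai, aj)
        d, ai, aj = best
        i, j = active[ai], active[aj]
        height = d / 2.0
        left, right = nodes[i], nodes[j]
        left.branch_length = max(0.0, height - left.height)
        right.branch_length = max(0.0, height - right.height)
        merged = Node(children=(left, right), height=height)
        # grow the matrix by one row/col for the merged cluster
        k = dist.shape[0]
        dist = np.pad(dist, ((0, 1), (0, 1)))
        for a in active:
            if a in (i, j):
                continue
            if variant == "wpgma":
                nd = 0.5 * (dist[i, a] + dist[j, a])
            else:
                nd = (sizes[i] * dist[i, a] + sizes[j] * dist[j, a]) / (
                    sizes[i] + sizes[j])
            dist[k, a] = dist[a, k] = nd
        nodes.append(merged)
        sizes.append(sizes[i] + sizes[j])
        active = [a for a in active if a not in (i, j)] + [k]
    root = nodes[active[0]]
    return GuideTree(root, ids)


def tree_distance_matrix(tree: GuideTree) -> np.ndarray:
    ids = tree.ids
    n = len(ids)
    M = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = tree.tree_distance(ids[i], ids[j])
    np.fill_diagonal(M, 1.0)
    return M
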