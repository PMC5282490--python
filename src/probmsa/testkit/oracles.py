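"""Exponential-time reference implementations used only in tests.

These deliberately share no code with the production modules: alignments
are enumerated as explicit op strings, consistency is a dense triple loop,
and clustering re-derives the WPGMA recurrence from scratch.  Hard size
caps keep each oracle within seconds.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np

_MAX_ENUM_LEN = 7


def enumerate_pairwise_alignments(nx: int, ny: int) -> Iterator[str]:
    """All monotone global alignments of nx vs ny residues as op strings
    over M (match), X (residue of x unmatched), Y (residue of y unmatched)."""
    if nx > _MAX_ENUM_LEN or ny > _MAX_ENUM_LEN:
        raise ValueError("enumeration oracle capped at length 7")

    def rec(i: int, j: int, prefix: str) -> Iterator[str]:
        if i == nx and j == ny:
            yield prefix
            return
        if i < nx and j < ny:
            yield from rec(i + 1, j + 1, prefix + "M")
        if i < nx:
            yield from rec(i + 1, j, prefix + "X")
        if j < ny:
            yield from rec(i, j + 1, prefix + "Y")

    yield from rec(0, 0, "")


def delannoy(m: int, n: int) -> int:
    """Count of monotone alignments, by the independent lattice recursion."""
    table = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 or j == 0:
                table[i][j] = 1
            else:
                table[i][j] = (table[i - 1][j] + table[i][j - 1]
                               + table[i - 1][j - 1])
    return table[m][n]


def hmm_posterior_oracle(x_idx, y_idx, pi, trans, match_emit,
                         ins_emit) -> np.ndarray:
    """Posterior match probabilities by exhaustive path enumeration.

    A path's weight is pi[first state] times transition and emission
    products (no end state).  Cell (i, j) accumulates the weights of all
    alignments that match residue i of x with residue j of y, divided by
    the total weight.
    """
    nx, ny = len(x_idx), len(y_idx)
    post = np.zeros((nx, ny))
    total = 0.0
    state_of = {"M": 0, "X": 1, "Y": 2}
    for ops in enumerate_pairwise_alignments(nx, ny):
        w = 1.0
        prev = None
        i = j = 0
        cells: List[Tuple[int, int]] = []
        for op in ops:
            s = state_of[op]
            w *= pi[s] if prev is None else trans[prev, s]
            if op == "M":
                w *= match_emit[x_idx[i], y_idx[j]]
                cells.append((i, j))
                i += 1
                j += 1
            elif op == "X":
                w *= ins_emit[x_idx[i]]
                i += 1
            else:
                w *= ins_emit[y_idx[j]]
                j += 1
            prev = s
        total += w
        for (a, b) in cells:
            post[a, b] += w
    return post / total


def partition_posterior_oracle(x_idx, y_idx, scores, gap_open, gap_ext,
                               temperature) -> np.ndarray:
    """Boltzmann pairing probabilities by exhaustive enumeration.

    Alignment energy: sum of substitution scores minus, per gap run of
    length k, gap_open + (k-1) * gap_ext; weight exp(energy/T).
    """
    nx, ny = len(x_idx), len(y_idx)
    post = np.zeros((nx, ny))
    total = 0.0
    for ops in enumerate_pairwise_alignments(nx, ny):
        energy = 0.0
        i = j = 0
        prev = None
        cells: List[Tuple[int, int]] = []
        for op in ops:
            if op == "M":
                energy += scores[x_idx[i], y_idx[j]]
                cells.append((i, j))
                i += 1
                j += 1
            else:
                energy -= gap_ext if op == prev else gap_open
                if op == "X":
                    i += 1
                else:
                    j += 1
            prev = op
        w = np.exp(energy / temperature)
        total += w
        for (a, b) in cells:
            post[a, b] += w
    return post / total


def mea_score_oracle(S: np.ndarray) -> float:
    """Best match-sum over all monotone alignments, by enumeration."""
    nx, ny = S.shape
    best = 0.0
    for ops in enumerate_pairwise_alignments(nx, ny):
        i = j = 0
        score = 0.0
        for op in ops:
            if op == "M":
                score += S[i, j]
                i += 1
                j += 1
            elif op == "X":
                i += 1
            else:
                j += 1
        best = max(best, score)
    return best


# the profile-column matching problem has the same search space; the alias
# makes test intent explicit
brute_column_match = mea_score_oracle


def dense_consistency(mats: Dict[Tuple[int, int], np.ndarray],
                      weights, h: float = 1.0, cap: int = 200,
                      ) -> Dict[Tuple[int, int], np.ndarray]:
    """One full-consistency transformation as a dense triple loop.

    ``mats`` holds dense S_xy for i < j.  Every pair is relaxed over every
    third sequence; h_xy follows the linear amplification rule.
    """
    n = max(max(k) for k in mats) + 1

    def get(i, j):
        if i < j:
            return mats[(i, j)]
        return mats[(j, i)].T

    out = {}
    for (i, j), S in mats.items():
        n_xy = n - 2
        h_xy = 1.0 + (h - 1.0) * min(n_xy, cap) / cap
        num = h_xy * (weights[i] + weights[j]) * S
        denom = h_xy * (weights[i] + weights[j])
        for z in range(n):
            if z in (i, j):
                continue
            num = num + weights[z] * (get(i, z) @ get(z, j))
            denom += weights[z]
        out[(i, j)] = num / denom
    return out


def brute_upgma(D: np.ndarray):
    """Independent WPGMA: returns (frozenset topology, heights dict).

    Clusters are frozensets of leaf indices; at each step the closest pair
    (first-in-order on ties) merges at height d/2 and its distance to any
    other cluster becomes the plain mean of the two parents' distances.
    """
    n = D.shape[0]
    clusters: List[frozenset] = [frozenset([i]) for i in range(n)]
    dist: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    heights: Dict[frozenset, float] = {c: 0.0 for c in clusters}
    merges: List[Tuple[frozenset, frozenset, frozenset]] = []
    idx = list(range(n))
    table = {i: clusters[i] for i in idx}
    nxt = n
    while len(idx) > 1:
        best = None
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                key = (min(idx[a], idx[b]), max(idx[a], idx[b]))
                d = dist[key]
                if best is None or d < best[0] - 1e-15:
                    best = (d, idx[a], idx[b])
        d, i, j = best
        merged = table[i] | table[j]
        heights[merged] = d / 2.0
        merges.append((table[i], table[j], merged))
        for k in idx:
            if k in (i, j):
                continue
            di = dist[(min(i, k), max(i, k))]
            dj = dist[(min(j, k), max(j, k))]
            dist[(min(nxt, k), max(nxt, k))] = 0.5 * (di + dj)
        table[nxt] = merged
        idx = [k for k in idx if k not in (i, j)] + [nxt]
        nxt += 1
    topology = frozenset(frozenset((a, b)) for a, b, _ in merges)
    return topology, heights


def minimal_subtree_size(parent_of: Dict[int, int], sizes: Dict[int, int],
                         x: int, y: int) -> int:
    """Brute-force minimal-subtree node count: walk every ancestor of x,
    take the first that is also an ancestor of y, return its node count."""
    anc = []
    node = x
    while node is not None:
        anc.append(node)
        node = parent_of.get(node)
    node = y
    y_anc = set()
    while node is not None:
        y_anc.add(node)
        node = parent_of.get(node)
    for a in anc:
        if a in y_anc:
            return sizes[a]
    raise ValueError("disconnected tree")
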