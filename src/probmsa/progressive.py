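"""Stage IV(a): progressive profile-profile alignment in guide-tree order.

Profiles are aligned by a dynamic program over column pairs whose score is
the weight-normalized sum of transformed posterior probabilities across all
cross-sequence pairs; gap columns carry no reward or penalty — the
posterior mass is the only signal, as in the MEA family of aligners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence as Seq, Tuple

import numpy as np

from .guidetree import GuideTree
from .posterior import PosteriorStore, mea_path
from .seqio import GAP, Alignment, SequenceSet


@dataclass(frozen=True)
class Profile:
    """An alignment block whose rows carry sequence indices and weights."""

    rows: tuple            # of (seq_index, gapped string)
    weights: tuple         # per-row weight, aligned with rows

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty profile")
        width = len(self.rows[0][1])
        if any(len(r) != width for _, r in self.rows):
            raise ValueError("ragged profile rows")
        if any(w <= 0 for w in self.weights):
            raise ValueError("profile weights must be positive")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def indices(self) -> tuple:
        return tuple(i for i, _ in self.rows)

    def column_residue_index(self, row: int) -> np.ndarray:
        """Per column: residue index within the ungapped sequence, or -1."""
        out = np.full(self.n_columns, -1, dtype=np.int64)
        k = 0
        for c, sym in enumerate(self.rows[row][1]):
            if sym != GAP:
                out[c] = k
                k += 1
        return out


def _merge(P: Profile, Q: Profile, ops: List[str]) -> Profile:
    new_rows = []
    for rows, take in ((P.rows, {"M", "X"}), (Q.rows, {"M", "Y"})):
        for idx, text in rows:
            buf = []
            k = 0
            for op in ops:
                if op in take:
                    buf.append(text[k])
                    k += 1
                else:
                    buf.append(GAP)
            new_rows.append((idx, "".join(buf)))
    return Profile(tuple(new_rows), tuple(P.weights) + tuple(Q.weights))


def profile_score_matrix(P: Profile, Q: Profile, store: PosteriorStore,
                         normalize: bool = True) -> np.ndarray:
    """Column-pair score: sum over cross pairs of w_x w_y S_xy[i_x, j_y]."""
    if set(P.indices) & set(Q.indices):
        raise ValueError("profiles share sequences")
    M = np.zeros((P.n_columns, Q.n_columns))
    ixs = [P.column_residue_index(a) for a in range(len(P.rows))]
    iys = [Q.column_residue_index(b) for b in range(len(Q.rows))]
    total_w = 0.0
    for a, (x, _) in enumerate(P.rows):
        ix = ixs[a]
        vx = ix >= 0
        for b, (y, _) in enumerate(Q.rows):
            iy = iys[b]
            vy = iy >= 0
            S = store.get_dense(x, y)
            w = P.weights[a] * Q.weights[b]
            total_w += w
            M[np.ix_(vx, vy)] += w * S[np.ix_(ix[vx], iy[vy])]
    if normalize and total_w > 0:
        M /= total_w
    return M


def profile_align(P: Profile, Q: Profile, store: PosteriorStore,
                  normalize: bool = True) -> Tuple[Profile, float]:
    """Merge two profiles along the optimal monotone column matching."""
    M = profile_score_matrix(P, Q, store, normalize)
    ops, score = mea_path(M)
    return _merge(P, Q, ops), score


def progressive_align(tree: GuideTree, store: PosteriorStore,
                      seqs: SequenceSet, normalize: bool = True) -> Alignment:
    """Post-order traversal of the guide tree, merging children profiles."""
    weights = tree.sequence_weights()
    index_of = {sid: i for i, sid in enumerate(seqs.ids)}
    profiles: Dict[int, Profile] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            i = index_of[node.id]
            profiles[id(node)] = Profile(((i, seqs[i].residues),),
                                         (weights[node.id],))
        else:
            left, right = (profiles.pop(id(c)) for c in node.children)
            profiles[id(node)], _ = profile_align(left, right, store, normalize)
    final = profiles[id(tree.root)]
    return profile_to_alignment(final, seqs)


def profile_to_alignment(profile: Profile, seqs: SequenceSet) -> Alignment:
    """Rows ordered by input order; validates alignment invariants."""
    by_index = dict(profile.rows)
    rows = [(seqs[i].id, by_index[i]) for i in sorted(by_index)]
    return Alignment(rows)


def alignment_to_profile(aln: Alignment, seqs: SequenceSet,
                         weights: Dict[str, float]) -> Profile:
    index_of = {sid: i for i, sid in enumerate(seqs.ids)}
    rows = tuple((index_of[sid], text) for sid, text in aln.rows)
    w = tuple(weights[sid] for sid, _ in aln.rows)
    return Profile(rows, w)
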