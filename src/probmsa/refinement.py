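"""Stage IV(b): iterative refinement of a multiple alignment.

The column-oriented strategy picks a random gapped column, splits the
alignment into the rows gapped/ungapped at that column, strips gap-only
columns from both halves (the gapped half always shortens) and realigns
the two profiles; random and tree-guided splits are available for
comparison.  A candidate replaces the incumbent according to the
acceptance rule: always, non-increasing alignment length (the default
supervision), or non-decreasing trident column-entropy score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence as Seq, Tuple

import numpy as np

from .guidetree import GuideTree
from .posterior import PosteriorStore
from .progressive import Profile, alignment_to_profile, profile_align, \
    profile_to_alignment
from .seqio import GAP, Alignment, SequenceSet

# Stereochemical partition used by the trident diversity term: aliphatic,
# aromatic, polar, positive, negative, plus cysteine, glycine and proline
# as their own classes.  Configurable through trident_score(classes=...).
STEREOCHEMICAL_CLASSES: Dict[str, int] = {}
for _cls, _letters in enumerate(["AVLIM", "FWY", "STNQ", "KRH", "DE",
                                 "C", "G", "P"]):
    for _a in _letters:
        STEREOCHEMICAL_CLASSES[_a] = _cls
STEREOCHEMICAL_CLASSES["X"] = 0
STEREOCHEMICAL_CLASSES["B"] = 2
STEREOCHEMICAL_CLASSES["Z"] = 2
_N_CLASSES = 8


@dataclass(frozen=True)
class RefinementConfig:
    strategy: str = "column"          # column | random | tree
    iterations: object = "auto"       # int, or 'auto' (30/200 rule)
    acceptance: str = "length"        # always | length | trident
    balance_bias: Optional[Tuple[str, float]] = None  # ('balanced'|'imbalanced', %)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("column", "random", "tree"):
            raise ValueError(f"unknown refinement strategy {self.strategy!r}")
        if self.acceptance not in ("always", "length", "trident"):
            raise ValueError(f"unknown acceptance rule {self.acceptance!r}")
        if self.iterations != "auto" and int(self.iterations) < 0:
            raise ValueError("iterations must be non-negative")
        if self.balance_bias is not None:
            kind, pct = self.balance_bias
            if kind not in ("balanced", "imbalanced") or not (0 < pct <= 100):
                raise ValueError("balance bias must be (kind, percentage in (0,100])")

    def resolved_iterations(self, consistency_iterations: int) -> int:
        """30 iterations when two consistency transformations ran, else 200."""
        if self.iterations != "auto":
            return int(self.iterations)
        return 30 if consistency_iterations == 2 else 200


def candidate_columns(aln: Alignment) -> List[int]:
    """Columns containing at least one gap and at least one residue."""
    out = []
    for c in range(aln.n_columns):
        col = aln.column(c)
        gaps = col.count(GAP)
        if 0 < gaps < len(col):
            out.append(c)
    return out


def select_column(candidates: Seq[int], aln: Alignment,
                  bias: Optional[Tuple[str, float]],
                  rng: np.random.Generator) -> int:
    """Uniform choice; with bias, restrict to the first/last p% of the
    candidates sorted by |g - N/2| ascending (most balanced first)."""
    if not candidates:
        raise ValueError("no candidate columns")
    pool = list(candidates)
    if bias is not None:
        kind, pct = bias
        n_rows = aln.n_rows
        key = sorted(pool, key=lambda c: (abs(aln.column(c).count(GAP)
                                              - n_rows / 2.0), c))
        keep = max(1, math.ceil(len(key) * pct / 100.0))
        pool = key[:keep] if kind == "balanced" else key[-keep:]
    return int(pool[rng.integers(len(pool))])


def split_by_column(aln: Alignment, col: int, seqs: SequenceSet,
                    weights: Dict[str, float]) -> Tuple[Profile, Profile]:
    """Rows gapped at ``col`` form the first profile, the rest the second."""
    gap_rows = [r for r in aln.rows if r[1][col] == GAP]
    res_rows = [r for r in aln.rows if r[1][col] != GAP]
    if not gap_rows or not res_rows:
        raise ValueError(f"column {col} does not split the alignment")
    return (alignment_rows_to_profile(gap_rows, seqs, weights),
            alignment_rows_to_profile(res_rows, seqs, weights))


def alignment_rows_to_profile(rows, seqs: SequenceSet,
                              weights: Dict[str, float]) -> Profile:
    index_of = {sid: i for i, sid in enumerate(seqs.ids)}
    return Profile(tuple((index_of[sid], text) for sid, text in rows),
                   tuple(weights[sid] for sid, _ in rows))


def strip_gap_columns(profile: Profile) -> Profile:
    """Remove columns made entirely of gaps."""
    texts = [t for _, t in profile.rows]
    keep = [c for c in range(profile.n_columns)
            if any(t[c] != GAP for t in texts)]
    rows = tuple((idx, "".join(t[c] for c in keep))
                 for idx, t in profile.rows)
    return Profile(rows, profile.weights)


def split_random(aln: Alignment, seqs: SequenceSet,
                 weights: Dict[str, float],
                 rng: np.random.Generator) -> Tuple[Profile, Profile]:
    """Fair-coin row assignment, redrawn until both halves are non-empty."""
    n = aln.n_rows
    while True:
        mask = rng.integers(0, 2, size=n).astype(bool)
        if mask.any() and not mask.all():
            break
    first = [r for r, m in zip(aln.rows, mask) if m]
    second = [r for r, m in zip(aln.rows, mask) if not m]
    return (alignment_rows_to_profile(first, seqs, weights),
            alignment_rows_to_profile(second, seqs, weights))


def split_tree(aln: Alignment, tree: GuideTree, seqs: SequenceSet,
               weights: Dict[str, float],
               rng: np.random.Generator) -> Tuple[Profile, Profile]:
    """Break a uniformly random edge of the guide tree; the leaves below it
    form one profile, the remaining leaves the other."""
    edges = tree.internal_edges()
    node = edges[rng.integers(len(edges))]
    below = set(node.leaf_ids())
    first = [r for r in aln.rows if r[0] in below]
    second = [r for r in aln.rows if r[0] not in below]
    return (alignment_rows_to_profile(first, seqs, weights),
            alignment_rows_to_profile(second, seqs, weights))


def _entropy(counts: Dict[object, int]) -> float:
    total = sum(counts.values())
    h = 0.0
    for c in counts.values():
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


def trident_score(aln: Alignment, a: float = 1.0, b: float = 1.0,
                  c: float = 1.0,
                  classes: Optional[Dict[str, int]] = None) -> float:
    """Mean over columns of (1-t)^a (1-r)^b (1-g)^c.

    t is the symbol-diversity entropy of the column's residues, normalized
    by log 20; r the entropy over stereochemical classes, normalized by
    log of the class count; g the gap fraction.  A fully conserved gapless
    column scores 1; maximal diversity drives the score to 0.
    """
    classes = classes if classes is not None else STEREOCHEMICAL_CLASSES
    n_classes = len(set(classes.values()))
    total = 0.0
    for col in range(aln.n_columns):
        column = aln.column(col)
        residues = [s for s in column if s != GAP]
        g = 1.0 - len(residues) / len(column)
        sym_counts: Dict[str, int] = {}
        cls_counts: Dict[int, int] = {}
        for s in residues:
            sym_counts[s] = sym_counts.get(s, 0) + 1
            k = classes[s]
            cls_counts[k] = cls_counts.get(k, 0) + 1
        t = min(1.0, _entropy(sym_counts) / math.log(20))
        r = min(1.0, _entropy(cls_counts) / math.log(n_classes))
        total += (1.0 - t) ** a * (1.0 - r) ** b * (1.0 - g) ** c
    return total / aln.n_columns


def accept(candidate: Alignment, incumbent: Alignment, rule: str) -> bool:
    """Acceptance rules: always; non-increasing length; non-decreasing trident."""
    if set(candidate.ids) != set(incumbent.ids):
        raise ValueError("alignments cover different sequence sets")
    for sid in candidate.ids:
        if candidate.degapped(sid) != incumbent.degapped(sid):
            raise ValueError(f"row {sid!r} differs after degapping")
    if rule == "always":
        return True
    if rule == "length":
        return candidate.n_columns <= incumbent.n_columns
    if rule == "trident":
        return trident_score(candidate) >= trident_score(incumbent)
    raise ValueError(f"unknown acceptance rule {rule!r}")


def refine(aln: Alignment, store: PosteriorStore, seqs: SequenceSet,
           tree: GuideTree, config: RefinementConfig,
           iterations: Optional[int] = None,
           normalize: bool = True) -> Alignment:
    """Run the split / strip / realign / accept loop.

    ``iterations`` overrides the config (the pipeline passes the 30/200
    auto value).  Iterations without a usable split (e.g. a gapless
    alignment under the column strategy) are counted but do nothing.
    """
    rng = np.random.default_rng(config.seed)
    iters = (iterations if iterations is not None
             else config.resolved_iterations(0))
    weights = tree.sequence_weights()
    incumbent = aln
    for _ in range(iters):
        if config.strategy == "column":
            cands = candidate_columns(incumbent)
            if not cands:
                continue
            col = select_column(cands, incumbent, config.balance_bias, rng)
            p, q = split_by_column(incumbent, col, seqs, weights)
        elif config.strategy == "random":
            if incumbent.n_rows < 2:
                continue
            p, q = split_random(incumbent, seqs, weights, rng)
        else:
            p, q = split_tree(incumbent, tree, seqs, weights, rng)
        p = strip_gap_columns(p)
        q = strip_gap_columns(q)
        merged, _ = profile_align(p, q, store, normalize)
        candidate = profile_to_alignment(merged, seqs)
        if accept(candidate, incumbent, config.acceptance):
            incumbent = candidate.reorder(incumbent.ids)
    return incumbent
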