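"""Supervised alignment quality scores against a reference alignment.

SP (sum-of-pairs) is the fraction of residue pairs co-aligned in the
reference that the test alignment also places in one column; TC (total
column) is the fraction of reference columns (with at least two residues)
whose full residue content is reproduced inside a single test column.
Q = sqrt(SP * TC) is the single-number summary; relative length compares
column counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

from .seqio import GAP, Alignment


@dataclass(frozen=True)
class ScoreReport:
    sp: float
    tc: float
    q: float
    relative_length: float

    def tsv(self) -> str:
        return (f"{self.sp:.6f}\t{self.tc:.6f}\t{self.q:.6f}"
                f"\t{self.relative_length:.6f}")


def _check_comparable(test: Alignment, ref: Alignment) -> None:
    if set(test.ids) != set(ref.ids):
        raise ValueError("test and reference cover different sequences")
    for sid in ref.ids:
        if test.degapped(sid).upper() != ref.degapped(sid).upper():
            raise ValueError(f"sequence {sid!r} differs between test and reference")


def _column_map(aln: Alignment) -> Dict[str, list]:
    """Per row id: residue index -> column, as a list over residues."""
    out = {}
    for sid, text in aln.rows:
        cols = [c for c, s in enumerate(text) if s != GAP]
        out[sid] = cols
    return out


def sp_score(test: Alignment, ref: Alignment) -> float:
    """Fraction of reference residue pairs co-aligned by the test."""
    _check_comparable(test, ref)
    tmap = _column_map(test)
    ids = ref.ids
    rmaps = _column_map(ref)
    # invert: per ref column, the (row, residue-index) entries
    ref_cols: Dict[int, list] = {}
    for sid in ids:
        for ridx, col in enumerate(rmaps[sid]):
            ref_cols.setdefault(col, []).append((sid, ridx))
    total = 0
    correct = 0
    for entries in ref_cols.values():
        for a in range(len(entries)):
            for b in range(a + 1, len(entries)):
                (sx, ix), (sy, iy) = entries[a], entries[b]
                total += 1
                if tmap[sx][ix] == tmap[sy][iy]:
                    correct += 1
    if total == 0:
        raise ValueError("reference alignment has no residue pairs")
    return correct / total


def tc_score(test: Alignment, ref: Alignment) -> float:
    """Fraction of reference columns fully reproduced by a test column.

    Only reference columns with at least two residues are counted; a
    column is reproduced when all of its residues share one test column.
    """
    _check_comparable(test, ref)
    tmap = _column_map(test)
    rmaps = _column_map(ref)
    ref_cols: Dict[int, list] = {}
    for sid in ref.ids:
        for ridx, col in enumerate(rmaps[sid]):
            ref_cols.setdefault(col, []).append((sid, ridx))
    scored = 0
    recovered = 0
    for entries in ref_cols.values():
        if len(entries) < 2:
            continue
        scored += 1
        test_cols = {tmap[sid][ridx] for sid, ridx in entries}
        if len(test_cols) == 1:
            recovered += 1
    if scored == 0:
        raise ValueError("reference alignment has no multi-residue columns")
    return recovered / scored


def combined_q(sp: float, tc: float) -> float:
    """Geometric mean of SP and TC."""
    if not (0 <= sp <= 1 and 0 <= tc <= 1):
        raise ValueError("scores must lie in [0, 1]")
    return (sp * tc) ** 0.5


def relative_length(test: Alignment, ref: Alignment) -> float:
    """Test columns divided by reference columns."""
    return test.n_columns / ref.n_columns


def score_report(test: Alignment, ref: Alignment) -> ScoreReport:
    sp = sp_score(test, ref)
    tc = tc_score(test, ref)
    return ScoreReport(sp=sp, tc=tc, q=combined_q(sp, tc),
                       relative_length=relative_length(test, ref))
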