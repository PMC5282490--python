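"""Sequence and alignment containers plus FASTA input/output.

The package works on protein sequences over the 20-letter amino-acid
alphabet.  Ambiguity codes (B, Z, X) are kept verbatim in the residue
strings; every scoring routine treats them as the wildcard ``X`` and scores
them by the background-weighted expectation over the alphabet.  The gap
symbol is ``-``; ``.`` is accepted on input and normalised.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO, Union

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY = "BZX"
WILDCARD = "X"
ALPHABET = AMINO_ACIDS + AMBIGUITY
GAP = "-"
_ALPHABET_SET = frozenset(ALPHABET)

#: residue -> index into the 21-symbol scoring alphabet (20 aa + wildcard).
#: B and Z collapse onto the wildcard index for scoring purposes.
SYMBOL_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
SYMBOL_INDEX.update({"X": 20, "B": 20, "Z": 20})

PathLike = Union[str, Path, TextIO]


class SequenceError(ValueError):
    """Raised on malformed sequence or alignment input."""


@dataclass(frozen=True)
class Sequence:
    """A named, validated, ungapped amino-acid sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for pos, sym in enumerate(self.residues):
            if sym in (GAP, "."):
                raise SequenceError(
                    f"gap symbol {sym!r} at position {pos} of unaligned "
                    f"record {self.id!r}"
                )
            if sym not in _ALPHABET_SET:
                raise SequenceError(
                    f"symbol {sym!r} at position {pos} of record "
                    f"{self.id!r} is outside the amino-acid alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def indices(self):
        """Residues as scoring-alphabet indices (numpy int array)."""
        import numpy as np

        return np.array([SYMBOL_INDEX[c] for c in self.residues], dtype=np.int64)


@dataclass(frozen=True)
class SequenceSet:
    """Ordered collection of sequences with unique ids (the input family)."""

    members: tuple

    def __init__(self, members: Iterable[Sequence]):
        object.__setattr__(self, "members", tuple(members))
        seen = set()
        for s in self.members:
            if s.id in seen:
                raise SequenceError(f"duplicate sequence id {s.id!r}")
            seen.add(s.id)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.members)

    def __getitem__(self, i: int) -> Sequence:
        return self.members[i]

    @property
    def ids(self) -> tuple:
        return tuple(s.id for s in self.members)

    def by_id(self, sid: str) -> Sequence:
        for s in self.members:
            if s.id == sid:
                return s
        raise KeyError(sid)


def _canonical_row(row: str) -> str:
    return row.upper().replace(".", GAP).rstrip("*")


@dataclass(frozen=True)
class Alignment:
    """A gapped block of sequences: equal-length rows, no all-gap column."""

    rows: tuple  # of (id, gapped string)

    def __init__(self, rows: Iterable):
        rows = tuple((str(i), str(r)) for i, r in rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise SequenceError("alignment must have at least one row")
        width = len(rows[0][1])
        seen = set()
        for sid, r in rows:
            if len(r) != width:
                raise SequenceError(f"ragged alignment row {sid!r}")
            if sid in seen:
                raise SequenceError(f"duplicate row id {sid!r}")
            seen.add(sid)
            for pos, sym in enumerate(r):
                if sym != GAP and sym not in _ALPHABET_SET:
                    raise SequenceError(
                        f"symbol {sym!r} at column {pos} of row {sid!r} "
                        "is outside the alphabet"
                    )
        for col in range(width):
            if all(r[col] == GAP for _, r in rows):
                raise SequenceError(f"column {col} consists entirely of gaps")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple:
        return tuple(i for i, _ in self.rows)

    def row(self, sid: str) -> str:
        for i, r in self.rows:
            if i == sid:
                return r
        raise KeyError(sid)

    def degapped(self, sid: str) -> str:
        return self.row(sid).replace(GAP, "")

    def to_sequences(self) -> SequenceSet:
        return SequenceSet(Sequence(i, r.replace(GAP, "")) for i, r in self.rows)

    def column(self, col: int) -> str:
        return "".join(r[col] for _, r in self.rows)

    def reorder(self, ids: Iterable[str]) -> "Alignment":
        return Alignment((i, self.row(i)) for i in ids)


def _open_maybe(path_or_stream: PathLike, mode: str):
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream, False
    return open(path_or_stream, mode), True


def read_fasta(path_or_stream: PathLike, aligned: bool = False):
    """Read FASTA records.

    With ``aligned=False`` (default) returns a :class:`SequenceSet`; any gap
    symbol is an error.  With ``aligned=True`` returns an :class:`Alignment`
    with gaps retained ('.' normalised to '-').
    """
    handle, close = _open_maybe(path_or_stream, "r")
    try:
        records = [(rec.id, _canonical_row(str(rec.seq)))
                   for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if close:
            handle.close()
    if not records:
        raise SequenceError("no FASTA records found")
    if aligned:
        return Alignment(records)
    return SequenceSet(Sequence(i, r) for i, r in records)


def read_alignment(path_or_stream: PathLike) -> Alignment:
    return read_fasta(path_or_stream, aligned=True)


_LINE_WIDTH = 60


def _write_records(records, path_or_stream: PathLike) -> None:
    handle, close = _open_maybe(path_or_stream, "w")
    try:
        for sid, seq in records:
            handle.write(f">{sid}\n")
            for start in range(0, len(seq), _LINE_WIDTH):
                handle.write(seq[start:start + _LINE_WIDTH] + "\n")
    finally:
        if close:
            handle.close()


def write_alignment(alignment: Alignment, path_or_stream: PathLike) -> None:
    """Write an alignment as aligned FASTA (60-column wrap, row order kept)."""
    if not isinstance(alignment, Alignment):
        raise SequenceError("write_alignment requires an Alignment")
    _write_records(alignment.rows, path_or_stream)


def write_fasta(seqs: SequenceSet, path_or_stream: PathLike) -> None:
    _write_records(((s.id, s.residues) for s in seqs), path_or_stream)


def alignment_to_string(alignment: Alignment) -> str:
    buf = io.StringIO()
    write_alignment(alignment, buf)
    return buf.getvalue()
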