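"""Substitution matrices and amino-acid background frequencies.

Named matrices are taken from Biopython's collection; user-supplied
matrices are read from a plain-text format with residue-labelled rows and
columns (whitespace separated, as distributed with most alignment tools).
Every matrix is expanded to a 21st wildcard row/column holding the
background-weighted expected score, used for ambiguity codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import AMINO_ACIDS

# Robinson & Robinson amino-acid background frequencies.
BACKGROUND = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

#: background as a length-21 vector over the scoring alphabet
#: (wildcard gets weight 1 so expectations stay well-defined).
def background_vector() -> np.ndarray:
    v = np.array([BACKGROUND[a] for a in AMINO_ACIDS], dtype=float)
    v = v / v.sum()
    return np.concatenate([v, [1.0]])


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A 21x21 score matrix over the scoring alphabet (20 aa + wildcard)."""

    name: str
    scores: np.ndarray  # (21, 21) float

    def score(self, i: int, j: int) -> float:
        return float(self.scores[i, j])


def _expand_wildcard(core: np.ndarray) -> np.ndarray:
    bg = background_vector()[:20]
    full = np.zeros((21, 21))
    full[:20, :20] = core
    full[:20, 20] = core @ bg
    full[20, :20] = bg @ core
    full[20, 20] = bg @ core @ bg
    return full


def _from_biopython(name: str) -> np.ndarray:
    m = substitution_matrices.load(name)
    letters = m.alphabet
    core = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if a in letters and b in letters:
                core[i, j] = m[a, b]
            else:  # pragma: no cover - named protein matrices cover all 20
                raise ValueError(f"matrix {name} lacks residue {a}/{b}")
    return core


def parse_matrix_text(text: str) -> np.ndarray:
    """Parse a residue-labelled plain-text score matrix into 20x20 order."""
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    header = lines[0].split()
    col_idx = {}
    for k, label in enumerate(header):
        if label.upper() in AMINO_ACIDS:
            col_idx[label.upper()] = k
    core = np.full((20, 20), np.nan)
    for ln in lines[1:]:
        parts = ln.split()
        row_label = parts[0].upper()
        if row_label not in AMINO_ACIDS:
            continue
        i = AMINO_ACIDS.index(row_label)
        values = parts[1:]
        for label, k in col_idx.items():
            j = AMINO_ACIDS.index(label)
            core[i, j] = float(values[k])
    if np.isnan(core).any():
        missing = [AMINO_ACIDS[i] for i in range(20) if np.isnan(core[i]).any()]
        raise ValueError(f"matrix file missing residues: {missing}")
    return core


def load_substitution_matrix(name_or_path: str) -> SubstitutionMatrix:
    """Load a score matrix by Biopython name or from a plain-text file."""
    name = str(name_or_path)
    if Path(name).is_file():
        core = parse_matrix_text(Path(name).read_text())
        label = Path(name).stem
    else:
        core = _from_biopython(name.upper())
        label = name.upper()
    return SubstitutionMatrix(label, _expand_wildcard(core))
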