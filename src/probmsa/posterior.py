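"""Stage I: pairwise posterior probability matrices and MEA alignments.

For every pair of sequences two posterior matrices are computed — one by
forward/backward over a 3-state pair hidden Markov model, one from an
affine-gap partition function at finite temperature — and combined
cellwise.  Combined matrices are thresholded into sparse form (sparsity
coefficient beta) and drive both guide-tree distances (via MEA scores) and
the consistency and alignment stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .matrices import SubstitutionMatrix, background_vector, load_substitution_matrix
from .seqio import GAP, Alignment, Sequence, SequenceSet

_TOL = 1e-12


def _expand_probs(core: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Extend a 20x20 joint-probability table with expectation wildcards."""
    full = np.zeros((21, 21))
    full[:20, :20] = core
    full[:20, 20] = core @ bg
    full[20, :20] = bg @ core
    full[20, 20] = bg @ core @ bg
    return full


@dataclass(frozen=True)
class PairHmmParams:
    """3-state pair-HMM (match M, insert-in-x X, insert-in-y Y).

    No X<->Y transitions; the model has no end state, so a path's weight is
    the start probability times transition and emission products.  The
    default match emission is a Boltzmann transform of BLOSUM62 over
    Robinson-Robinson backgrounds; gap-open/extend probabilities follow the
    classic consistency-aligner magnitudes.
    """

    pi: np.ndarray          # (3,)
    trans: np.ndarray       # (3, 3)
    match_emit: np.ndarray  # (21, 21) joint probabilities (+wildcard rows)
    ins_emit: np.ndarray    # (21,)

    def __post_init__(self) -> None:
        if abs(self.pi.sum() - 1.0) > _TOL:
            raise ValueError("start distribution must sum to 1")
        for s in range(3):
            if abs(self.trans[s].sum() - 1.0) > _TOL:
                raise ValueError(f"transitions from state {s} must sum to 1")
        if np.any(self.pi < 0) or np.any(self.trans < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.match_emit[:20, :20].sum() - 1.0) > 1e-9:
            raise ValueError("match emission matrix must be normalized")
        if abs(self.ins_emit[:20].sum() - 1.0) > 1e-9:
            raise ValueError("insert emission vector must be normalized")

    @classmethod
    def default(cls, delta: float = 0.0119, epsilon: float = 0.33,
                matrix: str = "BLOSUM62", boltzmann_beta: float = 0.32,
                ) -> "PairHmmParams":
        bg = background_vector()[:20]
        scores = load_substitution_matrix(matrix).scores[:20, :20]
        joint = np.outer(bg, bg) * np.exp(boltzmann_beta * scores)
        joint = joint / joint.sum()
        joint = 0.5 * (joint + joint.T)  # keep model exactly symmetric
        pi = np.array([1.0 - 2 * delta, delta, delta])
        trans = np.array([
            [1.0 - 2 * delta, delta, delta],
            [1.0 - epsilon, epsilon, 0.0],
            [1.0 - epsilon, 0.0, epsilon],
        ])
        return cls(pi=pi, trans=trans,
                   match_emit=_expand_probs(joint, bg),
                   ins_emit=np.concatenate([bg, [bg @ bg]]))

    def log_arrays(self):
        with np.errstate(divide="ignore"):
            return (np.log(self.pi), np.log(self.trans),
                    np.log(self.match_emit), np.log(self.ins_emit))


@dataclass(frozen=True)
class PartitionParams:
    """Affine-gap partition function parameters.

    Gap run of length k costs ``gap_open + (k-1) * gap_ext``; alignment
    weight is exp(score / temperature).  Defaults use the GONNET1992 matrix
    with penalties on the same scale (open 2.2, extend 0.1, T 0.5).
    """

    matrix: SubstitutionMatrix = field(
        default_factory=lambda: load_substitution_matrix("GONNET1992"))
    gap_open: float = 2.2
    gap_ext: float = 0.1
    temperature: float = 0.5

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (math.isfinite(self.gap_open) and math.isfinite(self.gap_ext)):
            raise ValueError("gap penalties must be finite")


def hmm_posterior(x: Sequence, y: Sequence, params: PairHmmParams) -> np.ndarray:
    """Posterior match probabilities P(x_i ~ y_j) by forward-backward."""
    xi, yi = x.indices, y.indices
    lpi, lt, lme, lie = params.log_arrays()
    nx, ny = len(xi), len(yi)
    lm = np.full((nx + 1, ny + 1), -np.inf)
    lm[1:, 1:] = lme[np.ix_(xi, yi)]
    lx = np.concatenate([[-np.inf], lie[xi]])
    ly = np.concatenate([[-np.inf], lie[yi]])
    FM, FX, FY = _kernels.hmm_forward(lm, lx, ly, lpi, lt)
    BM, _, _ = _kernels.hmm_backward(lm, lx, ly, lt)
    logz = np.logaddexp(FM[nx, ny], np.logaddexp(FX[nx, ny], FY[nx, ny]))
    post = np.exp(FM[1:, 1:] + BM[1:, 1:] - logz)
    return np.clip(post, 0.0, 1.0)


def partition_posterior(x: Sequence, y: Sequence,
                        params: PartitionParams) -> np.ndarray:
    """Boltzmann pairing probabilities under the affine-gap ensemble."""
    xi, yi = x.indices, y.indices
    nx, ny = len(xi), len(yi)
    t = params.temperature
    s = params.matrix.scores[np.ix_(xi, yi)] / t
    sm = np.full((nx + 1, ny + 1), -np.inf)
    sm[1:, 1:] = s
    lgo = -params.gap_open / t
    lge = -params.gap_ext / t
    ZM, ZX, ZY = _kernels.partition_forward(sm, lgo, lge)
    smr = np.full((nx + 1, ny + 1), -np.inf)
    smr[1:, 1:] = s[::-1, ::-1]
    RM, RX, RY = _kernels.partition_forward(smr, lgo, lge)
    logz = np.logaddexp(ZM[nx, ny], np.logaddexp(ZX[nx, ny], ZY[nx, ny]))
    # RM[nx-i+1, ny-j+1] sums suffix alignments beginning with match (i,j);
    # the match weight is counted in both halves, subtract once.
    BM = RM[::-1, ::-1][:-1, :-1]
    post = np.exp(ZM[1:, 1:] + BM - s - logz)
    return np.clip(post, 0.0, 1.0)


def combine_posteriors(a: np.ndarray, b: np.ndarray,
                       how: str = "mean") -> np.ndarray:
    if a.shape != b.shape:
        raise ValueError("posterior matrices differ in shape")
    if how == "mean":
        return 0.5 * (a + b)
    if how == "rms":
        return np.sqrt(0.5 * (a * a + b * b))
    raise ValueError(f"unknown combination rule {how!r}")


class PosteriorMatrix:
    """Sparse pairwise posterior matrix S_xy with sparsity coefficient beta."""

    __slots__ = ("csr", "x_id", "y_id", "cutoff")

    def __init__(self, csr: sp.csr_matrix, x_id: str = "x", y_id: str = "y",
                 cutoff: float = 0.0):
        self.csr = csr.tocsr()
        self.x_id = x_id
        self.y_id = y_id
        self.cutoff = cutoff

    @property
    def shape(self) -> Tuple[int, int]:
        return self.csr.shape

    @property
    def n_cells(self) -> int:
        return int(self.csr.nnz)

    @property
    def beta(self) -> float:
        nx, ny = self.shape
        return self.n_cells / (nx * ny)

    def densify(self) -> np.ndarray:
        return self.csr.toarray()

    def transpose(self) -> "PosteriorMatrix":
        return PosteriorMatrix(self.csr.T.tocsr(), self.y_id, self.x_id,
                               self.cutoff)

    def validate(self) -> None:
        data = self.csr.data
        if data.size and (data.min() <= 0 or data.max() > 1 + 1e-9):
            raise ValueError("stored posteriors must lie in (0, 1]")
        if data.size and self.cutoff > 0 and data.min() < self.cutoff - 1e-15:
            raise ValueError("stored cell below sparsity cutoff")


def sparsify(dense: np.ndarray, cutoff: float, x_id: str = "x",
             y_id: str = "y") -> PosteriorMatrix:
    """Keep cells with p >= cutoff (and p > 0); record beta implicitly."""
    if not (0 <= cutoff < 1):
        raise ValueError("cutoff must lie in [0, 1)")
    kept = np.where(dense >= max(cutoff, 0.0), dense, 0.0)
    csr = sp.csr_matrix(kept)
    csr.eliminate_zeros()
    return PosteriorMatrix(csr, x_id, y_id, cutoff)


def resparsify(csr: sp.csr_matrix, cutoff: float) -> sp.csr_matrix:
    if cutoff <= 0:
        out = csr.tocsr()
        out.eliminate_zeros()
        return out
    out = csr.tocsr().copy()
    out.data[out.data < cutoff] = 0.0
    out.eliminate_zeros()
    return out


def _mea_traceback(M: np.ndarray, D: np.ndarray):
    """Recover one optimal monotone path; ties prefer match, then a gap in
    the first profile (advance j), then a gap in the second (advance i)."""
    i, j = M.shape
    ops = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(D[i, j] - (D[i - 1, j - 1] + M[i - 1, j - 1])) <= 1e-13:
            ops.append("M")
            i -= 1
            j -= 1
        elif j > 0 and abs(D[i, j] - D[i, j - 1]) <= 1e-13:
            ops.append("Y")
            j -= 1
        else:
            ops.append("X")
            i -= 1
    ops.reverse()
    return ops


def mea_path(M: np.ndarray):
    """Optimal match-sum path over a dense score matrix: (ops, score)."""
    D = _kernels.mea_fill(np.ascontiguousarray(M, dtype=np.float64))
    return _mea_traceback(M, D), float(D[M.shape[0], M.shape[1]])


def mea_align(S, x: Sequence, y: Sequence) -> Tuple[Alignment, float]:
    """Maximum-expected-accuracy pairwise alignment over posterior S."""
    dense = S.densify() if isinstance(S, PosteriorMatrix) else np.asarray(S)
    if dense.shape != (len(x), len(y)):
        raise ValueError("posterior matrix shape does not match sequences")
    ops, score = mea_path(dense)
    rx, ry = [], []
    i = j = 0
    for op in ops:
        if op == "M":
            rx.append(x.residues[i]); ry.append(y.residues[j])
            i += 1; j += 1
        elif op == "X":
            rx.append(x.residues[i]); ry.append(GAP)
            i += 1
        else:
            rx.append(GAP); ry.append(y.residues[j])
            j += 1
    aln = Alignment([(x.id, "".join(rx)), (y.id, "".join(ry))])
    return aln, score


class PosteriorStore:
    """All-pairs sparse posterior matrices, keyed by sequence index pair.

    Matrices are stored once per unordered pair in canonical (i < j)
    orientation; the reversed orientation is served as a transpose.
    """

    def __init__(self, n: int, cutoff: float):
        self.n = n
        self.cutoff = cutoff
        self._mats: Dict[Tuple[int, int], sp.csr_matrix] = {}

    def set(self, i: int, j: int, csr: sp.csr_matrix) -> None:
        if i == j:
            raise KeyError("no self-pair matrices")
        if i < j:
            self._mats[(i, j)] = csr.tocsr()
        else:
            self._mats[(j, i)] = csr.T.tocsr()

    def get(self, i: int, j: int) -> sp.csr_matrix:
        if i < j:
            return self._mats[(i, j)]
        return self._mats[(j, i)].T.tocsr()

    def get_dense(self, i: int, j: int) -> np.ndarray:
        if i < j:
            return self._mats[(i, j)].toarray()
        return self._mats[(j, i)].toarray().T

    def pairs(self):
        return self._mats.keys()

    def mean_beta(self, lengths) -> float:
        betas = [m.nnz / (lengths[i] * lengths[j])
                 for (i, j), m in self._mats.items()]
        return float(np.mean(betas)) if betas else 0.0

    def copy_empty(self) -> "PosteriorStore":
        return PosteriorStore(self.n, self.cutoff)


def compute_posteriors(seqs: SequenceSet,
                       hmm_params: Optional[PairHmmParams] = None,
                       part_params: Optional[PartitionParams] = None,
                       cutoff: float = 0.01,
                       combine: str = "mean",
                       ) -> Tuple[PosteriorStore, np.ndarray]:
    """Stage I driver: combined sparse posteriors and MEA scores for all pairs.

    Returns the posterior store and the symmetric N x N MEA score matrix.
    """
    hmm_params = hmm_params or PairHmmParams.default()
    part_params = part_params or PartitionParams()
    n = len(seqs)
    scores = np.zeros((n, n))
    store = PosteriorStore(n, cutoff)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = seqs[i], seqs[j]
            h = hmm_posterior(x, y, hmm_params)
            p = partition_posterior(x, y, part_params)
            combined = combine_posteriors(h, p, combine)
            _, score = mea_path(combined)
            scores[i, j] = scores[j, i] = score
            store.set(i, j, sparsify(combined, cutoff, x.id, y.id).csr)
    return store, scores
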