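"""Numba dynamic-programming kernels (log-space forward/backward, MEA DP).

All recurrences are accumulated in log space with double precision, which
keeps per-cell error far below the 1e-10 contract on short oracles while
remaining overflow-safe for long sequences.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -np.inf


@njit(cache=True)
def _lse3(a, b, c):
    return np.logaddexp(a, np.logaddexp(b, c))


@njit(cache=True)
def hmm_forward(lm, lx, ly, lpi, lt):
    """Forward over the 3-state pair-HMM (M, X, Y).

    ``lm[i, j]`` is the log match emission for residues i of x and j of y
    (1-based); ``lx``/``ly`` are log insert emissions.  ``lt[s, s']`` is the
    log transition matrix, ``lpi`` the log start distribution.  There is no
    end state: a complete path covers both sequences.
    """
    nx = lm.shape[0] - 1
    ny = lm.shape[1] - 1
    FM = np.full((nx + 1, ny + 1), NEG)
    FX = np.full((nx + 1, ny + 1), NEG)
    FY = np.full((nx + 1, ny + 1), NEG)
    for i in range(nx + 1):
        for j in range(ny + 1):
            if i > 0 and j > 0:
                acc = _lse3(FM[i - 1, j - 1] + lt[0, 0],
                            FX[i - 1, j - 1] + lt[1, 0],
                            FY[i - 1, j - 1] + lt[2, 0])
                if i == 1 and j == 1:
                    acc = np.logaddexp(acc, lpi[0])
                FM[i, j] = lm[i, j] + acc
            if i > 0:
                acc = _lse3(FM[i - 1, j] + lt[0, 1],
                            FX[i - 1, j] + lt[1, 1],
                            FY[i - 1, j] + lt[2, 1])
                if i == 1 and j == 0:
                    acc = np.logaddexp(acc, lpi[1])
                FX[i, j] = lx[i] + acc
            if j > 0:
                acc = _lse3(FM[i, j - 1] + lt[0, 2],
                            FX[i, j - 1] + lt[1, 2],
                            FY[i, j - 1] + lt[2, 2])
                if i == 0 and j == 1:
                    acc = np.logaddexp(acc, lpi[2])
                FY[i, j] = ly[j] + acc
    return FM, FX, FY


@njit(cache=True)
def hmm_backward(lm, lx, ly, lt):
    """Backward companion of :func:`hmm_forward` (B[s, nx, ny] = 0)."""
    nx = lm.shape[0] - 1
    ny = lm.shape[1] - 1
    BM = np.full((nx + 1, ny + 1), NEG)
    BX = np.full((nx + 1, ny + 1), NEG)
    BY = np.full((nx + 1, ny + 1), NEG)
    BM[nx, ny] = 0.0
    BX[nx, ny] = 0.0
    BY[nx, ny] = 0.0
    for i in range(nx, -1, -1):
        for j in range(ny, -1, -1):
            if i == nx and j == ny:
                continue
            for s in range(3):
                acc = NEG
                if i < nx and j < ny:
                    acc = np.logaddexp(
                        acc, lt[s, 0] + lm[i + 1, j + 1] + BM[i + 1, j + 1])
                if i < nx:
                    acc = np.logaddexp(acc, lt[s, 1] + lx[i + 1] + BX[i + 1, j])
                if j < ny:
                    acc = np.logaddexp(acc, lt[s, 2] + ly[j + 1] + BY[i, j + 1])
                if s == 0:
                    BM[i, j] = acc
                elif s == 1:
                    BX[i, j] = acc
                else:
                    BY[i, j] = acc
    return BM, BX, BY


@njit(cache=True)
def partition_forward(sm, lgo, lge):
    """Affine-gap partition function over global alignments.

    ``sm[i, j]`` is the log Boltzmann match weight s(x_i, y_j)/T (1-based);
    ``lgo``/``lge`` are -open/T and -ext/T.  A gap run of length k weighs
    exp(-(open + (k-1) ext)/T).  Adjacent X/Y runs are distinct runs, each
    paying the opening weight.
    """
    nx = sm.shape[0] - 1
    ny = sm.shape[1] - 1
    ZM = np.full((nx + 1, ny + 1), NEG)
    ZX = np.full((nx + 1, ny + 1), NEG)
    ZY = np.full((nx + 1, ny + 1), NEG)
    for i in range(nx + 1):
        for j in range(ny + 1):
            if i > 0 and j > 0:
                acc = _lse3(ZM[i - 1, j - 1], ZX[i - 1, j - 1], ZY[i - 1, j - 1])
                if i == 1 and j == 1:
                    acc = np.logaddexp(acc, 0.0)
                ZM[i, j] = sm[i, j] + acc
            if i > 0:
                opened = np.logaddexp(ZM[i - 1, j], ZY[i - 1, j])
                if i == 1 and j == 0:
                    opened = np.logaddexp(opened, 0.0)
                ZX[i, j] = np.logaddexp(opened + lgo, ZX[i - 1, j] + lge)
            if j > 0:
                opened = np.logaddexp(ZM[i, j - 1], ZX[i, j - 1])
                if i == 0 and j == 1:
                    opened = np.logaddexp(opened, 0.0)
                ZY[i, j] = np.logaddexp(opened + lgo, ZY[i, j - 1] + lge)
    return ZM, ZX, ZY


@njit(cache=True)
def mea_fill(M):
    """Max-sum DP table for the match-sum MEA objective (gaps score 0)."""
    nx, ny = M.shape
    D = np.zeros((nx + 1, ny + 1))
    for i in range(1, nx + 1):
        for j in range(1, ny + 1):
            best = D[i - 1, j - 1] + M[i - 1, j - 1]
            if D[i - 1, j] > best:
                best = D[i - 1, j]
            if D[i, j - 1] > best:
                best = D[i, j - 1]
            D[i, j] = best
    return D
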