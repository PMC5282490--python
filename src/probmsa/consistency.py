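"""Stage III: selective consistency transformation of posterior matrices.

A transformation relaxes every matrix S_xy by adding weighted products
S_xz S_zy over third sequences z.  Selectivity restricts the z set either
deterministically (aggregated distance alpha(d_xz, d_yz) <= T on the
node-count tree distance) or stochastically (acceptance probability
F(alpha) on rank-normalized score distances).  Matrices that receive few
relaxations get their original signal amplified by a coefficient h_xy that
grows linearly from 1 (no relaxations) to h at the relaxation cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence as Seq, Tuple

import numpy as np

from .guidetree import GuideTree, rank_normalize, tree_distance_matrix
from .posterior import PosteriorStore, resparsify

AGGREGATIONS: Dict[str, Callable[[float, float], float]] = {
    "max": max,
    "min": min,
    "sum": lambda a, b: a + b,
}


def num_transformations(n: int) -> int:
    """Consistency iterations by family size: 2 below 50 sequences, else 1."""
    if n < 2:
        raise ValueError("need at least two sequences")
    return 2 if n < 50 else 1


def default_threshold(n: int) -> float:
    """Default deterministic threshold on the node-count tree distance."""
    return float(math.ceil(2.0 * math.sqrt(n)))


class TriangleFilter:
    """Triangle-shaped acceptance-probability filter on [0, 1] distances.

    ``shape`` selects which aggregated distances are promoted: ``low-pass``
    prefers closely related third sequences (peak at 0), ``high-pass``
    distantly related ones (peak at 1), ``mid-pass`` mildly related (peak
    at 0.5).  Each preset is calibrated so that the expected acceptance
    over uniformly distributed distances equals ``rate``.
    """

    def __init__(self, shape: str = "low-pass", rate: float = 0.10):
        if not (0 < rate <= 0.5):
            raise ValueError("rate must lie in (0, 0.5]")
        if shape not in ("low-pass", "mid-pass", "high-pass"):
            raise ValueError(f"unknown filter shape {shape!r}")
        self.shape = shape
        self.rate = rate

    def __call__(self, a: float) -> float:
        r = self.rate
        if self.shape == "low-pass":
            v = 1.0 - a / (2.0 * r)
        elif self.shape == "high-pass":
            v = 1.0 - (1.0 - a) / (2.0 * r)
        else:
            v = 1.0 - abs(a - 0.5) / r
        return max(0.0, min(1.0, v))

    def expected_acceptance(self) -> float:
        """Closed-form acceptance rate for uniform distances (= rate)."""
        return self.rate


@dataclass(frozen=True)
class ConsistencyConfig:
    """Tunables of the consistency stage.

    mode: 'full' (every z), 'deterministic-tree' (threshold T on tree
    distances) or 'stochastic-score' (filter F on rank-normalized score
    distances).  ``h`` defaults to 1 in full mode and 3 in selective modes;
    ``cap`` is the relaxation count at which h_xy reaches h (and a hard
    per-pair cap, closest-first by alpha).  ``iterations='auto'`` applies
    the family-size rule.  ``invert_filter`` switches the stochastic
    acceptance inequality to reject-with-probability-F semantics.
    """

    mode: str = "deterministic-tree"
    alpha: str = "max"
    T: Optional[float] = None
    filter_shape: str = "low-pass"
    filter_rate: float = 0.10
    h: Optional[float] = None
    cap: int = 200
    iterations: object = "auto"
    seed: int = 0
    invert_filter: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("full", "deterministic-tree", "stochastic-score"):
            raise ValueError(f"unknown consistency mode {self.mode!r}")
        if self.alpha not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.alpha!r}")
        if self.T is not None and self.T < 0:
            raise ValueError("threshold T must be non-negative")
        if self.h is not None and self.h < 1:
            raise ValueError("amplification ceiling h must be >= 1")
        if self.cap < 1:
            raise ValueError("relaxation cap must be >= 1")

    def resolved(self, n: int) -> "ConsistencyConfig":
        """Materialize 'auto' fields for a family of n sequences."""
        t = self.T if self.T is not None else default_threshold(n)
        h = self.h if self.h is not None else (1.0 if self.mode == "full" else 3.0)
        iters = (num_transformations(n) if self.iterations == "auto"
                 else int(self.iterations))
        if iters < 0:
            raise ValueError("iterations must be non-negative")
        return replace(self, T=t, h=h, iterations=iters)


def deterministic_accept(d_xz: float, d_yz: float, alpha: str, T: float) -> bool:
    """Accept relaxation over z iff alpha(d_xz, d_yz) <= T."""
    if d_xz < 0 or d_yz < 0:
        raise ValueError("distances must be non-negative")
    return AGGREGATIONS[alpha](d_xz, d_yz) <= T


def stochastic_accept(alpha0: float, F: Callable[[float], float],
                      rng: np.random.Generator,
                      invert: bool = False) -> bool:
    """Draw p ~ U[0,1]; accept iff p <= F(alpha0) (F is an acceptance
    probability; ``invert=True`` flips the inequality)."""
    f = F(alpha0)
    if not (0.0 <= f <= 1.0):
        raise ValueError("filter value outside [0, 1]")
    p = rng.random()
    return (f <= p) if invert else (p <= f)


@dataclass
class RelaxationPlan:
    """For each unordered pair (i, j) with i < j, the accepted z indices."""

    accepted: Dict[Tuple[int, int], List[int]]
    n: int

    def n_xy(self, i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        return len(self.accepted[key])

    def mean_accepted(self) -> float:
        if not self.accepted:
            return 0.0
        return float(np.mean([len(v) for v in self.accepted.values()]))


def build_plan(n: int, config: ConsistencyConfig,
               tree: Optional[GuideTree] = None,
               distances: Optional[np.ndarray] = None,
               rng: Optional[np.random.Generator] = None) -> RelaxationPlan:
    """Decide, for every pair, which third sequences relax it.

    ``tree`` supplies node-count distances for deterministic-tree mode;
    ``distances`` (rank-normalized) drives stochastic-score mode.  Accepted
    sets are capped at ``config.cap``, keeping the smallest-alpha third
    sequences.
    """
    cfg = config.resolved(n)
    agg = AGGREGATIONS[cfg.alpha]
    if cfg.mode == "deterministic-tree":
        if tree is None:
            raise ValueError("deterministic-tree mode requires a guide tree")
        D = tree_distance_matrix(tree)
    elif cfg.mode == "stochastic-score":
        if distances is None:
            raise ValueError("stochastic-score mode requires ranked distances")
        D = rank_normalize(distances)
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        F = TriangleFilter(cfg.filter_shape, cfg.filter_rate)
    else:
        D = None
    accepted: Dict[Tuple[int, int], List[int]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            chosen: List[Tuple[float, int]] = []
            for z in range(n):
                if z in (i, j):
                    continue
                if cfg.mode == "full":
                    chosen.append((0.0, z))
                    continue
                a0 = agg(D[i, z], D[j, z])
                if cfg.mode == "deterministic-tree":
                    if a0 <= cfg.T:
                        chosen.append((a0, z))
                else:
                    if stochastic_accept(a0, F, rng, cfg.invert_filter):
                        chosen.append((a0, z))
            chosen.sort(key=lambda t: (t[0], t[1]))  # closest-first, stable
            accepted[(i, j)] = [z for _, z in chosen[:cfg.cap]]
    return RelaxationPlan(accepted, n)


def amplification_coeff(n_xy: int, cap: int = 200, h: float = 3.0) -> float:
    """h_xy = 1 + (h - 1) * min(n_xy, cap) / cap."""
    if n_xy < 0 or h < 1 or cap < 1:
        raise ValueError("invalid amplification arguments")
    return 1.0 + (h - 1.0) * min(n_xy, cap) / cap


def relax_pair(S_xy, accepted, w_x: float, w_y: float, h_xy: float,
               cutoff: float = 0.0):
    """One relaxed matrix:
    S' = [h_xy (w_x + w_y) S_xy + sum_z w_z S_xz S_zy] / [h_xy (w_x + w_y) + sum w_z]

    ``accepted`` is a list of (w_z, S_xz, S_zy) sparse triples; the result
    is computed sparsely and re-thresholded at ``cutoff``.
    """
    if not accepted:
        # the formula reduces to S_xy exactly; avoid a multiply/divide round-trip
        return resparsify(S_xy, cutoff)
    self_w = h_xy * (w_x + w_y)
    num = S_xy.multiply(self_w).tocsr()
    total = self_w
    for w_z, S_xz, S_zy in accepted:
        if S_xz.shape[1] != S_zy.shape[0] or \
                S_xz.shape[0] != S_xy.shape[0] or S_zy.shape[1] != S_xy.shape[1]:
            raise ValueError("incompatible matrix dimensions in relaxation")
        num = num + (S_xz @ S_zy).multiply(w_z)
        total += w_z
    out = num.multiply(1.0 / total).tocsr()
    return resparsify(out, cutoff)


def consistency_transform(store: PosteriorStore, plan: RelaxationPlan,
                          weights: Seq[float],
                          config: ConsistencyConfig) -> PosteriorStore:
    """Apply ``config.iterations`` consistency transformations.

    Each pass is double-buffered: every relaxed matrix is computed from the
    pre-pass matrices, so the result does not depend on pair order.  The
    reverse orientation is the exact transpose by construction.
    """
    cfg = config.resolved(store.n)
    current = store
    for _ in range(int(cfg.iterations)):
        nxt = current.copy_empty()
        for (i, j) in sorted(current.pairs()):
            zs = plan.accepted[(i, j)]
            h_xy = amplification_coeff(len(zs), cfg.cap, cfg.h)
            triples = [(weights[z], current.get(i, z), current.get(z, j))
                       for z in zs]
            nxt.set(i, j, relax_pair(current.get(i, j), triples,
                                     weights[i], weights[j], h_xy,
                                     current.cutoff))
        current = nxt
    return current
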