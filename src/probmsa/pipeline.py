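"""End-to-end pipeline: posteriors -> guide tree -> consistency ->
progressive alignment -> iterative refinement, plus bulk mode and the
memory-capped sparsity adjustment.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence as Seq, Tuple

import numpy as np

from .consistency import ConsistencyConfig, build_plan, consistency_transform, \
    num_transformations
from .guidetree import GuideTree, distance_matrix_from_scores, upgma
from .posterior import PairHmmParams, PartitionParams, PosteriorStore, \
    compute_posteriors
from .progressive import progressive_align
from .refinement import RefinementConfig, refine
from .seqio import Alignment, SequenceSet, read_fasta, write_alignment

#: cutoff grid walked by the RAM fit, coarsest (most aggressive) last;
#: below the floor the posterior signal is too degraded to be useful.
CUTOFF_GRID = (0.01, 0.02, 0.05, 0.10, 0.20, 0.30, 0.50)
CUTOFF_FLOOR = 0.50
#: bytes per stored sparse cell (value + column index + row overhead share)
CELL_COST = 16


@dataclass(frozen=True)
class PipelineConfig:
    """Fully explicit configuration of all four stages."""

    cutoff: float = 0.01
    combine: str = "mean"
    hmm: Optional[PairHmmParams] = None
    partition: Optional[PartitionParams] = None
    tree_variant: str = "wpgma"
    consistency: ConsistencyConfig = field(default_factory=ConsistencyConfig)
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    normalize_profile_weights: bool = True
    memory_budget: Optional[int] = None
    seed: int = 0

    def resolved(self, n: int) -> "PipelineConfig":
        cons = self.consistency.resolved(n)
        if cons.seed == 0 and self.seed:
            cons = replace(cons, seed=self.seed)
        ref = self.refinement
        if ref.seed == 0 and self.seed:
            ref = replace(ref, seed=self.seed)
        return replace(self, consistency=cons, refinement=ref)

    def describe(self, n: int) -> List[str]:
        cfg = self.resolved(n)
        cons = cfg.consistency
        ref = cfg.refinement
        return [
            f"posterior.cutoff={cfg.cutoff} posterior.combine={cfg.combine}",
            f"tree.variant={cfg.tree_variant}",
            (f"consistency.mode={cons.mode} alpha={cons.alpha} T={cons.T} "
             f"h={cons.h} cap={cons.cap} iterations={cons.iterations} "
             f"seed={cons.seed}"),
            (f"refine.strategy={ref.strategy} acceptance={ref.acceptance} "
             f"iterations={ref.resolved_iterations(int(cons.iterations))} "
             f"seed={ref.seed}"),
            f"seed={cfg.seed} memory_budget={cfg.memory_budget}",
        ]


@dataclass
class PipelineResult:
    alignment: Alignment
    tree: GuideTree
    store: PosteriorStore
    unrefined: Alignment
    stats: Dict[str, object]


def fit_sparsity(memory_budget: int, n: int, lengths: Seq[int],
                 cutoff: float, grid: Seq[float] = CUTOFF_GRID,
                 cell_cost: int = CELL_COST) -> float:
    """Smallest grid cutoff >= current whose storage estimate fits.

    The estimate bounds each matrix's cell count by both its dense size and
    the per-row bound floor(1/cutoff) (each posterior row sums to at most
    one, so at most 1/cutoff cells can reach the cutoff).  Raising the
    cutoff beyond the floor would silently destroy the posterior signal,
    so an infeasible budget is an error instead.
    """
    if memory_budget <= 0:
        raise ValueError("memory budget must be positive")

    def estimate(c: float) -> int:
        total = 0
        for i in range(n):
            for j in range(i + 1, n):
                lx, ly = lengths[i], lengths[j]
                dense = lx * ly
                if c > 0:
                    per_row = int(1.0 / c)
                    bound = min(dense, lx * min(ly, per_row),
                                ly * min(lx, per_row))
                else:
                    bound = dense
                total += bound
        return total * cell_cost

    candidates = [c for c in sorted(grid) if c >= cutoff - 1e-12]
    if not candidates or cutoff > CUTOFF_FLOOR:
        candidates = [cutoff]
    for c in candidates:
        if estimate(c) <= memory_budget:
            return c
    raise MemoryError(
        f"budget of {memory_budget} bytes infeasible even at the floor "
        f"cutoff {CUTOFF_FLOOR}")


def run_pipeline(seqs: SequenceSet, config: Optional[PipelineConfig] = None,
                 ) -> PipelineResult:
    """Run stages I-IV with the family-size auto rules."""
    config = config or PipelineConfig()
    n = len(seqs)
    if n < 2:
        raise ValueError("alignment requires at least two sequences")
    cfg = config.resolved(n)
    stats: Dict[str, object] = {"n": n}
    lengths = [len(s) for s in seqs]

    cutoff = cfg.cutoff
    if cfg.memory_budget is not None:
        cutoff = fit_sparsity(cfg.memory_budget, n, lengths, cutoff)
        stats["cutoff"] = cutoff

    t0 = time.perf_counter()
    store, scores = compute_posteriors(seqs, cfg.hmm, cfg.partition,
                                       cutoff, cfg.combine)
    stats["stage1_s"] = time.perf_counter() - t0
    stats["mean_beta"] = store.mean_beta(lengths)

    t0 = time.perf_counter()
    D = distance_matrix_from_scores(scores, lengths)
    tree = upgma(D, seqs.ids, cfg.tree_variant)
    weights = tree.sequence_weights()
    wvec = [weights[sid] for sid in seqs.ids]
    stats["stage2_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cons = cfg.consistency
    plan = build_plan(n, cons, tree=tree, distances=D,
                      rng=np.random.default_rng(cons.seed))
    store = consistency_transform(store, plan, wvec, cons)
    stats["stage3_s"] = time.perf_counter() - t0
    stats["mean_relaxations"] = plan.mean_accepted()

    t0 = time.perf_counter()
    unrefined = progressive_align(tree, store, seqs,
                                  cfg.normalize_profile_weights)
    ref_iters = cfg.refinement.resolved_iterations(int(cons.iterations))
    final = refine(unrefined, store, seqs, tree, cfg.refinement,
                   iterations=ref_iters,
                   normalize=cfg.normalize_profile_weights)
    stats["stage4_s"] = time.perf_counter() - t0
    stats["refine_iterations"] = ref_iters
    stats["consistency_iterations"] = int(cons.iterations)
    stats["columns"] = final.n_columns

    return PipelineResult(alignment=final, tree=tree, store=store,
                          unrefined=unrefined, stats=stats)


def align_file(in_path, out_path, config: Optional[PipelineConfig] = None,
               ) -> PipelineResult:
    seqs = read_fasta(in_path)
    result = run_pipeline(seqs, config)
    write_alignment(result.alignment, out_path)
    return result


def bulk_run(paths: Seq, out_dir, config: Optional[PipelineConfig] = None,
             ) -> List[Dict[str, object]]:
    """Align many families with one shared config.

    Each family is independent; a failure is recorded as an error row and
    does not abort the batch.  Returns the summary rows (family, n, mean
    length, columns, elapsed seconds, status).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: List[Dict[str, object]] = []
    for path in paths:
        path = Path(path)
        row: Dict[str, object] = {"family": path.stem}
        t0 = time.perf_counter()
        try:
            seqs = read_fasta(path)
            result = run_pipeline(seqs, config)
            out_path = out_dir / f"{path.stem}.aligned.fasta"
            write_alignment(result.alignment, out_path)
            row.update(n=len(seqs),
                       mean_length=float(np.mean([len(s) for s in seqs])),
                       columns=result.alignment.n_columns,
                       elapsed_s=round(time.perf_counter() - t0, 3),
                       status="ok")
        except Exception as exc:  # noqa: BLE001 - batch isolation
            row.update(n=None, mean_length=None, columns=None,
                       elapsed_s=round(time.perf_counter() - t0, 3),
                       status=f"error: {exc}")
        rows.append(row)
    return rows
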