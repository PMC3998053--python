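"""Benchmark harness: repeated explorations over start/target pair sets.

Protocol: each pair is explored `reps` times (default 5) with an iteration
cap (default 1000).  A run that finds the path reports its iteration count; a
run that does not is recorded as the cap value (1000).  The headline per-pair
statistic is the mean iteration count over *successful* runs — or the cap when
no run succeeded; the mean over all runs with failures counted as the cap is
also reported as a stricter alternative.  The dataset summary is the median of
the per-pair statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import pandas as pd

from .chem import MoleculeRecord
from .explorer import ExplorationConfig, run

__all__ = ["PairResult", "BenchmarkReport", "pair_statistic", "run_benchmark"]


def pair_statistic(iteration_counts: Sequence[int], successes: Sequence[bool], cap: int) -> float:
    """Mean iterations over successful runs; the cap when none succeeded."""
    good = [n for n, ok in zip(iteration_counts, successes) if ok]
    if not good:
        return float(cap)
    return sum(good) / len(good)


@dataclass
class PairResult:
    pair_id: str
    iteration_counts: list[int]     # failures recorded as the cap
    successes: list[bool]
    statistic: float                # mean over successful runs, or cap
    statistic_all_runs: float       # mean over all runs, failures = cap

    @property
    def n_success(self) -> int:
        return sum(self.successes)


@dataclass
class BenchmarkReport:
    per_pair: list[PairResult]
    dataset_median: float           # median of per-pair headline statistics
    dataset_median_all_runs: float
    reps: int
    cap: int
    base_seed: int
    config: ExplorationConfig

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pair": p.pair_id,
                "runs": len(p.iteration_counts),
                "successes": p.n_success,
                "iterations": " ".join(str(n) for n in p.iteration_counts),
                "mean_success_iters": round(p.statistic, 2),
                "mean_all_runs": round(p.statistic_all_runs, 2),
            }
            for p in self.per_pair
        ]
        return pd.DataFrame(rows)


def run_benchmark(
    pairs: Sequence[tuple[MoleculeRecord, MoleculeRecord]],
    cfg: ExplorationConfig,
    reps: int = 5,
    cap: int = 1000,
    base_seed: int = 0,
) -> BenchmarkReport:
    """Run `reps` explorations per pair and aggregate the iteration counts.

    Run r of pair p uses seed ``base_seed + 1000*p + r``, so the report is
    reproducible and the runs are independent.
    """
    if not pairs:
        raise ValueError("pair set must not be empty")
    results: list[PairResult] = []
    for p, (start, target) in enumerate(pairs):
        pair_id = start.label or f"pair-{p + 1}"
        counts: list[int] = []
        successes: list[bool] = []
        for r in range(reps):
            seed = base_seed + 1000 * p + r
            outcome = run(
                start, target,
                ExplorationConfig(
                    fp_kind=cfg.fp_kind, coeff=cfg.coeff,
                    enabled_ops=cfg.enabled_ops, palette=cfg.palette,
                    filters=cfg.filters, decoys=cfg.decoys,
                    n_gen_per_parent=cfg.n_gen_per_parent,
                    accept_best=cfg.accept_best, accept_cap=cfg.accept_cap,
                    decay=cfg.decay, idle_threshold=cfg.idle_threshold,
                    max_iterations=cap, seed=seed,
                ),
            )
            successes.append(outcome.complete)
            counts.append(outcome.iterations_used if outcome.complete else cap)
        stat = pair_statistic(counts, successes, cap)
        results.append(
            PairResult(
                pair_id=pair_id,
                iteration_counts=counts,
                successes=successes,
                statistic=stat,
                statistic_all_runs=sum(counts) / len(counts),
            )
        )
    return BenchmarkReport(
        per_pair=results,
        dataset_median=float(median(p.statistic for p in results)),
        dataset_median_all_runs=float(median(p.statistic_all_runs for p in results)),
        reps=reps,
        cap=cap,
        base_seed=base_seed,
        config=cfg,
    )
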