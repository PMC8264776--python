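"""Shared fixtures.

The heavy session fixture runs the full synthetic benchmark once for a
sweep of seeds; classifier- and module-level tests reuse its artifacts
instead of re-running inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from grain import consensus as consensus_mod
from grain import inference, modules, simulate
from grain.types import ExpressionMatrix, LabelSet, RankedEdgeList

BENCH_SEEDS = list(range(1, 11))
BENCH_K = 1000
BENCH_QUANTILE = 0.8
BENCH_TREES = 100
ALL_METHODS = ("pcc", "scc", "clr", "aracne", "genie3")
CONSENSUS_METHODS = ("clr", "aracne", "genie3")


@dataclass
class BenchmarkRun:
    seed: int
    gt: simulate.GroundTruth
    expr: ExpressionMatrix
    labels: LabelSet
    full_lists: dict[str, RankedEdgeList]
    consensus: RankedEdgeList
    partition: modules.ModulePartition
    grain: pd.DataFrame

    @property
    def universe(self) -> set[tuple[str, str]]:
        return {
            (tf, g) for tf in self.gt.tf_ids for g in self.gt.gene_ids if g != tf
        }


def _run_benchmark(seed: int) -> BenchmarkRun:
    gt = simulate.simulate_grn(seed=seed)
    expr = simulate.simulate_expression(gt, seed=seed + 1000)
    tfs = gt.regulator_set()
    full_k = len(gt.tf_ids) * (len(gt.gene_ids) - 1)
    full_lists = {
        m: inference.infer(m, expr, tfs, top_k=full_k, n_trees=BENCH_TREES,
                           seed=seed)
        for m in ALL_METHODS
    }
    trio = [
        inference.top_k_filter(
            full_lists[m].edges[["regulator", "target", "score"]], BENCH_K, m
        )
        for m in CONSENSUS_METHODS
    ]
    cons = consensus_mod.consensus_network(trio, BENCH_K)
    reg_sets = modules.regulator_sets(cons)
    graph = modules.coregulation_graph(reg_sets, BENCH_QUANTILE)
    partition = modules.mcl_cluster(graph, 2.0)
    grain_matrix = modules.build_grain_matrix(cons, partition)
    return BenchmarkRun(
        seed=seed, gt=gt, expr=expr, labels=simulate.export_labels(gt),
        full_lists=full_lists, consensus=cons, partition=partition,
        grain=grain_matrix,
    )


@pytest.fixture(scope="session")
def benchmark_runs() -> dict[int, BenchmarkRun]:
    """Full benchmark artifacts for the ten sweep seeds."""
    return {seed: _run_benchmark(seed) for seed in BENCH_SEEDS}


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    import numpy as np

    rng = np.random.default_rng(5)
    values = pd.DataFrame(
        rng.normal(size=(5, 6)),
        index=[f"g{i}" for i in range(1, 6)],
        columns=[f"s{j}" for j in range(1, 7)],
    )
    cond = pd.Series(["control"] * 3 + ["stress"] * 3, index=values.columns)
    return ExpressionMatrix(values=values, condition=cond)
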