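"""End-to-end benchmark: simulate, detect with all methods, score, compare.

One master seed drives everything.  Per-dataset seeds are derived through a
counter-based :class:`numpy.random.SeedSequence` spawn, and each detector
further derives its own permutation stream from (dataset seed, method
index), so adding a method or dataset never perturbs the others' draws.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .concordance import MethodCallSets, common_degs, excess_crosstab, overall_score, venn_partition
from .datatypes import ConfigurationError, DetectionResult, GroundTruth, MetricSet
from .detectors import METHODS, MethodParams, detect
from .evaluation import evaluate_method, summary_frame
from .simulate import SimulationConfig, generate, preset

log = logging.getLogger(__name__)


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed below 2^31 from a master seed and counters."""
    ss = np.random.SeedSequence(entropy=int(master_seed) % 2**31,
                                spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class BenchmarkConfig:
    datasets: dict[str, SimulationConfig] = field(default_factory=dict)
    methods: tuple[str, ...] = METHODS
    replicates: int = 1
    seed: int = 0
    outdir: Path | None = None
    method_overrides: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.datasets:
            self.datasets = {"dataset1": preset("dataset1"),
                             "dataset2": preset("dataset2")}
        if not self.datasets or not self.methods:
            raise ConfigurationError("need at least one dataset and one method")
        if self.replicates < 1:
            raise ConfigurationError("replicate count must be >= 1")

    def method_params(self, method: str, seed: int) -> MethodParams:
        return MethodParams(method=method, seed=seed,
                            **self.method_overrides.get(method, {}))


def run_dataset(name: str, sim: SimulationConfig, config: BenchmarkConfig,
                replicate: int = 0):
    """Simulate one dataset and run every configured detector on it.

    Returns (expr, truth, results, evaluations) where ``results`` and
    ``evaluations`` are keyed by method name.
    """
    ds_index = list(config.datasets).index(name)
    sim_seed = derive_seed(config.seed, ds_index, replicate)
    expr, truth = generate(replace(sim, seed=sim_seed))
    results: dict[str, DetectionResult] = {}
    evaluations = {}
    for method in config.methods:
        t0 = time.perf_counter()
        params = config.method_params(method, seed=sim_seed)
        results[method] = detect(expr, params)
        evaluations[method] = evaluate_method(results[method], truth)
        log.info("stage=detect dataset=%s replicate=%d method=%s seed=%d "
                 "elapsed=%.2fs", name, replicate, method, sim_seed,
                 time.perf_counter() - t0)
    return expr, truth, results, evaluations


def run_benchmark(config: BenchmarkConfig) -> Path:
    """Full benchmark into ``config.outdir``; returns the report directory.

    Writes, per dataset: the expression/groups/truth TSVs, one result TSV
    per method, the concordance outputs, and a combined ``summary.tsv``
    (metric rows x method columns, one block per dataset).  With
    ``replicates > 1`` a ``replicate_stats.tsv`` with per-method mean/SD of
    every metric is added.
    """
    outdir = Path(config.outdir or "benchmark_out")
    outdir.mkdir(parents=True, exist_ok=True)
    summary_blocks = []
    replicate_rows = []
    per_dataset_metrics: dict[str, dict[str, MetricSet]] = {}

    for name, sim in config.datasets.items():
        ds_dir = outdir / name
        ds_dir.mkdir(exist_ok=True)
        for rep in range(config.replicates):
            expr, truth, results, evaluations = run_dataset(
                name, sim, config, replicate=rep)
            for method, (c, m) in evaluations.items():
                replicate_rows.append(
                    {"dataset": name, "replicate": rep, "method": method,
                     "TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN,
                     **m.as_dict()})
            if rep == 0:
                io.write_expression(expr, ds_dir / "expression.tsv",
                                    ds_dir / "groups.tsv")
                io.write_truth(truth, ds_dir / "truth.tsv")
                for method, res in results.items():
                    io.write_result(res, ds_dir / f"result_{method}.tsv")
                _write_concordance(results, truth, ds_dir)
                per_dataset_metrics[name] = {m: ev[1]
                                             for m, ev in evaluations.items()}
                block = summary_frame(evaluations)
                block.insert(0, "dataset", name)
                summary_blocks.append(block.reset_index())

    summary = pd.concat(summary_blocks, ignore_index=True)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    overall_score(per_dataset_metrics).to_csv(outdir / "overall_score.tsv",
                                              sep="\t")
    if config.replicates > 1:
        stats = (pd.DataFrame(replicate_rows)
                 .groupby(["dataset", "method"])
                 .agg(["mean", "std"]))
        stats.columns = ["_".join(c) for c in stats.columns]
        stats.drop(columns=[c for c in stats.columns
                            if c.startswith("replicate")], inplace=True)
        stats.to_csv(outdir / "replicate_stats.tsv", sep="\t")
    log.info("stage=benchmark outdir=%s datasets=%d methods=%d replicates=%d",
             outdir, len(config.datasets), len(config.methods),
             config.replicates)
    return outdir


def _write_concordance(results: dict[str, DetectionResult],
                       truth: GroundTruth, outdir: Path) -> None:
    calls = MethodCallSets.from_results(results)
    pd.Series(sorted(common_degs(calls)), name="gene_id").to_csv(
        outdir / "common.tsv", sep="\t", index=False)
    venn_partition(calls).to_csv(outdir / "venn_partition.tsv", sep="\t",
                                 index=False)
    excess_crosstab(calls, truth).to_csv(outdir / "excess_crosstab.tsv",
                                         sep="\t", index=False)
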