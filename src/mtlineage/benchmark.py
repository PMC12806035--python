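"""End-to-end benchmark driver: simulate, degrade, reconstruct, score.

One replicate runs the full pipeline: tissue growth + renewal, cell
sampling, ground-truth tree extraction, then three processing conditions of
the same sample — the noise-free VAF matrix (``all_vaf``), the entry-wise
VAF > cutoff filter (``vaf_gt_cutoff``) and simulated sequencing with a
read-support threshold (``sequenced``) — each reconstructed by neighbor
joining and scored with CAS and closest-pair truth distances.

The benchmark preset uses the presence-based ``jaccard_binarized`` cell
distance: the conditions differ precisely in which low-frequency variants
they retain, and under a squared-magnitude metric a variant at VAF 0.005
contributes O(1e-5) to pairwise distances, so only a presence-based metric
lets the contrast act through the quantity it manipulates (see
docs/methods.md).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

from skbio import TreeNode

from ._rng import SAMPLE_KEY, SEQ_KEY, child_seeds, spawn
from .evalmetrics import MetricsReport, compare_conditions, paired_condition_summary
from .mito_cell import SimConfig
from .population_sim import (
    Population,
    TissueConfig,
    grow,
    ground_truth_tree,
    renew,
    sample_cells,
)
from .seq_model import SeqConfig, VAFMatrix, build_true_vaf_matrix, filter_low_vaf, sequence


@dataclass(frozen=True)
class BenchmarkConfig:
    sim: SimConfig = SimConfig()
    tissue: TissueConfig = TissueConfig()
    seq: SeqConfig = SeqConfig()
    vaf_cutoff: float = 0.01
    k_clones: int = 20
    metric: str = "jaccard_binarized"


#: Named parameter sets. "tiny" runs in seconds for smoke tests; "desk" is the
#: scaled-down renewal benchmark used by the acceptance analysis (256 cells,
#: 1000 renewal steps, 100 sampled cells); "full" is the full-size
#: default (1024 cells, 2000 steps, 200 sampled cells).
PRESETS: dict[str, BenchmarkConfig] = {
    "tiny": BenchmarkConfig(
        sim=SimConfig(N=50, mu=2e-6),
        tissue=TissueConfig(growth_divisions=4, renewal_steps=20, sample_size=10),
        k_clones=4,
    ),
    "desk": BenchmarkConfig(
        sim=SimConfig(N=500, mu=1e-7),
        tissue=TissueConfig(growth_divisions=8, renewal_steps=1000, sample_size=100),
    ),
    "full": BenchmarkConfig(
        sim=SimConfig(N=500, mu=1e-7),
        tissue=TissueConfig(growth_divisions=10, renewal_steps=2000, sample_size=200),
    ),
}


@dataclass
class ReplicateResult:
    seed: int
    population: Population
    truth: TreeNode
    matrices: dict[str, VAFMatrix]
    reports: dict[str, MetricsReport] = field(default_factory=dict)


def simulate_sample(
    config: BenchmarkConfig, seed: int
) -> tuple[Population, list, TreeNode]:
    """Grow + renew a tissue, sample cells, extract the ground-truth tree."""
    pop = grow(config.sim, config.tissue, seed=seed)
    if config.tissue.renewal_steps:
        renew(pop, config.sim, config.tissue, seed=seed)
    sampled = sample_cells(pop, config.tissue.sample_size, spawn(seed, SAMPLE_KEY))
    truth = ground_truth_tree(pop, sampled)
    return pop, sampled, truth


def condition_matrices(
    true_matrix: VAFMatrix, config: BenchmarkConfig, seed: int
) -> dict[str, VAFMatrix]:
    """The three processing conditions applied to one true VAF matrix."""
    _, observed = sequence(true_matrix, config.seq, spawn(seed, SEQ_KEY))
    return {
        "all_vaf": true_matrix.drop_zero_columns(),
        "vaf_gt_cutoff": filter_low_vaf(true_matrix, config.vaf_cutoff),
        "sequenced": observed,
    }


def run_replicate(config: BenchmarkConfig, seed: int) -> ReplicateResult:
    """One full simulate -> degrade -> reconstruct -> score replicate."""
    pop, sampled, truth = simulate_sample(config, seed)
    true_matrix = build_true_vaf_matrix(sampled)
    matrices = condition_matrices(true_matrix, config, seed)
    reports = compare_conditions(
        truth, list(matrices.items()), k=config.k_clones, metric=config.metric
    )
    result = ReplicateResult(
        seed=seed, population=pop, truth=truth, matrices=matrices
    )
    result.reports = {r.condition_tag: r for r in reports}
    return result


def run_benchmark(
    config: BenchmarkConfig, n_replicates: int, seed: int
) -> tuple[list[ReplicateResult], dict]:
    """Run independent replicates and pool them into a paired summary."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = child_seeds(seed, n_replicates)
    replicates = [run_replicate(config, s) for s in seeds]
    summary = paired_condition_summary([r.reports for r in replicates])
    summary["replicate_seeds"] = seeds
    summary["config"] = config_to_dict(config)
    return replicates, summary


def config_to_dict(config: BenchmarkConfig) -> dict:
    return dataclasses.asdict(config)
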