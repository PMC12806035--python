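"""Sequencing-noise model and VAF-matrix handling.

Converts true per-cell heteroplasmies into observed variant-allele-frequency
matrices: per cell-variant coverage is Poisson (or fixed), alt reads are
binomial, and a variant is only called when supported by at least
``support_threshold`` reads — the read-support filter that dominates
detection of low-heteroplasmy variants at realistic depths. Also provides
the entry-wise VAF cutoff filter, the empirical clone-informative variant
filter (minimum heteroplasmy in a minimum fraction of a clone's cells), and
the mtDNA coverage arithmetic for whole-genome sequencing runs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._rng import as_rng
from .mito_cell import MT_GENOME_LENGTH, CellRecord, Variant, true_vaf
from .population_sim import tip_name


@dataclass
class VAFMatrix:
    """Cells x variants matrix of allele frequencies in [0, 1]."""

    cell_ids: list[str]
    variants: list[Variant]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.variants)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.variants)} variants"
            )
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise ValueError("VAF values must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_tokens(self) -> list[str]:
        return [v.token() for v in self.variants]

    def drop_zero_columns(self) -> "VAFMatrix":
        if not self.n_variants:
            return VAFMatrix(list(self.cell_ids), [], self.values.copy())
        keep = self.values.any(axis=0)
        return VAFMatrix(
            list(self.cell_ids),
            [v for v, k in zip(self.variants, keep) if k],
            self.values[:, keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.cell_ids, columns=self.variant_tokens()
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="cell_id")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VAFMatrix":
        variants = [Variant.from_token(c) for c in frame.columns]
        return cls([str(i) for i in frame.index], variants, frame.to_numpy(dtype=float))

    @classmethod
    def read_tsv(cls, path) -> "VAFMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col="cell_id"))


@dataclass
class ReadCounts:
    """Alt/total read counts per cell-variant, aligned with a VAFMatrix."""

    cell_ids: list[str]
    variants: list[Variant]
    alt: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.cov = np.asarray(self.cov, dtype=np.int64)
        if self.alt.shape != self.cov.shape:
            raise ValueError("alt and cov must have the same shape")
        if (self.alt > self.cov).any() or (self.alt < 0).any():
            raise ValueError("need 0 <= alt <= cov elementwise")


@dataclass(frozen=True)
class SeqConfig:
    """Sequencing parameters: depth, read-support threshold, error rate."""

    depth: float = 50.0
    support_threshold: int = 2
    error_rate: float = 0.0
    coverage_model: str = "poisson"

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.support_threshold < 1:
            raise ValueError("support_threshold must be >= 1")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.coverage_model not in ("poisson", "fixed"):
            raise ValueError(f"unknown coverage_model {self.coverage_model!r}")


def build_true_vaf_matrix(sampled_cells: Sequence[CellRecord]) -> VAFMatrix:
    """Noise-free VAF matrix over the union of variants in a cell sample.

    Columns are ordered by (position, allele); an entry is 0 when the cell
    does not carry the variant.
    """
    if not sampled_cells:
        raise ValueError("empty cell sample")
    vafs = [true_vaf(c.mito) for c in sampled_cells]
    union: set[Variant] = set()
    for m in vafs:
        union.update(m)
    variants = sorted(union)
    col = {v: j for j, v in enumerate(variants)}
    values = np.zeros((len(sampled_cells), len(variants)))
    for i, m in enumerate(vafs):
        for v, f in m.items():
            values[i, col[v]] = f
    return VAFMatrix([tip_name(c.cell_id) for c in sampled_cells], variants, values)


def sequence(
    true_matrix: VAFMatrix,
    seq_config: SeqConfig = SeqConfig(),
    rng: np.random.Generator | int | None = None,
) -> tuple[ReadCounts, VAFMatrix]:
    """Simulate sequencing of a true VAF matrix.

    Per cell-variant entry with true VAF p: coverage ~ Poisson(depth) (or
    fixed), alt ~ Binomial(cov, q) with q = p(1-e) + (1-p)e/3 (e = per-read
    miscall rate, misreads split over three alternatives), and the observed
    VAF is alt/cov when alt reaches the support threshold, else 0. Columns
    that are never called are dropped from the observed matrix; the returned
    counts keep the full input shape.
    """
    rng = as_rng(rng)
    p = true_matrix.values
    shape = p.shape
    if seq_config.coverage_model == "fixed":
        cov = np.full(shape, int(round(seq_config.depth)), dtype=np.int64)
    else:
        cov = rng.poisson(seq_config.depth, size=shape).astype(np.int64)
    e = seq_config.error_rate
    q = p * (1.0 - e) + (1.0 - p) * (e / 3.0)
    alt = rng.binomial(cov, q).astype(np.int64)
    called = (alt >= seq_config.support_threshold) & (cov > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = np.where(called, alt / np.maximum(cov, 1), 0.0)
    counts = ReadCounts(
        list(true_matrix.cell_ids), list(true_matrix.variants), alt, cov
    )
    observed = VAFMatrix(
        list(true_matrix.cell_ids), list(true_matrix.variants), obs
    ).drop_zero_columns()
    return counts, observed


def filter_low_vaf(matrix: VAFMatrix, cutoff: float = 0.01) -> VAFMatrix:
    """Zero out entries with VAF <= cutoff (strict > retained), drop dead columns."""
    if not (0.0 <= cutoff < 1.0):
        raise ValueError("cutoff must be in [0, 1)")
    values = np.where(matrix.values > cutoff, matrix.values, 0.0)
    return VAFMatrix(list(matrix.cell_ids), list(matrix.variants), values).drop_zero_columns()


def empirical_clone_filter(
    matrix: VAFMatrix,
    clone_labels: Mapping[str, int],
    min_het: float = 0.05,
    min_cell_frac: float = 0.80,
) -> list[Variant]:
    """Clone-informative variants by empirical cutoffs.

    A variant is selected when *some* clone has at least ``min_cell_frac`` of
    its cells carrying it at heteroplasmy >= ``min_het`` — the classic
    "minimum 5% heteroplasmy in at least 80% of a clone's cells" rule.
    """
    missing = set(matrix.cell_ids) - set(clone_labels)
    if missing:
        raise ValueError(f"clone_labels missing cells: {sorted(missing)[:5]}")
    groups: dict[int, list[int]] = {}
    for i, cid in enumerate(matrix.cell_ids):
        groups.setdefault(clone_labels[cid], []).append(i)
    if any(not idx for idx in groups.values()):
        raise ValueError("empty clone in clone_labels")
    selected = []
    for j, v in enumerate(matrix.variants):
        col = matrix.values[:, j]
        for idx in groups.values():
            frac = float(np.mean(col[idx] >= min_het))
            if frac >= min_cell_frac:
                selected.append(v)
                break
    return selected


class CoverageEstimate(NamedTuple):
    mt_reads: float
    fold_coverage: float


def expected_mt_coverage(
    total_read_pairs: float,
    mt_fraction: float,
    bases_per_pair: float = 300.0,
    genome_length: int = MT_GENOME_LENGTH,
) -> CoverageEstimate:
    """Expected mitochondrial fold coverage of a whole-genome sequencing run.

    A typical WGS library holds ~0.5% mtDNA-derived reads; with 10 million
    PE150 read pairs that is ~50,000 mtDNA reads and ~900x fold coverage of
    the 16.6 kb genome. Returns the intermediate mtDNA read count as well.
    """
    for name, x in (
        ("total_read_pairs", total_read_pairs),
        ("mt_fraction", mt_fraction),
        ("bases_per_pair", bases_per_pair),
        ("genome_length", genome_length),
    ):
        if x <= 0:
            raise ValueError(f"{name} must be positive, got {x}")
    mt_reads = total_read_pairs * mt_fraction
    fold = mt_reads * bases_per_pair / genome_length
    return CoverageEstimate(mt_reads=float(mt_reads), fold_coverage=float(fold))


def read_counts_to_tsv(counts: ReadCounts, alt_path, cov_path) -> None:
    """Sidecar TSVs for alt and total read counts."""
    tokens = [v.token() for v in counts.variants]
    pd.DataFrame(counts.alt, index=counts.cell_ids, columns=tokens).to_csv(
        alt_path, sep="\t", index_label="cell_id"
    )
    pd.DataFrame(counts.cov, index=counts.cell_ids, columns=tokens).to_csv(
        cov_path, sep="\t", index_label="cell_id"
    )
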