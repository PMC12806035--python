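"""Intracellular mtDNA dynamics.

A cell carries hundreds of mtDNA molecules; mutant and wild-type copies
coexist (heteroplasmy) and the mutant fraction of each variant — its
variant allele frequency (VAF) — drifts at every cell division because

* replication may be *relaxed* (molecules are chosen as templates with
  replacement while the pool doubles, so some replicate more than once),
* the doubled pool is randomly partitioned between the daughters
  (vegetative segregation),
* an optional germline-style *bottleneck* transiently shrinks the pool,
* *horizontal transfer* moves molecules between unrelated cells.

This module implements those operators on explicit molecule multisets, plus
de-novo mutation under a finite-sites model and true-VAF extraction.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np

from ._rng import DIVIDE_KEY, FOUNDER_KEY, as_rng, spawn

#: Length of the human mitochondrial genome in base pairs.
MT_GENOME_LENGTH = 16569

ALLELES = "ACGT"


class Variant(NamedTuple):
    """A single-nucleotide variant, identified by (position, allele).

    The reference sequence is abstract: only positions and alternate alleles
    matter. Two equal (position, allele) pairs denote the same variant
    everywhere in a run, so the same variant can recur in independent
    lineages (homoplasy under the finite-sites model).
    """

    position: int
    allele: str

    def token(self) -> str:
        """Serialized form ``pos:allele`` (0-based position)."""
        return f"{self.position}:{self.allele}"

    @classmethod
    def from_token(cls, token: str) -> "Variant":
        pos, allele = token.split(":")
        return cls(int(pos), allele)


def reference_allele(position: int) -> str:
    """Abstract reference base at a site (fixed periodic assignment)."""
    return ALLELES[position % 4]


def variant_at(position: int, which: int = 0) -> Variant:
    """Convenience constructor: the ``which``-th non-reference allele at a site."""
    alts = [a for a in ALLELES if a != reference_allele(position)]
    return Variant(position, alts[which])


#: A haplotype is the set of variants carried by one mtDNA molecule.
#: The empty frozenset is a reference molecule.
Haplotype = frozenset

REFERENCE: Haplotype = frozenset()


class MitoPopulation:
    """Multiset of mtDNA haplotypes within one cell, with copy counts."""

    __slots__ = ("copies",)

    def __init__(self, copies: Mapping[Haplotype, int]):
        clean: dict[Haplotype, int] = {}
        for hap, count in copies.items():
            count = int(count)
            if count < 0:
                raise ValueError(f"copy count must be >= 1, got {count}")
            if count:
                clean[frozenset(hap)] = clean.get(frozenset(hap), 0) + count
        if not clean:
            raise ValueError("a MitoPopulation must contain at least one molecule")
        self.copies = clean

    @property
    def copy_number(self) -> int:
        return sum(self.copies.values())

    def variant_counts(self) -> dict[Variant, int]:
        counts: dict[Variant, int] = {}
        for hap, c in self.copies.items():
            for v in hap:
                counts[v] = counts.get(v, 0) + c
        return counts

    def __eq__(self, other) -> bool:
        return isinstance(other, MitoPopulation) and self.copies == other.copies

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MitoPopulation(copy_number={self.copy_number}, n_haplotypes={len(self.copies)})"

    def _arrays(self) -> tuple[list[Haplotype], np.ndarray]:
        """Deterministically ordered haplotype list and matching count vector."""
        haps = sorted(self.copies, key=_hap_sort_key)
        counts = np.array([self.copies[h] for h in haps], dtype=np.int64)
        return haps, counts


def _hap_sort_key(hap: Haplotype) -> tuple:
    return tuple(sorted(hap))


@dataclass
class CellRecord:
    """One cell: identity, parentage, mtDNA state, divisions since founder."""

    cell_id: int
    parent_id: Optional[int]
    mito: MitoPopulation
    n_divisions: int = 0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the intracellular model.

    Parameters
    ----------
    L : genome length in bp (human mtDNA: 16569).
    N : mtDNA copies per cell at birth.
    mu : per-site per-replication mutation probability. mtDNA mutates one to
        two orders of magnitude faster than the nuclear genome; the default
        is a placeholder in that range and should be set explicitly for any
        quantitative study.
    replication_mode : ``"relaxed"`` (templates drawn with replacement from
        the growing pool) or ``"strict_doubling"`` (every molecule copied
        exactly once).
    bottleneck_size : if set, each daughter cell passes through a bottleneck
        of this many molecules immediately after segregation, then re-expands
        to N by relaxed replication.
    transfer_rate : expected number of horizontal-transfer events per
        renewal step (0 disables transfer).
    transfer_size : molecules moved per transfer event.
    seed : root RNG seed for runs driven by this config.
    """

    L: int = MT_GENOME_LENGTH
    N: int = 500
    mu: float = 1e-7
    replication_mode: str = "relaxed"
    bottleneck_size: Optional[int] = None
    transfer_rate: float = 0.0
    transfer_size: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be positive")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not (0.0 <= self.mu < 1.0):
            raise ValueError("mu must be in [0, 1)")
        if self.replication_mode not in ("relaxed", "strict_doubling"):
            raise ValueError(f"unknown replication_mode {self.replication_mode!r}")
        if self.bottleneck_size is not None and not (1 <= self.bottleneck_size < self.N):
            raise ValueError("bottleneck_size must satisfy 1 <= b < N")
        if self.transfer_rate < 0:
            raise ValueError("transfer_rate must be >= 0")
        if self.transfer_size < 0:
            raise ValueError("transfer_size must be >= 0")

    @property
    def transfer_enabled(self) -> bool:
        return self.transfer_rate > 0 and self.transfer_size > 0


# ---------------------------------------------------------------------------
# founder construction
# ---------------------------------------------------------------------------

def make_founder(
    config: SimConfig,
    preexisting: Sequence[tuple[Variant, float]] = (),
    rng: np.random.Generator | int | None = None,
) -> CellRecord:
    """Build the founder cell with optional pre-existing heteroplasmies.

    Each pre-existing variant is placed on ``round(frequency * N)`` molecules,
    chosen independently per variant, so co-occurrence on the same molecule
    is random.
    """
    positions = [v.position for v, _ in preexisting]
    if len(set(positions)) != len(positions):
        raise ValueError("pre-existing variants must have distinct positions")
    for v, f in preexisting:
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"frequency {f} outside [0, 1] for {v}")
        if not (0 <= v.position < config.L):
            raise ValueError(f"variant position {v.position} outside [0, {config.L})")
    if rng is None:
        rng = spawn(config.seed, FOUNDER_KEY)
    rng = as_rng(rng)

    molecules: list[set] = [set() for _ in range(config.N)]
    for v, f in preexisting:
        k = int(round(f * config.N))
        if k:
            for i in rng.choice(config.N, size=k, replace=False):
                molecules[int(i)].add(v)
    pop = MitoPopulation(Counter(frozenset(m) for m in molecules))
    return CellRecord(cell_id=0, parent_id=None, mito=pop, n_divisions=0)


# ---------------------------------------------------------------------------
# replication with mutation
# ---------------------------------------------------------------------------

def _mutate(hap: Haplotype, k: int, config: SimConfig, rng: np.random.Generator) -> Haplotype:
    """Copy ``hap`` with ``k`` de-novo variants at uniform positions.

    A drawn position already mutated on this molecule is redrawn
    (no two variants share a position within one haplotype); recurrence at
    the same position on *other* molecules remains possible.
    """
    variants = set(hap)
    occupied = {v.position for v in variants}
    for _ in range(k):
        if len(occupied) >= config.L:
            raise ValueError("molecule already mutated at every site")
        pos = int(rng.integers(config.L))
        while pos in occupied:
            pos = int(rng.integers(config.L))
        alts = [a for a in ALLELES if a != reference_allele(pos)]
        variants.add(Variant(pos, alts[int(rng.integers(3))]))
        occupied.add(pos)
    return frozenset(variants)


def replicate_molecule(
    hap: Haplotype, config: SimConfig, rng: np.random.Generator | int | None = None
) -> Haplotype:
    """Replicate one molecule: the copy gains K ~ Poisson(mu * L) new variants."""
    rng = as_rng(rng)
    lam = config.mu * config.L
    k = int(rng.poisson(lam)) if lam > 0 else 0
    return _mutate(hap, k, config, rng) if k else hap


# ---------------------------------------------------------------------------
# doubling
# ---------------------------------------------------------------------------

def _relaxed_events(
    haps: list[Haplotype],
    counts: list[int],
    n_events: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[Haplotype], list[int]]:
    """Run ``n_events`` sequential replication events on a growing pool.

    Each event picks a template uniformly with replacement from the current
    pool and appends one (possibly mutated) copy — a Polya-urn scheme that
    realises relaxed replication.
    """
    lam = config.mu * config.L
    ks = rng.poisson(lam, size=n_events) if lam > 0 else np.zeros(n_events, dtype=np.int64)
    us = rng.random(n_events)
    total = int(sum(counts))
    for e in range(n_events):
        t = int(us[e] * total)
        i = 0
        acc = counts[0]
        while acc <= t:
            i += 1
            acc += counts[i]
        k = int(ks[e])
        if k:
            haps.append(_mutate(haps[i], k, config, rng))
            counts.append(1)
        else:
            counts[i] += 1
        total += 1
    return haps, counts


def _collect(haps: Iterable[Haplotype], counts: Iterable[int]) -> MitoPopulation:
    agg: Counter = Counter()
    for h, c in zip(haps, counts):
        if c:
            agg[h] += int(c)
    return MitoPopulation(agg)


def double_population(
    mito: MitoPopulation, config: SimConfig, rng: np.random.Generator | int | None = None
) -> MitoPopulation:
    """Replicate a cell's mtDNA pool from C to 2C molecules before division.

    ``strict_doubling`` copies every molecule exactly once; ``relaxed`` runs C
    replication events whose templates are drawn uniformly with replacement
    from the growing pool, so some molecules replicate more than once and
    others not at all (extra intracellular drift).
    """
    rng = as_rng(rng)
    c_total = mito.copy_number
    if c_total != config.N and not config.transfer_enabled:
        raise ValueError(
            f"copy_number {c_total} != configured N {config.N} at replication"
        )
    haps, count_arr = mito._arrays()
    counts = [int(c) for c in count_arr]
    if config.replication_mode == "strict_doubling":
        return _double_strict(haps, counts, config, rng)
    haps, counts = _relaxed_events(list(haps), counts, c_total, config, rng)
    return _collect(haps, counts)


def _double_strict(
    haps: list[Haplotype], counts: list[int], config: SimConfig, rng: np.random.Generator
) -> MitoPopulation:
    c_total = int(sum(counts))
    lam = config.mu * config.L
    new = Counter({h: 2 * c for h, c in zip(haps, counts)})
    # sum of C iid Poisson(lam) mutation counts == Poisson(C * lam) total
    # mutations, each landing on a uniformly chosen replication event
    t_mut = int(rng.poisson(lam * c_total)) if lam > 0 else 0
    if t_mut:
        cum = np.cumsum(counts)
        events = Counter(int(e) for e in rng.integers(0, c_total, size=t_mut))
        for e, k in sorted(events.items()):
            h = haps[int(np.searchsorted(cum, e, side="right"))]
            new[h] -= 1
            new[_mutate(h, k, config, rng)] += 1
    return MitoPopulation(new)


# ---------------------------------------------------------------------------
# segregation, bottleneck, transfer
# ---------------------------------------------------------------------------

def segregate(
    mito2n: MitoPopulation, rng: np.random.Generator | int | None = None
) -> tuple[MitoPopulation, MitoPopulation]:
    """Randomly partition a doubled pool into two equal daughter pools.

    Daughter 1 receives a uniform without-replacement sample of half the
    molecules (multivariate hypergeometric over haplotype counts); daughter 2
    receives the complement, so molecule identities are conserved.
    """
    rng = as_rng(rng)
    c_total = mito2n.copy_number
    if c_total % 2:
        raise ValueError(f"cannot split an odd pool of {c_total} molecules")
    haps, counts = mito2n._arrays()
    d1 = rng.multivariate_hypergeometric(counts, c_total // 2)
    d2 = counts - d1
    return _collect(haps, d1), _collect(haps, d2)


def bottleneck(
    mito: MitoPopulation, config: SimConfig, rng: np.random.Generator | int | None = None
) -> MitoPopulation:
    """Shrink the pool to ``bottleneck_size`` molecules, then re-expand to N.

    The surviving molecules are a uniform without-replacement sample; the
    re-expansion uses relaxed replication (and can therefore add de-novo
    mutations). Low-frequency variants are frequently lost outright, while a
    surviving variant's frequency can jump drastically — up to fixation.
    """
    rng = as_rng(rng)
    b = config.bottleneck_size
    if b is None:
        raise ValueError("bottleneck_size is not set in this config")
    if b >= config.N:
        raise ValueError(f"bottleneck_size {b} must be < N = {config.N}")
    if b >= mito.copy_number:
        raise ValueError(f"bottleneck_size {b} must be < copy_number {mito.copy_number}")
    haps, counts = mito._arrays()
    kept = rng.multivariate_hypergeometric(counts, b)
    haps2 = [h for h, c in zip(haps, kept) if c]
    counts2 = [int(c) for c in kept if c]
    haps2, counts2 = _relaxed_events(haps2, counts2, config.N - b, config, rng)
    return _collect(haps2, counts2)


def transfer(
    donor: CellRecord,
    recipient: CellRecord,
    k: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[CellRecord, CellRecord]:
    """Move ``k`` molecules from donor to recipient (horizontal transfer).

    Move semantics: the sampled molecules are removed from the donor and added
    to the recipient, so the VAFs of *both* cells change and total copies of
    every variant across the pair are conserved.
    """
    rng = as_rng(rng)
    if not (1 <= k < donor.mito.copy_number):
        raise ValueError(
            f"transfer size {k} must satisfy 1 <= k < donor copy_number "
            f"{donor.mito.copy_number}"
        )
    haps, counts = donor.mito._arrays()
    moved = rng.multivariate_hypergeometric(counts, k)
    donor_pop = _collect(haps, counts - moved)
    merged: Counter = Counter(recipient.mito.copies)
    for h, c in zip(haps, moved):
        if c:
            merged[h] += int(c)
    return (
        replace(donor, mito=donor_pop),
        replace(recipient, mito=MitoPopulation(merged)),
    )


# ---------------------------------------------------------------------------
# division and readout
# ---------------------------------------------------------------------------

def divide(
    cell: CellRecord,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    child_ids: Optional[tuple[int, int]] = None,
) -> tuple[CellRecord, CellRecord]:
    """Divide a cell: double the pool, segregate, optionally bottleneck.

    Daughters get fresh ids (binary-heap labelling ``2i+1, 2i+2`` by default,
    which keeps ids globally unique when all divisions use it) and
    ``n_divisions`` incremented.
    """
    if rng is None:
        rng = spawn(config.seed, DIVIDE_KEY, cell.cell_id)
    rng = as_rng(rng)
    doubled = double_population(cell.mito, config, rng)
    m1, m2 = segregate(doubled, rng)
    if config.bottleneck_size is not None:
        m1 = bottleneck(m1, config, rng)
        m2 = bottleneck(m2, config, rng)
    if child_ids is None:
        child_ids = (2 * cell.cell_id + 1, 2 * cell.cell_id + 2)
    nd = cell.n_divisions + 1
    d1 = CellRecord(child_ids[0], cell.cell_id, m1, nd)
    d2 = CellRecord(child_ids[1], cell.cell_id, m2, nd)
    return d1, d2


def true_vaf(mito: MitoPopulation) -> dict[Variant, float]:
    """Exact per-variant heteroplasmy: carrying copies / total copies.

    Variants absent from the cell do not appear in the map, so every reported
    frequency is in (0, 1].
    """
    c_total = mito.copy_number
    return {v: c / c_total for v, c in sorted(mito.variant_counts().items())}


# ---------------------------------------------------------------------------
# debug serialization
# ---------------------------------------------------------------------------

def population_to_tsv(mito: MitoPopulation) -> str:
    """Tab-separated dump: haplotype_id, copy_count, comma-joined pos:allele."""
    lines = ["haplotype_id\tcopy_count\tvariants"]
    haps, counts = mito._arrays()
    for i, (h, c) in enumerate(zip(haps, counts)):
        tokens = ",".join(v.token() for v in sorted(h))
        lines.append(f"{i}\t{int(c)}\t{tokens}")
    return "\n".join(lines) + "\n"


def population_from_tsv(text: str) -> MitoPopulation:
    copies: Counter = Counter()
    for line in text.strip().splitlines()[1:]:
        _, count, tokens = line.split("\t")
        hap = frozenset(Variant.from_token(t) for t in tokens.split(",") if t)
        copies[hap] += int(count)
    return MitoPopulation(copies)
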