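"""Tissue-level simulation: expansion, renewal, sampling, ground-truth trees.

A tissue starts from one founder cell, expands by synchronous divisions to
2^g cells (the developmental phase), then enters a constant-size renewal
phase modelled as a Moran process: each step one cell divides and another
dies, so the population size stays fixed while the number of surviving
founder-era lineages decays. The full division history is recorded, and the
genealogy of any sampled set of cells can be extracted as a rooted tree with
branch lengths in cell divisions — the ground truth that reconstructed
phylogenies are scored against.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skbio import TreeNode

from ._rng import DIVIDE_KEY, SAMPLE_KEY, STEP_KEY, as_rng, spawn
from .mito_cell import CellRecord, SimConfig, Variant, divide, make_founder, transfer


@dataclass(frozen=True)
class TissueConfig:
    """Population-level parameters.

    growth_divisions : rounds of synchronous expansion g (2^g cells).
    renewal_steps : Moran birth-death steps r after expansion.
    sample_size : cells sampled at the end of the run.
    max_cells : guard against accidentally huge expansions.
    renewal_mode : ``"moran"`` (divide one / kill one per step) or
        ``"synchronous_culling"`` (every cell divides, then half survive).
    """

    growth_divisions: int = 10
    renewal_steps: int = 2000
    sample_size: int = 200
    max_cells: int = 100_000
    renewal_mode: str = "moran"

    def __post_init__(self):
        if self.growth_divisions < 0:
            raise ValueError("growth_divisions must be >= 0")
        if self.renewal_steps < 0:
            raise ValueError("renewal_steps must be >= 0")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.sample_size > 2 ** self.growth_divisions:
            raise ValueError("sample_size exceeds final population size 2^g")
        if self.renewal_mode not in ("moran", "synchronous_culling"):
            raise ValueError(f"unknown renewal_mode {self.renewal_mode!r}")


class Population:
    """Alive cells plus the append-only division/death history."""

    def __init__(self, founder: CellRecord):
        self.founder_id = founder.cell_id
        self.alive: dict[int, CellRecord] = {founder.cell_id: founder}
        self.parent: dict[int, Optional[int]] = {founder.cell_id: founder.parent_id}
        self.n_divisions: dict[int, int] = {founder.cell_id: founder.n_divisions}
        self.history: list[tuple] = []

    @property
    def size(self) -> int:
        return len(self.alive)

    def alive_ids(self) -> list[int]:
        return sorted(self.alive)

    def _register_division(self, parent_id: int, d1: CellRecord, d2: CellRecord, step: int):
        if d1.cell_id in self.parent or d2.cell_id in self.parent:
            raise RuntimeError("duplicate cell id in genealogy")
        del self.alive[parent_id]
        for d in (d1, d2):
            self.alive[d.cell_id] = d
            self.parent[d.cell_id] = parent_id
            self.n_divisions[d.cell_id] = d.n_divisions
        self.history.append(("division", parent_id, d1.cell_id, d2.cell_id, step))

    def _register_death(self, cell_id: int, step: int):
        del self.alive[cell_id]
        self.history.append(("death", cell_id, step))


def grow(
    sim_config: SimConfig,
    tissue_config: TissueConfig,
    seed: Optional[int] = None,
    preexisting: Sequence[tuple[Variant, float]] = (),
) -> Population:
    """Expand one founder through g rounds of synchronous division.

    Every alive cell divides in every round, so the final population has
    2^g cells, all with ``n_divisions == g``. Per-cell RNG streams are keyed
    by (seed, cell id), so the iteration order is irrelevant.
    """
    if seed is None:
        seed = sim_config.seed
    if 2 ** tissue_config.growth_divisions > tissue_config.max_cells:
        raise ValueError(
            f"2^{tissue_config.growth_divisions} cells would exceed "
            f"max_cells={tissue_config.max_cells}"
        )
    founder = make_founder(sim_config, preexisting)
    pop = Population(founder)
    for round_idx in range(tissue_config.growth_divisions):
        for cell_id in pop.alive_ids():
            cell = pop.alive[cell_id]
            d1, d2 = divide(cell, sim_config, rng=spawn(seed, DIVIDE_KEY, cell_id))
            pop._register_division(cell_id, d1, d2, step=-(round_idx + 1))
    return pop


def renew(
    pop: Population,
    sim_config: SimConfig,
    tissue_config: TissueConfig,
    seed: Optional[int] = None,
) -> Population:
    """Run the constant-size renewal phase in place and return the population.

    Moran mode: each step one uniformly chosen cell divides (both daughters
    enter) and one cell chosen uniformly among the *other* pre-division cells
    dies, so a step's daughters never die in the same step and the size is
    conserved exactly. Optional horizontal-transfer events (Poisson per step)
    move molecules between distinct alive cells.
    """
    if seed is None:
        seed = sim_config.seed
    if pop.size < 2:
        raise ValueError("renewal needs at least 2 cells")
    if tissue_config.renewal_mode == "synchronous_culling":
        return _renew_synchronous(pop, sim_config, tissue_config, seed)
    step_rng = spawn(seed, STEP_KEY)
    for step in range(tissue_config.renewal_steps):
        ids = pop.alive_ids()
        m = len(ids)
        divider = ids[int(step_rng.integers(m))]
        others = [i for i in ids if i != divider]
        victim = others[int(step_rng.integers(m - 1))]
        cell = pop.alive[divider]
        d1, d2 = divide(cell, sim_config, rng=spawn(seed, DIVIDE_KEY, divider))
        pop._register_division(divider, d1, d2, step)
        pop._register_death(victim, step)
        if sim_config.transfer_enabled:
            _transfer_events(pop, sim_config, step_rng)
    return pop


def _transfer_events(pop: Population, sim_config: SimConfig, rng: np.random.Generator):
    n_events = int(rng.poisson(sim_config.transfer_rate))
    for _ in range(n_events):
        ids = pop.alive_ids()
        donor_id, recip_id = (ids[int(i)] for i in rng.choice(len(ids), size=2, replace=False))
        donor, recip = pop.alive[donor_id], pop.alive[recip_id]
        k = sim_config.transfer_size
        if 1 <= k < donor.mito.copy_number:
            donor, recip = transfer(donor, recip, k, rng)
            pop.alive[donor_id] = donor
            pop.alive[recip_id] = recip


def _renew_synchronous(
    pop: Population, sim_config: SimConfig, tissue_config: TissueConfig, seed: int
) -> Population:
    """Alternative renewal: every cell divides, then a uniform half survives."""
    step_rng = spawn(seed, STEP_KEY)
    for step in range(tissue_config.renewal_steps):
        m = pop.size
        for cell_id in pop.alive_ids():
            cell = pop.alive[cell_id]
            d1, d2 = divide(cell, sim_config, rng=spawn(seed, DIVIDE_KEY, cell_id))
            pop._register_division(cell_id, d1, d2, step)
        ids = pop.alive_ids()
        survivors = set(
            ids[int(i)] for i in step_rng.choice(len(ids), size=m, replace=False)
        )
        for cell_id in ids:
            if cell_id not in survivors:
                pop._register_death(cell_id, step)
    return pop


def sample_cells(
    pop: Population, n: int, rng: np.random.Generator | int | None = None
) -> list[CellRecord]:
    """Uniform without-replacement sample of alive cells (seed-deterministic)."""
    rng = as_rng(rng)
    ids = pop.alive_ids()
    if n > len(ids):
        raise ValueError(f"cannot sample {n} cells from {len(ids)} alive")
    chosen = sorted(ids[int(i)] for i in rng.choice(len(ids), size=n, replace=False))
    return [pop.alive[i] for i in chosen]


# ---------------------------------------------------------------------------
# ground-truth tree extraction
# ---------------------------------------------------------------------------

def tip_name(cell_id: int) -> str:
    return f"cell{cell_id}"


def ground_truth_tree(pop: Population, sampled: Sequence[CellRecord]) -> TreeNode:
    """Prune the recorded genealogy to the sampled cells.

    Returns a rooted tree whose root is the sample MRCA, tips are labelled
    ``cell<ID>`` and branch lengths count cell divisions. Unifurcating
    internal nodes are suppressed with their branch lengths summed.
    """
    if not sampled:
        raise ValueError("sampled cell list is empty")
    tips = set()
    for c in sampled:
        if c.cell_id not in pop.parent:
            raise ValueError(f"cell id {c.cell_id} not in genealogy")
        tips.add(c.cell_id)

    keep: set[int] = set()
    for t in tips:
        x: Optional[int] = t
        while x is not None and x not in keep:
            keep.add(x)
            x = pop.parent[x]
    children: dict[int, list[int]] = {}
    for x in keep:
        p = pop.parent[x]
        if p is not None:
            children.setdefault(p, []).append(x)

    def build(x: int) -> TreeNode:
        ch = sorted(children.get(x, ()))
        if not ch:
            node = TreeNode(name=tip_name(x))
            node.length = 1.0
            return node
        subs = [build(c) for c in ch]
        if len(subs) == 1:
            # unifurcation: absorb this node's parent edge into the child
            subs[0].length += 1.0
            return subs[0]
        node = TreeNode(children=subs)
        node.length = 1.0
        return node

    root = build(pop.founder_id)
    root.length = None
    return root


def cell_metadata_tsv(
    pop: Population,
    sampled: Sequence[CellRecord],
    clone_labels: Optional[dict[str, int]] = None,
) -> str:
    """TSV of sampled cells: cell_id, parent_id, n_divisions, clone_label."""
    lines = ["cell_id\tparent_id\tn_divisions\tclone_label"]
    for c in sorted(sampled, key=lambda c: c.cell_id):
        clone = "" if clone_labels is None else clone_labels.get(tip_name(c.cell_id), "")
        parent = "" if c.parent_id is None else c.parent_id
        lines.append(f"{c.cell_id}\t{parent}\t{c.n_divisions}\t{clone}")
    return "\n".join(lines) + "\n"
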