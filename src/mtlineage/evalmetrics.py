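"""Benchmark metrics for reconstructed single-cell lineages.

Two complementary scores quantify how well a tree reconstructed from mtDNA
variant profiles recovers a recorded ground-truth genealogy:

* the clone aggregation score (CAS) measures, per ground-truth clone, how
  tightly the clone's cells cluster in the reconstructed tree (coarse,
  clone-level accuracy), and
* the closest-pair ground-truth distance takes each tip's nearest neighbour
  in the *reconstructed* tree and measures their path distance (in cell
  divisions) in the *truth* tree — small values mean the reconstruction
  resolves fine-scale relatives correctly.

Both depend only on distance ranks in the reconstruction plus truth-tree
distances, so they are invariant to rerooting and uniform rescaling of the
reconstructed tree.

The CAS formula used here is a nearest-neighbour purity: for a clone with
n_c >= 2 cells, each cell's m = n_c - 1 nearest other tips (by reconstructed
cophenetic distance, ties broken by label) are inspected and the same-clone
fraction averaged over the clone. A perfectly monophyletic clone in an
ultrametric reconstruction scores 1; random labels score (n_c - 1)/(n - 1)
in expectation. Singleton clones score 1 by convention. The definition is
isolated in one function so an alternative formula can be swapped in.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from skbio import TreeNode

from .phylo import cophenetic, neighbor_joining, vaf_distance
from .seq_model import VAFMatrix

CONDITION_TAGS = ("all_vaf", "vaf_gt_cutoff", "sequenced")


@dataclass
class CloneAssignment:
    """Map from tip label to clone index in [0, k)."""

    labels: dict[str, int]
    k: int

    def clone_sizes(self) -> dict[int, int]:
        return dict(Counter(self.labels.values()))


def _tipset(node: TreeNode) -> frozenset:
    if node.is_tip():
        return frozenset((node.name,))
    return frozenset(t.name for t in node.tips())


def assign_clones(truth: TreeNode, k: int = 20) -> CloneAssignment:
    """Partition the truth tree's tips into k clades of similar size.

    Greedy top-down splitting: start from the root's children and repeatedly
    replace the group with the most tips by its root bifurcation's children
    until k groups exist. Every group is a clade of the truth tree and the
    procedure is deterministic (ties by smallest tip label).
    """
    tips = [t.name for t in truth.tips()]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(tips):
        raise ValueError(f"k = {k} exceeds tip count {len(tips)}")
    groups: list[TreeNode] = list(truth.children)
    while len(groups) < k:
        splittable = [g for g in groups if not g.is_tip()]
        # largest group first; ties by smallest descendant label
        target = min(splittable, key=lambda g: (-len(_tipset(g)), min(_tipset(g))))
        groups.remove(target)
        groups.extend(target.children)
    groups.sort(key=lambda g: min(_tipset(g)))
    labels = {
        tip: idx for idx, g in enumerate(groups) for tip in _tipset(g)
    }
    return CloneAssignment(labels=labels, k=len(groups))


@dataclass
class CASResult:
    per_clone: dict[int, float]
    per_cell: dict[str, float]

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_clone.values())))


def _neighbour_order(dmat: np.ndarray, ids: list[str]) -> list[list[int]]:
    """For each tip, indices of the other tips sorted by (distance, label)."""
    order = []
    for i in range(len(ids)):
        others = [j for j in range(len(ids)) if j != i]
        others.sort(key=lambda j: (dmat[i, j], ids[j]))
        order.append(others)
    return order


def clone_aggregation_score(
    recon: TreeNode, assignment: CloneAssignment
) -> CASResult:
    """Clone aggregation score per clone (see module docstring for the formula)."""
    coph = cophenetic(recon)
    ids = list(coph.ids)
    if set(ids) != set(assignment.labels):
        raise ValueError("reconstructed tree tips do not match clone assignment")
    labels = assignment.labels
    sizes = Counter(labels.values())
    dmat = coph.data
    order = _neighbour_order(dmat, ids)
    per_cell: dict[str, float] = {}
    for i, name in enumerate(ids):
        c = labels[name]
        m = sizes[c] - 1
        if m == 0:
            per_cell[name] = 1.0
            continue
        nearest = order[i][:m]
        per_cell[name] = sum(labels[ids[j]] == c for j in nearest) / m
    per_clone = {
        c: float(np.mean([per_cell[name] for name in ids if labels[name] == c]))
        for c in sorted(sizes)
    }
    return CASResult(per_clone=per_clone, per_cell=per_cell)


def closest_pair_truth_distance(
    recon: TreeNode,
    truth: TreeNode,
    mode: str = "path",
) -> dict[str, float]:
    """Ground-truth distance to each tip's nearest reconstructed neighbour.

    For each tip i, the partner j* minimizes the reconstructed cophenetic
    distance (ties broken by smallest label). ``mode="path"`` returns the
    truth-tree path distance d_truth(i, j*) in divisions; ``mode="terminal_edges"``
    returns the sum of the pair's two terminal branch lengths in the truth
    tree instead.
    """
    if mode not in ("path", "terminal_edges"):
        raise ValueError(f"unknown mode {mode!r}")
    cr = cophenetic(recon)
    ct = cophenetic(truth)
    if set(cr.ids) != set(ct.ids):
        raise ValueError("reconstructed and truth trees have different tip sets")
    ids = list(cr.ids)
    order = _neighbour_order(cr.data, ids)
    if mode == "terminal_edges":
        term = {t.name: float(t.length or 0.0) for t in truth.tips()}
    out: dict[str, float] = {}
    tindex = {name: i for i, name in enumerate(ct.ids)}
    for i, name in enumerate(ids):
        j = order[i][0]
        partner = ids[j]
        if mode == "path":
            out[name] = float(ct.data[tindex[name], tindex[partner]])
        else:
            out[name] = term[name] + term[partner]
    return out


def _summary(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(list(values), dtype=float)
    return {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "q25": float(np.quantile(arr, 0.25)),
        "q75": float(np.quantile(arr, 0.75)),
    }


@dataclass
class MetricsReport:
    """Per-condition evaluation: CAS per clone/cell plus closest-pair distances."""

    condition_tag: str
    cas_per_clone: dict[int, float]
    cas_per_cell: dict[str, float]
    closest_pair: dict[str, float]
    summary: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.summary:
            self.summary = {
                "cas": _summary(self.cas_per_clone.values()),
                "cas_per_cell_mean": float(np.mean(list(self.cas_per_cell.values()))),
                "closest_pair": _summary(self.closest_pair.values()),
            }

    @property
    def cas_mean(self) -> float:
        return self.summary["cas"]["mean"]

    @property
    def closest_pair_mean(self) -> float:
        return self.summary["closest_pair"]["mean"]

    def to_dict(self) -> dict:
        return {
            "condition_tag": self.condition_tag,
            "cas_per_clone": {str(k): v for k, v in self.cas_per_clone.items()},
            "cas_per_cell": dict(self.cas_per_cell),
            "closest_pair_truth_distances": dict(self.closest_pair),
            "summary": self.summary,
        }


def evaluate_reconstruction(
    recon: TreeNode,
    truth: TreeNode,
    assignment: CloneAssignment,
    condition_tag: str = "all_vaf",
) -> MetricsReport:
    """Score one reconstructed tree against the truth tree."""
    cas = clone_aggregation_score(recon, assignment)
    cp = closest_pair_truth_distance(recon, truth)
    return MetricsReport(
        condition_tag=condition_tag,
        cas_per_clone=cas.per_clone,
        cas_per_cell=cas.per_cell,
        closest_pair=cp,
    )


def compare_conditions(
    truth: TreeNode,
    matrices: Sequence[tuple[str, VAFMatrix]],
    k: int = 20,
    metric: str = "euclidean",
) -> list[MetricsReport]:
    """Reconstruct and score one VAF matrix per processing condition.

    Each matrix (e.g. all variants / VAF-cutoff filtered / sequencing-derived)
    must cover the same cell set as the truth tree; the pipeline per condition
    is vaf_distance -> neighbor_joining -> CAS + closest-pair distances.
    """
    truth_tips = {t.name for t in truth.tips()}
    assignment = assign_clones(truth, k)
    reports = []
    for tag, matrix in matrices:
        if set(matrix.cell_ids) != truth_tips:
            raise ValueError(f"matrix {tag!r} cells do not match truth tips")
        recon = neighbor_joining(vaf_distance(matrix, metric))
        reports.append(evaluate_reconstruction(recon, truth, assignment, tag))
    return reports


# ---------------------------------------------------------------------------
# replicate-level paired comparisons
# ---------------------------------------------------------------------------

def sign_test(deltas: Sequence[float], alternative: str = "greater") -> dict:
    """Paired sign test on per-replicate deltas (zero deltas dropped)."""
    nonzero = [d for d in deltas if d != 0.0]
    n_pos = sum(d > 0 for d in nonzero)
    if not nonzero:
        return {"n": 0, "n_positive": 0, "p_value": 1.0}
    p = stats.binomtest(n_pos, len(nonzero), 0.5, alternative=alternative).pvalue
    return {"n": len(nonzero), "n_positive": n_pos, "p_value": float(p)}


def paired_condition_summary(
    replicate_reports: Sequence[Mapping[str, MetricsReport]],
) -> dict:
    """Pool per-replicate reports into condition means and directional tests.

    Tests the two benchmark directions: sequencing noise lowers the mean CAS
    relative to the noise-free all-variant condition, and excluding low-VAF
    variants raises the mean closest-pair ground-truth distance.
    """
    tags = list(replicate_reports[0])
    means_cas = {t: [rep[t].cas_mean for rep in replicate_reports] for t in tags}
    means_cp = {t: [rep[t].closest_pair_mean for rep in replicate_reports] for t in tags}
    out: dict = {
        "n_replicates": len(replicate_reports),
        "cas_mean": {t: float(np.mean(means_cas[t])) for t in tags},
        "closest_pair_mean": {t: float(np.mean(means_cp[t])) for t in tags},
    }
    if "all_vaf" in tags and "sequenced" in tags:
        deltas = [a - s for a, s in zip(means_cas["all_vaf"], means_cas["sequenced"])]
        out["cas_drop_under_sequencing"] = {
            "deltas": deltas,
            **sign_test(deltas, "greater"),
        }
    if "all_vaf" in tags and "vaf_gt_cutoff" in tags:
        deltas = [c - a for c, a in zip(means_cp["vaf_gt_cutoff"], means_cp["all_vaf"])]
        out["closest_pair_rise_under_cutoff"] = {
            "deltas": deltas,
            **sign_test(deltas, "greater"),
        }
    return out
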