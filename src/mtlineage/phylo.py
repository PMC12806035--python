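"""Distance-based phylogeny reconstruction from single-cell VAF profiles.

Pairwise cell distances over variant-frequency vectors feed a classical
neighbor-joining reconstruction (consistent on additive distance matrices,
which additive-tree round-trip tests exploit as an exact oracle), with
cophenetic distances and canonical Newick I/O on top.
"""
from __future__ import annotations

import io
import warnings
from typing import Iterable

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from ._rng import as_rng
from .seq_model import VAFMatrix

METRICS = ("euclidean", "manhattan", "jaccard_binarized")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def vaf_distance(matrix: VAFMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise cell-cell distances over VAF vectors.

    ``euclidean`` and ``manhattan`` act on raw frequencies;
    ``jaccard_binarized`` first binarizes at VAF > 0 and uses one minus the
    Jaccard index of the variant presence sets (two cells with no variants at
    all are at distance 0). A matrix with zero variants yields an all-zero
    distance matrix with a warning.
    """
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells for a distance matrix")
    ids = [str(c) for c in matrix.cell_ids]
    if matrix.n_variants == 0:
        warnings.warn("VAF matrix has no variants; distances are all zero")
        return DistanceMatrix(np.zeros((matrix.n_cells, matrix.n_cells)), ids)
    x = matrix.values
    if metric == "euclidean":
        d = squareform(pdist(x, metric="euclidean"))
    elif metric == "manhattan":
        d = squareform(pdist(x, metric="cityblock"))
    elif metric == "jaccard_binarized":
        b = (x > 0).astype(float)
        inter = b @ b.T
        sizes = b.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(union > 0, 1.0 - inter / np.maximum(union, 1e-300), 0.0)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining.

    At each step joins the pair minimizing
    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),
    with the standard limb-length and distance-update formulas. Ties are
    broken by the smallest (label, label) pair so runs are reproducible, and
    negative limb lengths are clamped to zero per join. Returns an unrooted
    tree represented with a trifurcating root (single edge for n = 2).
    """
    ids = list(dm.ids)
    d = np.asarray(dm.data, dtype=float).copy()
    if (d < 0).any():
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    n = len(ids)
    if n == 0:
        raise ValueError("empty distance matrix")
    nodes = [TreeNode(name=i) for i in ids]
    reps = list(ids)  # smallest descendant tip label per active node

    while len(nodes) > 3:
        m = len(nodes)
        row = d.sum(axis=1)
        q = (m - 2) * d - row[:, None] - row[None, :]
        # rounding makes q asymmetric in the last ulp; search i < j only
        q[np.tril_indices(m)] = np.inf
        ties = np.argwhere(q == q.min())
        i, j = min(
            ((tuple(sorted((reps[a], reps[b]))), (int(a), int(b))) for a, b in ties)
        )[1]
        dij = d[i, j]
        li_raw = 0.5 * dij + (row[i] - row[j]) / (2.0 * (m - 2))
        lj_raw = dij - li_raw
        nodes[i].length = max(li_raw, 0.0)
        nodes[j].length = max(lj_raw, 0.0)
        joined = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [joined]
        reps = [reps[k] for k in keep] + [new_rep]

    if len(nodes) == 3:
        d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
        limbs = (
            0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01),
        )
        for node, limb in zip(nodes, limbs):
            node.length = max(limb, 0.0)
        root = TreeNode(children=nodes)
    elif len(nodes) == 2:
        nodes[0].length = nodes[1].length = d[0, 1] / 2.0
        root = TreeNode(children=nodes)
    else:
        root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# cophenetic distances
# ---------------------------------------------------------------------------

def cophenetic(tree: TreeNode) -> DistanceMatrix:
    """Path-length distance between every tip pair, ids sorted (rooting-invariant)."""
    work = tree.copy()
    for node in work.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    dm = work.tip_tip_distances()
    return dm.filter(sorted(dm.ids))


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = set("():;,[]' \t\n")


def _format_length(length) -> str:
    if length is None:
        return ""
    x = float(length)
    if x.is_integer():
        return f":{int(x)}"
    return f":{format(x, '.12g')}"


def _min_tip_label(node: TreeNode) -> str:
    if node.is_tip():
        return node.name or ""
    return min(_min_tip_label(c) for c in node.children)


def write_newick(tree: TreeNode) -> str:
    """Serialize in canonical form: children sorted by smallest descendant label,
    integer-valued branch lengths written as integers."""

    def ser(node: TreeNode) -> str:
        if node.is_tip():
            name = node.name or ""
            if set(name) & _NEWICK_UNSAFE:
                raise ValueError(f"tip label {name!r} contains newick metacharacters")
            return f"{name}{_format_length(node.length)}"
        parts = sorted(node.children, key=_min_tip_label)
        inner = ",".join(ser(c) for c in parts)
        return f"({inner}){_format_length(node.length)}"

    return ser(tree) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string, reporting the position of structural errors."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"newick parse error at position {pos}: unmatched ')'")
    if depth != 0:
        raise ValueError(
            f"newick parse error at position {len(text) - 1}: {depth} unclosed '('"
        )
    if ";" not in text:
        raise ValueError(f"newick parse error at position {len(text) - 1}: missing ';'")
    try:
        return TreeNode.read(io.StringIO(text), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio NewickFormatError
        raise ValueError(f"newick parse error: {exc}") from exc


# ---------------------------------------------------------------------------
# oracle helpers: random additive trees, Robinson-Foulds
# ---------------------------------------------------------------------------

def random_additive_tree(
    n_tips: int,
    rng: np.random.Generator | int | None = None,
    min_len: int = 1,
    max_len: int = 10,
) -> TreeNode:
    """Random binary tree with integer branch lengths (additive-matrix oracle)."""
    rng = as_rng(rng)
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    forest = [TreeNode(name=f"T{i}") for i in range(n_tips)]
    for node in forest:
        node.length = float(rng.integers(min_len, max_len + 1))
    while len(forest) > 2:
        i, j = sorted(int(k) for k in rng.choice(len(forest), size=2, replace=False))
        b = forest.pop(j)
        a = forest.pop(i)
        joined = TreeNode(children=[a, b])
        joined.length = float(rng.integers(min_len, max_len + 1))
        forest.append(joined)
    root = TreeNode(children=forest)
    root.length = None
    return root


def _splits(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of the tip set (unrooted view)."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        clade = frozenset(t.name for t in node.tips())
        other = all_tips - clade
        if len(clade) >= 2 and len(other) >= 2:
            splits.add(frozenset((clade, other)))
    return splits


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Unrooted Robinson-Foulds distance (symmetric split difference)."""
    tips1 = {t.name for t in t1.tips()}
    tips2 = {t.name for t in t2.tips()}
    if tips1 != tips2:
        raise ValueError("trees have different tip sets")
    return len(_splits(t1) ^ _splits(t2))
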