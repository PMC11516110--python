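"""UPGMA trees and clustering-quality metrics.

Two statistics score how well a dendrogram groups receptors of like
specificity: the number of label (colour) changes between successive leaves
around the circular tree, and the pMHC-distance — per peptide, the mean
cophenetic (branch-length) distance over all leaf pairs sharing that
peptide, averaged with equal peptide weights.  Significance is assessed by
permuting the pairwise distances themselves and re-clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .core import DistanceMatrix

__all__ = [
    "ClusterTree",
    "upgma",
    "colour_changes",
    "pmhc_distance",
    "cluster_count",
    "permutation_null",
    "PermutationResult",
]


@dataclass
class ClusterTree:
    """Rooted ultrametric UPGMA dendrogram over TCR leaves.

    Wraps a scipy linkage matrix.  Leaf order is deterministic: at every
    internal node the subtree containing the smallest original leaf index
    comes first.  Node heights are half the merge distance, so the patristic
    (sum of branch lengths) distance between two leaves equals their
    cophenetic merge distance.
    """

    ids: tuple[str, ...]
    linkage: np.ndarray
    leaf_order: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        order = self._subtree_leaves(len(self.ids) + len(self.linkage) - 1)
        self.leaf_order = tuple(self.ids[i] for i in order)

    def _children(self, node: int) -> tuple[int, int]:
        row = self.linkage[node - len(self.ids)]
        return int(row[0]), int(row[1])

    def _subtree_leaves(self, node: int) -> list[int]:
        n = len(self.ids)
        if node < n:
            return [node]
        left = self._subtree_leaves(self._children(node)[0])
        right = self._subtree_leaves(self._children(node)[1])
        if min(right) < min(left):
            left, right = right, left
        return left + right

    def _height(self, node: int) -> float:
        n = len(self.ids)
        return 0.0 if node < n else float(self.linkage[node - n, 2]) / 2.0

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distances (== patristic, ultrametric)."""
        return hierarchy.cophenet(self.linkage)

    def newick(self) -> str:
        def fmt(node: int, parent_h: float) -> str:
            blen = parent_h - self._height(node)
            if node < len(self.ids):
                return f"{self.ids[node]}:{blen:.10g}"
            a, b = self._children(node)
            h = self._height(node)
            la = self._subtree_leaves(a)
            lb = self._subtree_leaves(b)
            if min(lb) < min(la):
                a, b = b, a
            return f"({fmt(a, h)},{fmt(b, h)}):{blen:.10g}"

        root = len(self.ids) + len(self.linkage) - 1
        return fmt(root, self._height(root)) + ";"


def upgma(matrix: DistanceMatrix, use_normalized: bool = True) -> ClusterTree:
    """Average-linkage (UPGMA) tree, by default from the normalized distances."""
    vec = matrix.normalized if use_normalized else matrix.raw
    if len(matrix.ids) < 2:
        raise ValueError("need at least 2 leaves")
    if np.any(~np.isfinite(vec)):
        raise ValueError("distance matrix contains NaN/inf")
    Z = hierarchy.linkage(vec, method="average")
    return ClusterTree(ids=matrix.ids, linkage=Z)


def _require_labels(tree: ClusterTree, labels: Mapping[str, str]) -> list[str]:
    missing = [i for i in tree.leaf_order if i not in labels]
    if missing:
        raise ValueError(f"unlabelled leaves: {missing}")
    return [labels[i] for i in tree.leaf_order]


def colour_changes(tree: ClusterTree, labels: Mapping[str, str]) -> int:
    """Label switches between successive leaves in circular order."""
    seq = _require_labels(tree, labels)
    return sum(a != b for a, b in zip(seq, seq[1:] + seq[:1]))


def cluster_count(tree: ClusterTree, labels: Mapping[str, str],
                  peptide: str) -> int:
    """Number of contiguous blocks the peptide's leaves form (circular)."""
    seq = _require_labels(tree, labels)
    if peptide not in seq:
        raise ValueError(f"peptide {peptide!r} not present on any leaf")
    hits = [lab == peptide for lab in seq]
    if all(hits):
        return 1
    starts = sum(
        hits[i] and not hits[i - 1] for i in range(len(hits))
    )  # i-1 wraps at i=0
    return starts


def pmhc_distance(
    tree: ClusterTree, labels: Mapping[str, str]
) -> tuple[float, pd.DataFrame]:
    """Mean within-peptide cophenetic distance, equal weight per peptide.

    Peptides with fewer than 2 leaves (singletons) are excluded.  Returns
    the overall statistic and a per-peptide table (n_tcrs, mean distance,
    number of circular clusters).
    """
    seq = _require_labels(tree, labels)
    from scipy.spatial.distance import squareform

    coph = squareform(tree.cophenetic())
    index = {tid: i for i, tid in enumerate(tree.ids)}
    rows = []
    for peptide in sorted(set(seq)):
        members = [i for i in tree.ids if labels[i] == peptide]
        if len(members) < 2:
            continue
        pairs = [
            coph[index[a], index[b]]
            for k, a in enumerate(members)
            for b in members[k + 1 :]
        ]
        rows.append({
            "peptide": peptide,
            "n_tcrs": len(members),
            "pmhc_distance": float(np.mean(pairs)),
            "n_clusters": cluster_count(tree, labels, peptide),
        })
    if not rows:
        raise ValueError("no peptide has >= 2 labelled TCRs")
    table = pd.DataFrame(rows)
    return float(table["pmhc_distance"].mean()), table


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    p_value: float
    n_permutations: int
    null_values: np.ndarray


def permutation_null(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    statistic: str = "pmhc_distance",
    B: int = 1000,
    seed: int | None = None,
    permute: str = "distances",
    use_normalized: bool = True,
) -> PermutationResult:
    """Null distribution of a clustering statistic under permutation.

    The condensed pairwise distances are shuffled B times (the published
    randomization scheme; ``permute='labels'`` shuffles leaf labels instead
    as a sensitivity check), the tree is rebuilt and the statistic
    recomputed.  Both statistics are lower-is-better, so
    p = (1 + #{null <= observed}) / (B + 1).
    """
    if B < 100:
        raise ValueError("use at least B=100 permutations")
    stats: dict[str, Callable] = {
        "colour_changes": lambda t: float(colour_changes(t, lab)),
        "pmhc_distance": lambda t: pmhc_distance(t, lab)[0],
    }
    if statistic not in stats:
        raise ValueError(f"unknown statistic {statistic!r}")

    lab = dict(labels)
    observed = stats[statistic](upgma(matrix, use_normalized))

    rng = np.random.default_rng(seed)
    null = np.empty(B)
    base = (matrix.normalized if use_normalized else matrix.raw).copy()
    ids = list(matrix.ids)
    for b in range(B):
        if permute == "distances":
            perm = DistanceMatrix(
                ids=matrix.ids, raw=rng.permutation(base), variant=matrix.variant
            )
            lab = dict(labels)
            tree = upgma(perm, use_normalized=False)  # base already on scale
        elif permute == "labels":
            shuffled = rng.permutation([labels[i] for i in ids])
            lab = dict(zip(ids, shuffled))
            tree = upgma(matrix, use_normalized)
        else:
            raise ValueError(f"unknown permutation unit {permute!r}")
        null[b] = stats[statistic](tree)

    lab = dict(labels)
    p = (1 + int(np.sum(null <= observed))) / (B + 1)
    return PermutationResult(
        observed=observed,
        null_mean=float(null.mean()),
        p_value=float(p),
        n_permutations=B,
        null_values=null,
    )
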