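"""Nearest-neighbour specificity prediction and deorphanization.

An orphan receptor inherits the specificity of its nearest labelled
neighbour when their distance falls below a call threshold (default 0.15,
strict).  Confidence is supported by the enrichment factor — how
over-represented the predicted specificity is among the query's ten nearest
references relative to the whole reference repertoire — and by the empirical
distance -> probability-of-sharing curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core import DEFAULT_THRESHOLDS, DistanceMatrix, WeightScheme, pairwise_matrix
from .io import Repertoire, Specificity, TCRRecord

__all__ = [
    "NeighborRanking",
    "DeorphanizationCall",
    "rank_neighbors",
    "topk_success",
    "enrichment_factor",
    "share_probability_curve",
    "peptide_auc",
    "deorphanize",
]


@dataclass
class NeighborRanking:
    """Sorted references for one query (ties broken by reference order)."""

    query_id: str
    neighbors: list[tuple[str, float, str | None]]  # (ref id, distance, label)

    def top(self, k: int) -> list[tuple[str, float, str | None]]:
        return self.neighbors[:k]

    @property
    def nearest(self) -> tuple[str, float, str | None]:
        return self.neighbors[0]


@dataclass
class DeorphanizationCall:
    orphan_id: str
    peptide: str | None
    mhc: str | None
    reference_id: str | None
    distance: float
    enrichment: float | None
    share_probability: float | None
    called: bool


def _combined_matrix(queries: Repertoire, references: Repertoire, variant,
                     weights, thresholds) -> tuple[DistanceMatrix, list[str]]:
    """One matrix over queries + references: shared normalization constant."""
    qids = set(queries.ids)
    overlap = qids & set(references.ids)
    records = list(queries) + [r for r in references if r.id not in qids]
    merged = Repertoire(records, name="combined")
    mat = pairwise_matrix(merged, variant=variant, weights=weights,
                          thresholds=thresholds)
    return mat, sorted(overlap)


def rank_neighbors(
    queries: Repertoire,
    references: Repertoire,
    variant: str = "6cdrs",
    weights: WeightScheme | None = None,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
) -> dict[str, NeighborRanking]:
    """Full sorted reference ranking per query under a shared normalization."""
    if len(references) == 0:
        raise ValueError("empty reference set")
    mat, _ = _combined_matrix(queries, references, variant, weights, thresholds)
    sq = mat.square()
    ref_ids = list(references.ids)
    ref_labels = {r.id: r.label for r in references}
    out = {}
    for q in queries.ids:
        qi = mat.index(q)
        cand = [
            (rid, float(sq[qi, mat.index(rid)]), ref_labels[rid])
            for rid in ref_ids
            if rid != q
        ]
        cand.sort(key=lambda t: t[1])  # stable: ties keep reference input order
        out[q] = NeighborRanking(query_id=q, neighbors=cand)
    return out


def topk_success(
    repertoire: Repertoire,
    variant: str = "6cdrs",
    k: int = 1,
    threshold: float | None = None,
    weights: WeightScheme | None = None,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    matrix: DistanceMatrix | None = None,
) -> tuple[float, float]:
    """Leave-one-out top-k specificity recovery over a labelled repertoire.

    Each receptor queries all the others; success means its own peptide
    appears among its k nearest neighbours.  With a distance threshold only
    queries whose nearest neighbour lies strictly below it are evaluated.
    Returns (success fraction among evaluated queries, evaluated fraction).
    A precomputed matrix for the same repertoire may be passed to avoid
    recomputation across k values.
    """
    labels = repertoire.labels()
    if len(labels) != len(repertoire):
        raise ValueError("topk_success requires every record to be labelled")
    if matrix is None:
        matrix = pairwise_matrix(repertoire, variant=variant, weights=weights,
                                 thresholds=thresholds)
    sq = matrix.square()
    ids = list(matrix.ids)
    evaluated = successes = 0
    for i, q in enumerate(ids):
        order = sorted((j for j in range(len(ids)) if j != i),
                       key=lambda j: sq[i, j])
        if threshold is not None and sq[i, order[0]] >= threshold:
            continue
        evaluated += 1
        if any(labels[ids[j]] == labels[q] for j in order[:k]):
            successes += 1
    if evaluated == 0:
        return 0.0, 0.0
    return successes / evaluated, evaluated / len(ids)


def enrichment_factor(
    ranking: NeighborRanking,
    specificity: str,
    references: Repertoire,
    top_n: int = 10,
) -> float:
    """Top-n frequency of a specificity over its whole-repertoire frequency."""
    ref_count = sum(1 for r in references if r.label == specificity)
    if ref_count == 0:
        raise ValueError(
            f"specificity {specificity!r} absent from the reference repertoire"
        )
    top = ranking.top(top_n)
    top_count = sum(1 for _, _, lab in top if lab == specificity)
    return (top_count / len(top)) / (ref_count / len(references))


def share_probability_curve(
    repertoire: Repertoire,
    variant: str = "6cdrs",
    bins: int | Sequence[float] = 10,
    weights: WeightScheme | None = None,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    matrix: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """P(two receptors share a peptide) per normalized-distance bin.

    Bins with no pairs are reported with NaN probability, not zero.  The
    first bin is closed on the left so exact-zero distances are counted.
    """
    labels = repertoire.labels()
    if len(set(labels.values())) < 2:
        raise ValueError("need at least 2 distinct labels")
    if matrix is None:
        matrix = pairwise_matrix(repertoire, variant=variant, weights=weights,
                                 thresholds=thresholds)
    edges = (np.linspace(0.0, 1.0, bins + 1) if np.isscalar(bins)
             else np.asarray(bins, dtype=float))
    dist = matrix.normalized
    ids = list(matrix.ids)
    n = len(ids)
    share = np.array([
        labels[ids[i]] == labels[ids[j]]
        for i in range(n) for j in range(i + 1, n)
    ])
    which = np.digitize(dist, edges[1:-1], right=False)
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        rows.append({
            "bin_left": edges[b],
            "bin_right": edges[b + 1],
            "n_pairs": int(mask.sum()),
            "share_probability": float(share[mask].mean()) if mask.any() else np.nan,
        })
    out = pd.DataFrame(rows)
    out.attrs["base_rate"] = float(share.mean())
    return out


def peptide_auc(
    repertoire: Repertoire,
    peptide: str,
    variant: str = "6cdrs",
    n_splits: int = 6,
    reference_fraction: float = 0.30,
    seed: int | None = None,
    min_tcrs: int = 20,
    allow_small: bool = False,
    weights: WeightScheme | None = None,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    matrix: DistanceMatrix | None = None,
) -> tuple[float, float]:
    """Cross-validated nearest-reference AUC for one peptide.

    Per split, a random ``reference_fraction`` of the peptide's receptors is
    held out as the reference panel; every remaining receptor is scored by
    minus its distance to the nearest reference, and the ROC over that score
    (positives = remaining receptors of the peptide) gives the AUC.  Returns
    the mean and standard deviation over ``n_splits`` splits.
    """
    labels = repertoire.labels()
    members = [i for i in repertoire.ids if labels.get(i) == peptide]
    if len(members) < min_tcrs and not allow_small:
        raise ValueError(
            f"peptide {peptide!r} has {len(members)} TCRs (< {min_tcrs}); "
            "pass allow_small=True to override"
        )
    if len(members) < 2:
        raise ValueError(f"peptide {peptide!r} needs >= 2 specific TCRs")
    if matrix is None:
        matrix = pairwise_matrix(repertoire, variant=variant, weights=weights,
                                 thresholds=thresholds)
    sq = matrix.square()
    idx = {tid: i for i, tid in enumerate(matrix.ids)}
    rng = np.random.default_rng(seed)
    n_ref = max(1, int(round(reference_fraction * len(members))))

    aucs = []
    for _ in range(n_splits):
        ref = list(rng.choice(members, size=n_ref, replace=False))
        rest = [i for i in repertoire.ids if i not in set(ref)]
        y = np.array([labels[i] == peptide for i in rest])
        if y.sum() < 2 or y.all():
            continue  # degenerate split: too few positives or no negatives
        ref_idx = [idx[r] for r in ref]
        scores = np.array([-sq[idx[i], ref_idx].min() for i in rest])
        aucs.append(roc_auc_score(y, scores))
    if not aucs:
        raise ValueError("no usable split had >= 2 positives")
    return float(np.mean(aucs)), float(np.std(aucs))


def deorphanize(
    orphans: Repertoire,
    references: Repertoire,
    variant: str = "6cdrs",
    call_threshold: float = 0.15,
    weights: WeightScheme | None = None,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    curve: pd.DataFrame | None = None,
) -> list[DeorphanizationCall]:
    """Call a specificity for every orphan whose NN distance is < threshold.

    Orphans at or above the threshold are reported as no-calls (``called``
    False) with their nearest distance, never dropped.  An optional share
    probability curve (from ``share_probability_curve``) attaches the
    empirical probability band for each call distance.
    """
    rankings = rank_neighbors(orphans, references, variant=variant,
                              weights=weights, thresholds=thresholds)
    ref_specs = {r.id: r.specificity for r in references}
    calls = []
    for oid in orphans.ids:
        ranking = rankings[oid]
        rid, dist, lab = ranking.nearest
        called = dist < call_threshold
        prob = None
        if curve is not None:
            row = curve[(curve["bin_left"] <= dist) & (dist <= curve["bin_right"])]
            if len(row):
                prob = float(row.iloc[0]["share_probability"])
        ef = None
        if called and lab is not None:
            ef = enrichment_factor(ranking, lab, references)
        spec = ref_specs.get(rid) if called else None
        calls.append(DeorphanizationCall(
            orphan_id=oid,
            peptide=lab if called else None,
            mhc=spec.mhc if (called and spec) else None,
            reference_id=rid if called else None,
            distance=dist,
            enrichment=ef,
            share_probability=prob,
            called=called,
        ))
    return calls
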