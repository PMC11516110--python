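"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive everything with plain nested loops
and textbook algorithms so they stay independent of the vectorized library
code they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from tcrpcdist import (
    ATCHLEY,
    LOOPS,
    Repertoire,
    Specificity,
    TCRRecord,
    table4_fixtures,
)


def make_record(rid, cdr3a="CAVSDLEPNSSASKIIF", cdr3b="CASSEPGYEQYF",
                cdr1a="TSGFNG", cdr2a="NVLDGL", cdr1b="SNHLY", cdr2b="FYNNEI",
                peptide=None, nsesa=None):
    return TCRRecord(
        id=rid,
        cdr={"CDR1a": cdr1a, "CDR2a": cdr2a, "CDR3a": cdr3a,
             "CDR1b": cdr1b, "CDR2b": cdr2b, "CDR3b": cdr3b},
        specificity=Specificity(peptide) if peptide else None,
        nsesa=nsesa,
    )


def all_exposed_profile(record):
    """An nSESA profile keeping every residue (100% exposure)."""
    return {loop: [100.0] * len(seq) for loop, seq in record.cdr.items()}


def random_repertoire(rng, n, peptides=None):
    """Small random repertoire with fully random CDR3s."""
    aa = list(ATCHLEY.letters)
    recs = []
    for i in range(n):
        c3a = "C" + "".join(rng.choice(aa, size=int(rng.integers(9, 15)))) + "F"
        c3b = "C" + "".join(rng.choice(aa, size=int(rng.integers(9, 15)))) + "F"
        pep = peptides[i % len(peptides)] if peptides else None
        recs.append(make_record(f"T{i:02d}", cdr3a=c3a, cdr3b=c3b, peptide=pep))
    return Repertoire(recs, name="random")


# ---------------------------------------------------------------- oracles

def oracle_max_pair() -> float:
    best = 0.0
    for a in ATCHLEY.letters:
        for b in ATCHLEY.letters:
            s = sum(abs(x - y) for x, y in zip(ATCHLEY[a], ATCHLEY[b]))
            best = max(best, s)
    return best


def oracle_windows(seq, loop, mode, nsesa=None, thresholds=None):
    """Straight-loop re-derivation of admissible residue subsequences."""
    from tcrpcdist.core import DEFAULT_THRESHOLDS

    thresholds = thresholds or DEFAULT_THRESHOLDS
    if mode == "cdr3_trimmed" and loop.startswith("CDR3") and len(seq) >= 11:
        kept = seq[4:-3]
    elif mode == "exposed":
        kept = "".join(s for s, v in zip(seq, nsesa) if v > thresholds[loop])
        if len(kept) < 4:
            kept = seq
    else:
        kept = seq
    k = min(4, len(kept))
    return [kept[i:i + k] for i in range(len(kept) - k + 1)], k


def oracle_cdr_distance(seq1, seq2, loop, mode, nsesa1=None, nsesa2=None):
    w1, k1 = oracle_windows(seq1, loop, mode, nsesa1)
    w2, k2 = oracle_windows(seq2, loop, mode, nsesa2)
    k = min(k1, k2)
    if k < k1:
        w1 = sorted({w[i:i + k] for w in w1 for i in range(len(w) - k + 1)})
    if k < k2:
        w2 = sorted({w[i:i + k] for w in w2 for i in range(len(w) - k + 1)})
    best = None
    for a in w1:
        for b in w2:
            d = sum(
                abs(x - y)
                for ra, rb in zip(a, b)
                for x, y in zip(ATCHLEY[ra], ATCHLEY[rb])
            )
            best = d if best is None else min(best, d)
    return best / (k * oracle_max_pair())


def oracle_tcr_distance(r1, r2, variant="6cdrs"):
    weights = ({"CDR3b": 1.0} if variant == "cdr3b" else
               {"CDR1a": 0.1, "CDR2a": 0.1, "CDR3a": 0.3,
                "CDR1b": 0.1, "CDR2b": 0.1, "CDR3b": 0.3})
    total = 0.0
    for loop, w in weights.items():
        if variant == "3d":
            mode, n1, n2 = "exposed", r1.nsesa[loop], r2.nsesa[loop]
        else:
            mode, n1, n2 = ("cdr3_trimmed" if loop.startswith("CDR3")
                            else "full"), None, None
        total += w * oracle_cdr_distance(r1.cdr[loop], r2.cdr[loop], loop,
                                         mode, n1, n2)
    return total


def oracle_upgma_cophenetic(square):
    """Textbook UPGMA; returns the square cophenetic matrix."""
    n = square.shape[0]
    active = {i: [i] for i in range(n)}
    coph = np.zeros_like(square)
    next_id = n

    def cluster_dist(a, b):
        # UPGMA distance == mean over all original member pairs
        return float(np.mean([square[p, q] for p in active[a] for q in active[b]]))

    while len(active) > 1:
        ids = sorted(active)
        pairs = {(ids[x], ids[y]): cluster_dist(ids[x], ids[y])
                 for x in range(len(ids)) for y in range(x + 1, len(ids))}
        (i, j), dmin = min(pairs.items(), key=lambda kv: (kv[1], kv[0]))
        for a in active[i]:
            for b in active[j]:
                coph[a, b] = coph[b, a] = dmin
        active[next_id] = active.pop(i) + active.pop(j)
        next_id += 1
    return coph


@pytest.fixture(scope="session")
def table4():
    return table4_fixtures()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240819)
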