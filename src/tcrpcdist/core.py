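"""Physicochemical TCR distance core.

The metric compares two TCRs loop by loop.  Each CDR loop is decomposed into
sliding 4-mer windows (all consecutive windows, trimmed windows for CDR3 in
the sequence-only variants, or windows over the solvent-exposed residues in
the 3D variant).  Every window is encoded as a 4x5 matrix of Atchley factors
and two windows are compared with the Manhattan distance between their
matrices.  The distance between two loops is the minimum over all n x m
window pairs, normalized by the maximum Manhattan distance attainable by any
window pair of that length, so per-loop scores lie in [0, 1].  The distance
between two TCRs is the weighted sum over active loops (weights 0.1 for
CDR1/CDR2 and 0.3 for CDR3 by default).  Across a repertoire, pairwise
distances are finally rescaled by the largest observed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist, squareform

__all__ = [
    "LOOPS",
    "AtchleyTable",
    "ATCHLEY",
    "FourmerEncoding",
    "WindowSet",
    "WeightScheme",
    "DistanceMatrix",
    "DEFAULT_WEIGHTS",
    "CDR3B_WEIGHTS",
    "DEFAULT_THRESHOLDS",
    "VARIANTS",
    "extract_windows",
    "fourmer_distance",
    "cdr_distance",
    "tcr_distance",
    "pairwise_matrix",
]

#: Canonical loop names, alpha chain first.
LOOPS = ("CDR1a", "CDR2a", "CDR3a", "CDR1b", "CDR2b", "CDR3b")

#: Distance variants exposed to users.
VARIANTS = ("cdr3b", "6cdrs", "3d")

#: Default loop weights: 10% per CDR1/CDR2, 30% per CDR3.
DEFAULT_WEIGHTS: Mapping[str, float] = {
    "CDR1a": 0.1, "CDR2a": 0.1, "CDR3a": 0.3,
    "CDR1b": 0.1, "CDR2b": 0.1, "CDR3b": 0.3,
}

#: Single-loop scheme used by the CDR3beta-only variant.
CDR3B_WEIGHTS: Mapping[str, float] = {"CDR3b": 1.0}

#: nSESA retention thresholds (percent); residues must be strictly above.
DEFAULT_THRESHOLDS: Mapping[str, float] = {
    "CDR1a": 5.0, "CDR2a": 5.0, "CDR3a": 20.0,
    "CDR1b": 5.0, "CDR2b": 5.0, "CDR3b": 20.0,
}


class AtchleyTable:
    """The five published Atchley factor values for the 20 standard residues.

    Factors: H (polarity/hydrophobicity), SS (secondary structure), SM
    (size/mass), CD (codon degeneracy), ES (electrostatic charge).  The table
    is immutable; ``max_pair_sum`` is the largest possible sum of absolute
    factor differences between any two residues, the per-position
    normalization constant of the window distance.
    """

    FACTORS = ("H", "SS", "SM", "CD", "ES")

    def __init__(self, values: Mapping[str, Sequence[float]]):
        if len(values) != 20:
            raise ValueError(f"expected 20 amino acids, got {len(values)}")
        self._values = {aa: np.asarray(v, dtype=float) for aa, v in values.items()}
        for aa, v in self._values.items():
            if v.shape != (5,) or not np.all(np.isfinite(v)):
                raise ValueError(f"bad factor vector for {aa!r}")
        mat = np.stack([self._values[aa] for aa in sorted(self._values)])
        self.max_pair_sum = float(
            np.abs(mat[:, None, :] - mat[None, :, :]).sum(axis=2).max()
        )

    @classmethod
    def load(cls) -> "AtchleyTable":
        values: dict[str, list[float]] = {}
        text = resources.files("tcrpcdist.data").joinpath("atchley_factors.tsv").read_text()
        for line in text.splitlines():
            if not line or line.startswith("#") or line.startswith("aa\t"):
                continue
            parts = line.split("\t")
            values[parts[0]] = [float(x) for x in parts[1:6]]
        return cls(values)

    def __contains__(self, aa: str) -> bool:
        return aa in self._values

    def __getitem__(self, aa: str) -> np.ndarray:
        try:
            return self._values[aa]
        except KeyError:
            raise ValueError(f"residue {aa!r} is not a standard amino acid") from None

    @property
    def letters(self) -> tuple[str, ...]:
        return tuple(sorted(self._values))

    def encode(self, seq: str) -> np.ndarray:
        """Encode a peptide string as a (len, 5) factor matrix."""
        return np.stack([self[aa] for aa in seq])


#: Module-level singleton; the table is static data.
ATCHLEY = AtchleyTable.load()


@dataclass(frozen=True)
class FourmerEncoding:
    """One window: its residues, 1-based source positions and factor matrix."""

    residues: str
    positions: tuple[int, ...]
    matrix: np.ndarray

    def __post_init__(self):
        if len(self.residues) != len(self.positions):
            raise ValueError("residues/positions length mismatch")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("window positions must be strictly increasing")


@dataclass
class WindowSet:
    """All admissible windows of one CDR loop under one extraction mode.

    ``residues``/``positions`` hold the admissible residue subsequence (the
    whole loop, the trimmed CDR3 interior, or the solvent-exposed residues in
    original order); windows are every consecutive run of ``k`` residues of
    that subsequence, so exposed-mode windows may span non-consecutive
    sequence positions.  ``k`` is 4 unless the loop itself is shorter.
    ``fallback`` records that the trimming/exposure rule left fewer than 4
    residues and the full loop was used instead.
    """

    loop: str
    mode: str
    residues: str
    positions: tuple[int, ...]
    k: int
    fallback: bool = False
    _stack: np.ndarray | None = field(default=None, repr=False)

    @property
    def windows(self) -> list[FourmerEncoding]:
        enc = ATCHLEY.encode(self.residues)
        return [
            FourmerEncoding(
                self.residues[i : i + self.k],
                self.positions[i : i + self.k],
                enc[i : i + self.k],
            )
            for i in range(len(self.residues) - self.k + 1)
        ]

    def stack(self, k: int | None = None) -> np.ndarray:
        """(n_windows, k*5) matrix of flattened window encodings."""
        k = self.k if k is None else k
        if k == self.k and self._stack is not None:
            return self._stack
        enc = ATCHLEY.encode(self.residues)
        n = len(self.residues) - k + 1
        out = np.stack([enc[i : i + k].ravel() for i in range(n)])
        if k == self.k:
            self._stack = out
        return out


@dataclass(frozen=True)
class WeightScheme:
    """Per-loop weights; renormalized to sum 1 over the active loops."""

    weights: Mapping[str, float]

    def __post_init__(self):
        bad = set(self.weights) - set(LOOPS)
        if bad:
            raise ValueError(f"unknown loops in weight scheme: {sorted(bad)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if sum(self.weights.values()) <= 0:
            raise ValueError("at least one positive weight required")

    @property
    def active_loops(self) -> tuple[str, ...]:
        return tuple(l for l in LOOPS if self.weights.get(l, 0.0) > 0)

    def normalized(self) -> dict[str, float]:
        total = sum(self.weights[l] for l in self.active_loops)
        return {l: self.weights[l] / total for l in self.active_loops}


def _is_cdr3(loop: str) -> bool:
    return loop.startswith("CDR3")


def extract_windows(
    cdr: str,
    loop: str,
    mode: str = "full",
    nsesa: Sequence[float] | None = None,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
) -> WindowSet:
    """Extract the admissible windows of one loop.

    Modes: ``full`` keeps every residue; ``cdr3_trimmed`` drops the first 4
    and last 3 residues (CDR3 loops only; other loops are kept whole);
    ``exposed`` keeps residues whose nSESA strictly exceeds the loop
    threshold.  If trimming/filtering leaves fewer than 4 residues the whole
    loop is used and the fallback flag is set; loops shorter than 4 residues
    yield a single window of the loop length.
    """
    if loop not in LOOPS:
        raise ValueError(f"unknown loop {loop!r}")
    if not cdr:
        raise ValueError(f"empty CDR sequence for {loop}")
    for aa in cdr:
        if aa not in ATCHLEY:
            raise ValueError(f"residue {aa!r} in {loop} is not a standard amino acid")

    fallback = False
    if mode == "full":
        residues, positions = cdr, tuple(range(1, len(cdr) + 1))
    elif mode == "cdr3_trimmed":
        if _is_cdr3(loop) and len(cdr) - 7 >= 4:
            residues = cdr[4 : len(cdr) - 3]
            positions = tuple(range(5, len(cdr) - 2))
        else:
            fallback = _is_cdr3(loop)
            residues, positions = cdr, tuple(range(1, len(cdr) + 1))
    elif mode == "exposed":
        if nsesa is None:
            raise ValueError(f"mode='exposed' requires an nSESA profile for {loop}")
        if len(nsesa) != len(cdr):
            raise ValueError(
                f"nSESA profile length {len(nsesa)} != loop length {len(cdr)} for {loop}"
            )
        thr = thresholds[loop]
        kept = [i for i, v in enumerate(nsesa) if v > thr]
        if len(kept) >= 4:
            residues = "".join(cdr[i] for i in kept)
            positions = tuple(i + 1 for i in kept)
        else:
            fallback = True
            residues, positions = cdr, tuple(range(1, len(cdr) + 1))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    k = min(4, len(residues))
    return WindowSet(loop=loop, mode=mode, residues=residues,
                     positions=positions, k=k, fallback=fallback)


def fourmer_distance(a: FourmerEncoding, b: FourmerEncoding) -> float:
    """Raw Manhattan distance between two window factor matrices."""
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("windows have different lengths")
    return float(np.abs(a.matrix - b.matrix).sum())


def max_window_distance(k: int = 4) -> float:
    """Largest Manhattan distance attainable between two length-k windows."""
    return k * ATCHLEY.max_pair_sum


def cdr_distance(wa: WindowSet, wb: WindowSet) -> float:
    """Normalized minimum window distance between two loops, in [0, 1].

    The minimum over all window pairs of the Manhattan matrix distance,
    divided by the maximum distance attainable by a window pair of the
    common length.  When the two sets carry windows of different lengths
    (one loop shorter than 4 residues) both are re-windowed at the shorter
    length before comparison.
    """
    k = min(wa.k, wb.k)
    da = cdist(wa.stack(k), wb.stack(k), metric="cityblock")
    return float(da.min()) / max_window_distance(k)


def _loop_mode(loop: str, variant: str) -> str:
    if variant == "3d":
        return "exposed"
    if variant in ("cdr3b", "6cdrs"):
        return "cdr3_trimmed" if _is_cdr3(loop) else "full"
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def _record_windows(record, variant, weights, thresholds, trim_cdr3=True):
    """WindowSets for every active loop of one record."""
    out = {}
    for loop in weights.active_loops:
        cdr = (record.cdr or {}).get(loop)
        if not cdr:
            raise ValueError(f"record {record.id!r} is missing loop {loop}")
        mode = _loop_mode(loop, variant)
        if mode == "cdr3_trimmed" and not trim_cdr3:
            mode = "full"
        nsesa = None
        if mode == "exposed":
            nsesa = (record.nsesa or {}).get(loop)
            if nsesa is None:
                raise ValueError(
                    f"variant '3d' requires an nSESA profile for loop {loop} "
                    f"of record {record.id!r}"
                )
        out[loop] = extract_windows(cdr, loop, mode, nsesa=nsesa, thresholds=thresholds)
    return out


def tcr_distance(
    t1,
    t2,
    variant: str = "6cdrs",
    weights: WeightScheme | None = None,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    trim_cdr3: bool = True,
) -> float:
    """Weighted sum of per-loop distances between two TCR records."""
    weights = weights or _default_scheme(variant)
    w = weights.normalized()
    wins1 = _record_windows(t1, variant, weights, thresholds, trim_cdr3)
    wins2 = _record_windows(t2, variant, weights, thresholds, trim_cdr3)
    return sum(w[l] * cdr_distance(wins1[l], wins2[l]) for l in weights.active_loops)


def _default_scheme(variant: str) -> WeightScheme:
    if variant == "cdr3b":
        return WeightScheme(CDR3B_WEIGHTS)
    return WeightScheme(DEFAULT_WEIGHTS)


@dataclass
class DistanceMatrix:
    """Pairwise TCR distances of one repertoire.

    ``raw`` holds the condensed weighted per-pair distances (already on the
    [0, 1] per-comparison scale); ``normalized`` divides them by the largest
    observed value (``norm_const``), the repertoire-level rescaling.  If all
    raw distances are zero the normalization constant is reported as 0 and
    the normalized distances are all zero.
    """

    ids: tuple[str, ...]
    raw: np.ndarray
    variant: str

    def __post_init__(self):
        n = len(self.ids)
        if len(self.raw) != n * (n - 1) // 2:
            raise ValueError("condensed length does not match id count")
        if np.any(self.raw < 0) or not np.all(np.isfinite(self.raw)):
            raise ValueError("raw distances must be finite and non-negative")

    @property
    def norm_const(self) -> float:
        return float(self.raw.max()) if len(self.raw) else 0.0

    @property
    def normalized(self) -> np.ndarray:
        c = self.norm_const
        return self.raw / c if c > 0 else np.zeros_like(self.raw)

    def square(self, normalized: bool = True) -> np.ndarray:
        vec = self.normalized if normalized else self.raw
        return squareform(vec)

    def index(self, tcr_id: str) -> int:
        return self.ids.index(tcr_id)

    def get(self, id1: str, id2: str, normalized: bool = True) -> float:
        if id1 == id2:
            return 0.0
        return float(self.square(normalized)[self.index(id1), self.index(id2)])


def pairwise_matrix(
    repertoire,
    variant: str = "6cdrs",
    weights: WeightScheme | None = None,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    trim_cdr3: bool = True,
) -> DistanceMatrix:
    """Condensed pairwise distance matrix over a repertoire (>= 2 records)."""
    records = list(repertoire)
    if len(records) < 2:
        raise ValueError("need at least 2 records for a pairwise matrix")
    weights = weights or _default_scheme(variant)
    w = weights.normalized()

    windows = []
    for rec in records:
        try:
            windows.append(_record_windows(rec, variant, weights, thresholds, trim_cdr3))
        except ValueError as err:
            raise ValueError(f"cannot window record {rec.id!r}: {err}") from err

    n = len(records)
    raw = np.zeros(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                raw[idx] = sum(
                    w[l] * cdr_distance(windows[i][l], windows[j][l])
                    for l in weights.active_loops
                )
            except ValueError as err:
                raise ValueError(
                    f"distance failed for pair ({records[i].id!r}, "
                    f"{records[j].id!r}): {err}"
                ) from err
            idx += 1

    ids = tuple(rec.id for rec in records)
    return DistanceMatrix(ids=ids, raw=raw, variant=variant)
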