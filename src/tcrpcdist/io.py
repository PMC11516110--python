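"""Repertoire, nSESA-profile and lookup-table I/O.

Repertoires are plain TSV tables with one receptor per row (columns: id,
patient, trav, traj, trbv, trbj, cdr1a, cdr2a, cdr3a, cdr1b, cdr2b, cdr3b,
peptide, mhc).  CDR1/CDR2 may be omitted and resolved from the V-gene names
through a lookup table; rows that cannot be resolved are collected into a
rejection report rather than dropped silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .core import ATCHLEY, LOOPS, DistanceMatrix

__all__ = [
    "Specificity",
    "TCRRecord",
    "Repertoire",
    "VGeneLookup",
    "load_default_vgene_lookup",
    "read_vgene_lookup",
    "read_repertoire",
    "write_repertoire",
    "read_nsesa",
    "attach_nsesa",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_newick",
]

_CDR_COLUMNS = {
    "CDR1a": "cdr1a", "CDR2a": "cdr2a", "CDR3a": "cdr3a",
    "CDR1b": "cdr1b", "CDR2b": "cdr2b", "CDR3b": "cdr3b",
}


class Specificity(NamedTuple):
    peptide: str
    mhc: str | None = None


@dataclass
class TCRRecord:
    """One alpha/beta receptor: genes, CDR loops, optional label and nSESA."""

    id: str
    patient: str | None = None
    trav: str | None = None
    traj: str | None = None
    trbv: str | None = None
    trbj: str | None = None
    cdr: dict[str, str] = field(default_factory=dict)
    specificity: Specificity | None = None
    nsesa: dict[str, list[float]] | None = None

    def __post_init__(self):
        for loop, seq in self.cdr.items():
            if loop not in LOOPS:
                raise ValueError(f"unknown loop {loop!r} on record {self.id!r}")
            for aa in seq:
                if aa not in ATCHLEY:
                    raise ValueError(
                        f"record {self.id!r}, loop {loop}: residue {aa!r} is not "
                        "a standard amino acid"
                    )
        if self.nsesa:
            for loop, vals in self.nsesa.items():
                seq = self.cdr.get(loop)
                if seq is not None and len(vals) != len(seq):
                    raise ValueError(
                        f"record {self.id!r}, loop {loop}: nSESA length "
                        f"{len(vals)} != sequence length {len(seq)}"
                    )
                if any(v < 0 or v > 100 for v in vals):
                    raise ValueError(
                        f"record {self.id!r}, loop {loop}: nSESA out of [0, 100]"
                    )

    @property
    def label(self) -> str | None:
        return self.specificity.peptide if self.specificity else None


@dataclass
class Repertoire:
    """An ordered collection of TCR records with unique ids.

    Input order is preserved; it drives reproducible tie-breaking in
    clustering and neighbour ranking.  ``rejected`` carries (row id, reason)
    pairs for rows that could not be turned into records.
    """

    records: list[TCRRecord]
    name: str = "repertoire"
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    def __iter__(self) -> Iterator[TCRRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, tcr_id: str) -> TCRRecord:
        for rec in self.records:
            if rec.id == tcr_id:
                return rec
        raise KeyError(tcr_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def labels(self) -> dict[str, str]:
        """id -> peptide label for every labelled record."""
        return {r.id: r.label for r in self.records if r.label is not None}

    def subset(self, ids, name: str | None = None) -> "Repertoire":
        wanted = set(ids)
        return Repertoire(
            [r for r in self.records if r.id in wanted],
            name=name or self.name,
        )


def normalize_gene_name(name: str) -> str:
    """Strip whitespace and allele suffixes ('*01'); keep '/DV' names verbatim."""
    return re.sub(r"\*\w+$", "", name.strip())


@dataclass
class VGeneLookup:
    """V-gene name -> (CDR1, CDR2) germline loop sequences."""

    table: Mapping[str, tuple[str, str]]
    species: str = "human"

    def __post_init__(self):
        self.table = {normalize_gene_name(g): v for g, v in self.table.items()}
        for gene, (c1, c2) in self.table.items():
            for aa in c1 + c2:
                if aa not in ATCHLEY:
                    raise ValueError(f"non-standard residue in lookup entry {gene!r}")

    def __contains__(self, gene: str) -> bool:
        return normalize_gene_name(gene) in self.table

    def resolve(self, gene: str) -> tuple[str, str]:
        key = normalize_gene_name(gene)
        if key not in self.table:
            raise KeyError(f"V gene {gene!r} not in lookup table")
        return self.table[key]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.table))


def read_vgene_lookup(path, species: str = "human") -> VGeneLookup:
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, c1, c2 = line.split("\t")[:3]
            table[gene] = (c1, c2)
    return VGeneLookup(table, species=species)


def load_default_vgene_lookup() -> VGeneLookup:
    """Bundled synthetic stand-in lookup (see the data file header).

    The sequences are plausible IMGT-style CDR1/CDR2 loops, not an
    authoritative IMGT export; override with ``read_vgene_lookup`` for
    production analyses.
    """
    with resources.as_file(
        resources.files("tcrpcdist.data").joinpath("vgene_cdrs_synthetic.tsv")
    ) as p:
        return read_vgene_lookup(p)


def read_tsv(path) -> pd.DataFrame:
    """TSV reader skipping full-line '#' comments ('#' is legal inside fields)."""
    import io as _io

    with open(path) as fh:
        text = "".join(l for l in fh if not l.startswith("#"))
    return pd.read_csv(_io.StringIO(text), sep="\t", dtype=str)


def _cell(row, col) -> str | None:
    val = row.get(col)
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return None
    val = str(val).strip()
    return val or None


def read_repertoire(path, lookup: VGeneLookup | None = None,
                    name: str | None = None) -> Repertoire:
    """Read a repertoire TSV; resolve CDR1/2 from V genes where absent."""
    df = read_tsv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "id" not in df.columns:
        raise ValueError("repertoire TSV must have an 'id' column")
    for col in ("cdr3a", "cdr3b"):
        if col not in df.columns:
            raise ValueError(f"repertoire TSV is missing the required {col} column")

    records, rejected = [], []
    for _, row in df.iterrows():
        rid = _cell(row, "id")
        try:
            cdr = {}
            for loop, col in _CDR_COLUMNS.items():
                seq = _cell(row, col) if col in df.columns else None
                if seq is None and loop[-1] in "ab" and loop.startswith(("CDR1", "CDR2")):
                    gene = _cell(row, "trav" if loop.endswith("a") else "trbv")
                    if gene is not None and lookup is not None:
                        try:
                            c1, c2 = lookup.resolve(gene)
                        except KeyError as err:
                            raise ValueError(str(err)) from None
                        seq = c1 if loop.startswith("CDR1") else c2
                if seq is not None:
                    cdr[loop] = seq
            spec = None
            peptide = _cell(row, "peptide")
            if peptide is not None:
                spec = Specificity(peptide, _cell(row, "mhc"))
            records.append(TCRRecord(
                id=rid,
                patient=_cell(row, "patient"),
                trav=_cell(row, "trav"), traj=_cell(row, "traj"),
                trbv=_cell(row, "trbv"), trbj=_cell(row, "trbj"),
                cdr=cdr, specificity=spec,
            ))
        except ValueError as err:
            rejected.append((rid if rid else "<missing id>", str(err)))

    import os
    rep_name = name or os.path.splitext(os.path.basename(str(path)))[0]
    return Repertoire(records, name=rep_name, rejected=rejected)


def write_repertoire(repertoire: Repertoire, path) -> None:
    rows = []
    for r in repertoire:
        rows.append({
            "id": r.id, "patient": r.patient,
            "trav": r.trav, "traj": r.traj, "trbv": r.trbv, "trbj": r.trbj,
            **{col: r.cdr.get(loop) for loop, col in _CDR_COLUMNS.items()},
            "peptide": r.specificity.peptide if r.specificity else None,
            "mhc": r.specificity.mhc if r.specificity else None,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_nsesa(path) -> dict[str, dict[str, list[tuple[str, float]]]]:
    """Read per-residue nSESA profiles.

    TSV columns: tcr_id, loop, residue_index (1-based), residue,
    nsesa_percent.  Returns id -> loop -> ordered (residue, value) list.
    """
    df = read_tsv(path)
    required = {"tcr_id", "loop", "residue_index", "residue", "nsesa_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"nSESA TSV is missing columns: {sorted(missing)}")
    profiles: dict[str, dict[str, list[tuple[int, str, float]]]] = {}
    for _, row in df.iterrows():
        val = float(row["nsesa_percent"])
        if val < 0 or val > 100:
            raise ValueError(
                f"nSESA {val} out of [0, 100] for {row['tcr_id']}/{row['loop']}"
                f" index {row['residue_index']}"
            )
        loop = row["loop"]
        if loop not in LOOPS:
            raise ValueError(f"unknown loop {loop!r} in nSESA file")
        profiles.setdefault(row["tcr_id"], {}).setdefault(loop, []).append(
            (int(row["residue_index"]), str(row["residue"]), val)
        )
    out: dict[str, dict[str, list[tuple[str, float]]]] = {}
    for tid, loops in profiles.items():
        out[tid] = {}
        for loop, entries in loops.items():
            entries.sort(key=lambda e: e[0])
            idxs = [e[0] for e in entries]
            if idxs != list(range(1, len(idxs) + 1)):
                raise ValueError(
                    f"non-contiguous residue indices for {tid}/{loop}: {idxs}"
                )
            out[tid][loop] = [(res, val) for _, res, val in entries]
    return out


def attach_nsesa(repertoire: Repertoire, profiles) -> None:
    """Attach parsed nSESA profiles to records, validating residue letters."""
    for rec in repertoire:
        prof = profiles.get(rec.id)
        if prof is None:
            continue
        nsesa: dict[str, list[float]] = {}
        for loop, entries in prof.items():
            seq = rec.cdr.get(loop)
            if seq is None:
                continue
            if len(entries) != len(seq):
                raise ValueError(
                    f"record {rec.id!r}, loop {loop}: profile has {len(entries)}"
                    f" residues, sequence has {len(seq)}"
                )
            for i, ((res, _), aa) in enumerate(zip(entries, seq), start=1):
                if res != aa:
                    raise ValueError(
                        f"record {rec.id!r}, loop {loop}: residue mismatch at "
                        f"index {i} (profile {res!r} vs sequence {aa!r})"
                    )
            nsesa[loop] = [val for _, val in entries]
        rec.nsesa = nsesa or None


def write_distance_matrix(matrix: DistanceMatrix, path,
                          normalized: bool = True) -> None:
    """Square TSV grid with an id header row and column; zero diagonal."""
    df = pd.DataFrame(matrix.square(normalized=normalized),
                      index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_distance_matrix(path, variant: str = "6cdrs") -> DistanceMatrix:
    import io as _io

    from scipy.spatial.distance import squareform

    with open(path) as fh:
        text = "".join(l for l in fh if not l.startswith("#"))
    df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0)
    sq = df.to_numpy(dtype=float)
    if not np.allclose(sq, sq.T, atol=1e-9) or not np.allclose(np.diag(sq), 0):
        raise ValueError("distance matrix TSV is not symmetric with zero diagonal")
    sq = (sq + sq.T) / 2
    np.fill_diagonal(sq, 0.0)
    return DistanceMatrix(ids=tuple(str(i) for i in df.index),
                          raw=squareform(sq, checks=False), variant=variant)


def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")
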