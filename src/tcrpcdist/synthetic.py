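"""Synthetic labelled repertoires with controllable cluster structure.

The generator emulates the shape of real specificity-annotated repertoires:
a handful of specificity groups, each derived from a seed receptor by a
small number of CDR3 point substitutions, plus unrelated singletons, with
optional per-residue solvent-exposure profiles.  It deliberately does not
model V(D)J recombination, indels or biased amino-acid usage — it provides
ground-truth cluster structure for testing the distance, clustering and
prediction stages.  The in-print orphan/reference pairs from the four
deorphanization rounds are also packaged here as a fixture repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import ATCHLEY, DEFAULT_THRESHOLDS, LOOPS
from .io import Repertoire, Specificity, TCRRecord, load_default_vgene_lookup

__all__ = ["GeneratorConfig", "generate_repertoire", "table4_fixtures"]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic repertoire.

    Defaults: 8 specificity groups of 5 receptors each, derived from their
    seed by 2 CDR3 substitutions per chain, plus 10 singletons; CDR3 lengths
    12-16 with the conserved C...F motif; 30% of loop residues buried in the
    exposure model.
    """

    n_specificities: int = 8
    tcrs_per_specificity: tuple[int, int] = (5, 5)
    n_singletons: int = 10
    cdr3_length: tuple[int, int] = (12, 16)
    substitutions: tuple[int, int] = (2, 2)
    buried_fraction: float = 0.30
    with_nsesa: bool = False
    seed: int | None = None

    def __post_init__(self):
        if min(self.n_specificities, self.n_singletons) < 0:
            raise ValueError("counts must be non-negative")
        if self.tcrs_per_specificity[0] > self.tcrs_per_specificity[1]:
            raise ValueError("bad tcrs_per_specificity range")
        if self.substitutions[1] >= self.cdr3_length[0]:
            raise ValueError("substitutions must be fewer than the CDR3 length")
        if not 0.0 <= self.buried_fraction <= 1.0:
            raise ValueError("buried_fraction must lie in [0, 1]")


_AA = None


def _alphabet():
    global _AA
    if _AA is None:
        _AA = list(ATCHLEY.letters)
    return _AA


def _random_cdr3(rng, length: int) -> str:
    """C + random interior + F, the conserved junctional motif."""
    inner = rng.choice(_alphabet(), size=length - 2)
    return "C" + "".join(inner) + "F"


def _substitute(rng, cdr3: str, n_subs: int) -> str:
    """Point substitutions, never touching the first or last residue."""
    seq = list(cdr3)
    positions = rng.choice(np.arange(1, len(seq) - 1), size=n_subs, replace=False)
    for pos in positions:
        alternatives = [a for a in _alphabet() if a != seq[pos]]
        seq[pos] = rng.choice(alternatives)
    return "".join(seq)


def _nsesa_profile(rng, cdr: dict[str, str], buried_fraction: float):
    """Exposure profile: a buried fraction of residues below threshold."""
    out = {}
    for loop, seq in cdr.items():
        thr = DEFAULT_THRESHOLDS[loop]
        buried = rng.random(len(seq)) < buried_fraction
        vals = np.where(
            buried,
            rng.uniform(0.0, thr * 0.8, len(seq)),
            rng.uniform(min(thr * 1.5, 99.0), 100.0, len(seq)),
        )
        out[loop] = [float(v) for v in vals]
    return out


def generate_repertoire(cfg: GeneratorConfig) -> Repertoire:
    """Deterministic (seeded) labelled repertoire per the config."""
    rng = np.random.default_rng(cfg.seed)
    lookup = load_default_vgene_lookup()
    travs = [g for g in lookup.genes if g.startswith("TRAV")]
    trbvs = [g for g in lookup.genes if g.startswith("TRBV")]

    records = []

    def make_record(rid, trav, trbv, cdr3a, cdr3b, peptide):
        c1a, c2a = lookup.resolve(trav)
        c1b, c2b = lookup.resolve(trbv)
        cdr = {"CDR1a": c1a, "CDR2a": c2a, "CDR3a": cdr3a,
               "CDR1b": c1b, "CDR2b": c2b, "CDR3b": cdr3b}
        nsesa = (_nsesa_profile(rng, cdr, cfg.buried_fraction)
                 if cfg.with_nsesa else None)
        return TCRRecord(
            id=rid, trav=trav, trbv=trbv, cdr=cdr,
            specificity=Specificity(peptide) if peptide else None,
            nsesa=nsesa,
        )

    for s in range(cfg.n_specificities):
        peptide = f"PEP{s + 1:02d}"
        trav = str(rng.choice(travs))
        trbv = str(rng.choice(trbvs))
        seed_a = _random_cdr3(rng, int(rng.integers(*cfg.cdr3_length,
                                                    endpoint=True)))
        seed_b = _random_cdr3(rng, int(rng.integers(*cfg.cdr3_length,
                                                    endpoint=True)))
        size = int(rng.integers(*cfg.tcrs_per_specificity, endpoint=True))
        for t in range(size):
            if t == 0:
                a, b = seed_a, seed_b
            else:
                n_subs = int(rng.integers(*cfg.substitutions, endpoint=True))
                a = _substitute(rng, seed_a, n_subs)
                b = _substitute(rng, seed_b, n_subs)
            records.append(make_record(f"{peptide}_{t + 1:02d}", trav, trbv,
                                       a, b, peptide))

    for s in range(cfg.n_singletons):
        trav = str(rng.choice(travs))
        trbv = str(rng.choice(trbvs))
        a = _random_cdr3(rng, int(rng.integers(*cfg.cdr3_length, endpoint=True)))
        b = _random_cdr3(rng, int(rng.integers(*cfg.cdr3_length, endpoint=True)))
        records.append(make_record(f"SGL_{s + 1:02d}", trav, trbv, a, b,
                                   f"SINGLETON{s + 1:02d}"))

    return Repertoire(records, name=f"synthetic-seed{cfg.seed}")


def _read_table4() -> pd.DataFrame:
    from .io import read_tsv

    with resources.as_file(
        resources.files("tcrpcdist.data").joinpath("table4_rounds.tsv")
    ) as p:
        return read_tsv(p)


def table4_fixtures(resolve_cdr12: bool = True) -> Repertoire:
    """The printed orphan/reference rows of the four deorphanization rounds.

    Gene names and CDR3 sequences are transcribed exactly as printed (43
    rows; repeated reference rows get suffixed ids to keep ids unique).
    CDR1/CDR2 are filled from the bundled synthetic lookup by default.
    """
    df = _read_table4()
    lookup = load_default_vgene_lookup() if resolve_cdr12 else None
    records = []
    seen: dict[str, int] = {}
    for _, row in df.iterrows():
        rid = row["id"]
        seen[rid] = seen.get(rid, 0) + 1
        if seen[rid] > 1:
            rid = f"{rid}.{seen[rid]}"
        cdr = {"CDR3a": row["cdr3a"], "CDR3b": row["cdr3b"]}
        if lookup is not None:
            c1a, c2a = lookup.resolve(row["trav"])
            c1b, c2b = lookup.resolve(row["trbv"])
            cdr.update({"CDR1a": c1a, "CDR2a": c2a, "CDR1b": c1b, "CDR2b": c2b})
        spec = row["specificity"]
        records.append(TCRRecord(
            id=rid, patient=row["patient"],
            trav=row["trav"], traj=row["traj"],
            trbv=row["trbv"], trbj=row["trbj"],
            cdr=cdr,
            specificity=None if spec == "orphan" else Specificity(spec),
        ))
    return Repertoire(records, name="deorphanization-rounds")
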