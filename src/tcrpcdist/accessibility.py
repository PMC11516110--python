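"""Per-residue solvent accessibility (nSESA) for the 3D distance variant.

A residue's normalized surface area is its solvent-accessible area in the
receptor structure divided by its reference area in an extended Gly-X-Gly
tripeptide, expressed in percent and clipped to [0, 100].  Surface areas are
computed with the Shrake-Rupley rolling-probe algorithm (probe 1.4 A); the
exposure masks that feed window extraction keep residues strictly above the
per-loop thresholds (5% for CDR1/CDR2, 20% for CDR3).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "NSESAProfile",
    "load_reference_areas",
    "compute_nsesa",
    "apply_thresholds",
    "write_nsesa",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class NSESAProfile:
    """Per-loop (residue letter, nSESA %) lists for one receptor."""

    tcr_id: str
    loops: dict[str, list[tuple[str, float]]]
    provenance: str = "computed"

    def __post_init__(self):
        for loop, entries in self.loops.items():
            for res, val in entries:
                if not 0.0 <= val <= 100.0:
                    raise ValueError(
                        f"{self.tcr_id}/{loop}: nSESA {val} outside [0, 100]"
                    )

    def values(self) -> dict[str, list[float]]:
        return {loop: [v for _, v in entries] for loop, entries in self.loops.items()}

    def sequences(self) -> dict[str, str]:
        return {loop: "".join(r for r, _ in entries)
                for loop, entries in self.loops.items()}


def load_reference_areas() -> dict[str, float]:
    """Gly-X-Gly reference areas (A^2) bundled with the package."""
    areas = {}
    text = resources.files("tcrpcdist.data").joinpath(
        "gxg_reference_areas.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("aa\t"):
            continue
        aa, val = line.split("\t")
        areas[aa] = float(val)
    return areas


def compute_nsesa(
    structure_path,
    tcr_id: str,
    cdr_ranges: Mapping[str, tuple[str, int, int]],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> NSESAProfile:
    """nSESA profile from a PDB-format structure.

    ``cdr_ranges`` maps loop name -> (chain id, first residue number, last
    residue number), 1-based inclusive in PDB numbering.  Residues listed in
    a range but absent from the structure are a hard error.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(tcr_id, str(structure_path))
    model = next(structure.get_models())
    ShrakeRupley(probe_radius=probe_radius, n_points=n_points).compute(
        model, level="R"
    )
    reference = load_reference_areas()

    loops: dict[str, list[tuple[str, float]]] = {}
    for loop, (chain_id, start, end) in cdr_ranges.items():
        if chain_id not in model:
            raise ValueError(f"chain {chain_id!r} not found in {structure_path}")
        chain = model[chain_id]
        entries = []
        missing = []
        for num in range(start, end + 1):
            key = (" ", num, " ")
            if key not in chain:
                missing.append(num)
                continue
            residue = chain[key]
            name = residue.get_resname().upper()
            if name not in _THREE_TO_ONE:
                raise ValueError(
                    f"{tcr_id}/{loop}: non-standard residue {name} at {num}"
                )
            letter = _THREE_TO_ONE[name]
            nsesa = 100.0 * float(residue.sasa) / reference[letter]
            entries.append((letter, min(100.0, max(0.0, nsesa))))
        if missing:
            raise ValueError(
                f"{tcr_id}/{loop}: residues missing from chain {chain_id}: {missing}"
            )
        loops[loop] = entries
    return NSESAProfile(tcr_id=tcr_id, loops=loops, provenance="computed")


def apply_thresholds(
    profile: NSESAProfile,
    thresholds: Mapping[str, float] | None = None,
) -> dict[str, list[bool]]:
    """Per-loop exposure masks: True where nSESA strictly exceeds the threshold."""
    from .core import DEFAULT_THRESHOLDS

    thresholds = thresholds or DEFAULT_THRESHOLDS
    return {
        loop: [val > thresholds[loop] for _, val in entries]
        for loop, entries in profile.loops.items()
    }


def write_nsesa(profiles, path) -> None:
    """Write profiles in the nSESA TSV layout understood by ``read_nsesa``."""
    rows = []
    for prof in profiles:
        for loop, entries in prof.loops.items():
            for i, (res, val) in enumerate(entries, start=1):
                rows.append({
                    "tcr_id": prof.tcr_id, "loop": loop, "residue_index": i,
                    "residue": res, "nsesa_percent": round(val, 4),
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
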