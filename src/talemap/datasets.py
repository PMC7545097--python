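"""Bundled cross-link summary tables for the two TALE heterodimer datasets.

The shipped TSVs transcribe the published peptide summary tables for the
PREP1–PBX1 and MEIS1–PBX1 complexes in the compact
``PROT(residue)`` / ``PEPTIDE(position)`` notation. Replicate labels are
recorded only where the source states them (the PREP1–PBX1 inter-protein
peptides were identified in both biological replicates).
"""

from __future__ import annotations

from importlib import resources

from .xlink_core import PeptideIdentification, parse_compact_table

__all__ = [
    "fixture_path",
    "load_prep1_pbx1",
    "load_meis1_pbx1",
    "PREP1_PBX1_TABLES",
    "MEIS1_PBX1_TABLES",
]

PREP1_PBX1_TABLES = ("prep1_pbx1_inter", "prep1_pbx1_intra", "prep1_pbx1_loop")
MEIS1_PBX1_TABLES = ("meis1_pbx1_inter", "meis1_pbx1_intra", "meis1_pbx1_loop")


def fixture_path(name: str):
    """Filesystem path of a bundled table (without the .tsv suffix)."""
    return resources.files("talemap.data") / f"{name}.tsv"


def _load(names) -> list[PeptideIdentification]:
    records: list[PeptideIdentification] = []
    for name in names:
        records.extend(parse_compact_table(str(fixture_path(name))))
    return records


def load_prep1_pbx1(tables=PREP1_PBX1_TABLES) -> list[PeptideIdentification]:
    """Identifications of the PREP1–PBX1 dataset (inter, intra and looped)."""
    return _load(tables)


def load_meis1_pbx1(tables=MEIS1_PBX1_TABLES) -> list[PeptideIdentification]:
    """Identifications of the MEIS1–PBX1 dataset (inter, intra and looped)."""
    return _load(tables)
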