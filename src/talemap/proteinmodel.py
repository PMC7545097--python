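"""Protein sequences, domain and heptad-repeat annotation, in-silico digestion.

Residue numbering is 1-based throughout, with inclusive intervals, matching
the K87/K153-style notation used for cross-linked lysines. Heptad registers
follow the coiled-coil convention: seven positions labelled ``a``..``g``
cycling with period 7, with the hydrophobic interaction face usually at
``a`` and ``d``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "HEPTAD_LETTERS",
    "ProteinRecord",
    "DomainAnnotation",
    "HeptadAssignment",
    "DigestSpec",
    "Peptide",
    "load_fasta",
    "assign_heptad",
    "hydrophobic_face",
    "digest_in_silico",
    "annotate_domains",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
HEPTAD_LETTERS = "abcdefg"

DOMAIN_LABELS = {"HR1", "HR2", "HR3", "PBC-A", "PBC-B", "homeodomain"}


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending entry."""


@dataclass(frozen=True)
class DomainAnnotation:
    """A labelled interval on a protein, 1-based inclusive."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain {self.label}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"domain {self.label}: start must be >= 1")


@dataclass
class ProteinRecord:
    """A named amino-acid sequence with domain annotations.

    ``lysines`` is derived from the sequence and lists the 1-based positions
    of every K residue (the residues reactive toward an amine-specific
    cross-linker such as BS3).
    """

    name: str
    sequence: str
    domains: list[DomainAnnotation] = field(default_factory=list)
    permissive: bool = False
    lysines: list[int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - AMINO_ACIDS
        if bad and not self.permissive:
            raise ValueError(
                f"{self.name}: non-standard residues {sorted(bad)} "
                "(pass permissive=True to accept)"
            )
        labels = [d.label for d in self.domains]
        if len(labels) != len(set(labels)):
            raise ValueError(f"{self.name}: duplicate domain labels")
        for d in self.domains:
            if d.end > len(self.sequence):
                raise ValueError(f"{self.name}: domain {d.label} exceeds sequence length")
        self.lysines = [i + 1 for i, aa in enumerate(self.sequence) if aa == "K"]

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Amino acid at a 1-based position."""
        self._check_position(position)
        return self.sequence[position - 1]

    def domain_of(self, position: int) -> str:
        """Label of the domain covering ``position``; ``"linker"`` if none."""
        self._check_position(position)
        for d in self.domains:
            if d.start <= position <= d.end:
                return d.label
        return "linker"

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"{self.name}: residue {position} outside 1..{len(self.sequence)}"
            )


@dataclass(frozen=True)
class HeptadAssignment:
    """A periodic a–g register over a residue interval."""

    start: int
    phase: str
    end: int
    registers: dict[int, str]

    def letter(self, position: int) -> str:
        try:
            return self.registers[position]
        except KeyError:
            raise IndexError(f"residue {position} outside heptad interval "
                             f"{self.start}..{self.end}") from None


@dataclass(frozen=True)
class DigestSpec:
    """Enzymatic digestion rules.

    trypsin cleaves C-terminal to K/R (blocked before P when
    ``proline_block``); Glu-C cleaves C-terminal to E, optionally also D
    (``gluc_cleaves_d``, buffer-dependent specificity). ``blocked_sites``
    are residue positions at which cleavage never occurs immediately after
    — used for cross-linker-modified lysines, which proteases do not cut.
    """

    enzymes: frozenset[str] = frozenset({"trypsin", "gluc"})
    max_missed: int = 5
    gluc_cleaves_d: bool = False
    proline_block: bool = True
    blocked_sites: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.enzymes) - {"trypsin", "gluc"}
        if unknown:
            raise ValueError(f"unknown enzymes: {sorted(unknown)}")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.max_missed > 5:
            raise ValueError("max_missed above 5 exceeds the search setting")


@dataclass(frozen=True)
class Peptide:
    """A digestion product with 1-based inclusive coordinates."""

    sequence: str
    start: int
    end: int
    missed: int

    def __len__(self) -> int:
        return len(self.sequence)


def load_fasta(path, permissive: bool = False) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Duplicate record names are rejected; sequences containing letters
    outside the 20 standard amino acids raise unless ``permissive``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        name = entry.id
        if not name:
            raise FastaParseError(f"{path}: FASTA entry with empty header")
        if name in seen:
            raise FastaParseError(f"{path}: duplicate record name {name!r}")
        seen.add(name)
        try:
            records.append(ProteinRecord(name, str(entry.seq), permissive=permissive))
        except ValueError as exc:
            raise FastaParseError(f"{path}: entry {name!r}: {exc}") from exc
    return records


def assign_heptad(
    protein: ProteinRecord, start: int, phase: str, end: int
) -> HeptadAssignment:
    """Assign an a–g heptad register to ``start``..``end``.

    ``phase`` is the letter carried by ``start``; subsequent residues cycle
    through a,b,c,d,e,f,g with period 7.
    """
    if phase not in HEPTAD_LETTERS:
        raise ValueError(f"phase must be one of {HEPTAD_LETTERS!r}, got {phase!r}")
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    protein._check_position(start)
    protein._check_position(end)
    base = HEPTAD_LETTERS.index(phase)
    registers = {
        pos: HEPTAD_LETTERS[(base + pos - start) % 7] for pos in range(start, end + 1)
    }
    return HeptadAssignment(start=start, phase=phase, end=end, registers=registers)


def hydrophobic_face(
    assignment: HeptadAssignment,
    protein: ProteinRecord,
    letters: Iterable[str],
) -> list[tuple[int, str]]:
    """Residues occupying the requested register letters, ascending.

    With ``letters={"a", "d"}`` this reports the canonical hydrophobic
    interaction face of an amphipathic helix.
    """
    wanted = set(letters)
    unknown = wanted - set(HEPTAD_LETTERS)
    if unknown:
        raise ValueError(f"unknown heptad letters: {sorted(unknown)}")
    return [
        (pos, protein.residue(pos))
        for pos in sorted(assignment.registers)
        if assignment.registers[pos] in wanted
    ]


def cleavage_sites(sequence: str, spec: DigestSpec) -> list[int]:
    """1-based positions after which cleavage occurs (protein C-terminus excluded)."""
    sites: list[int] = []
    n = len(sequence)
    for i in range(1, n):  # no cut after the final residue
        if i in spec.blocked_sites:
            continue
        aa = sequence[i - 1]
        cut = False
        if "trypsin" in spec.enzymes and aa in "KR":
            cut = not (spec.proline_block and sequence[i] == "P")
        if not cut and "gluc" in spec.enzymes:
            if aa == "E" or (spec.gluc_cleaves_d and aa == "D"):
                cut = True
        if cut:
            sites.append(i)
    return sites


def digest_in_silico(protein: ProteinRecord, spec: DigestSpec) -> list[Peptide]:
    """Enumerate digestion peptides with up to ``spec.max_missed`` missed cleavages.

    The zero-missed peptides tile the sequence; a peptide with k missed
    cleavages is the merge of k+1 adjacent zero-missed peptides. Peptides
    are returned ordered by start, then by missed-cleavage count.
    """
    seq = protein.sequence
    sites = cleavage_sites(seq, spec)
    bounds = [0] + sites + [len(seq)]
    base = [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]
    peptides: list[Peptide] = []
    for i in range(len(base)):
        for k in range(spec.max_missed + 1):
            j = i + k
            if j >= len(base):
                break
            start, end = base[i][0], base[j][1]
            peptides.append(Peptide(seq[start - 1 : end], start, end, missed=k))
    peptides.sort(key=lambda p: (p.start, p.missed))
    return peptides


def annotate_domains(
    protein: ProteinRecord, table: Sequence[DomainAnnotation]
) -> ProteinRecord:
    """Return a copy of ``protein`` carrying the given domain annotations."""
    return ProteinRecord(
        name=protein.name,
        sequence=protein.sequence,
        domains=list(table),
        permissive=protein.permissive,
    )


# Approximate default domain tables. Only fragmentary boundaries are printed
# for these proteins (hydrophobic stretches 43-55, 77-84/90, 105-113 and
# 197-204/211 of PBX1; HR1 63-73 and HR2 117-132 of PREP1; the "HR3" stretch
# 242-252); the intervals below bracket those stretches and are flagged
# approximate — they serve display and domain-pair summaries, not analysis.
APPROXIMATE_DOMAINS: dict[str, list[DomainAnnotation]] = {
    "PREP1": [
        DomainAnnotation("HR1", 58, 84),
        DomainAnnotation("HR2", 113, 137),
        DomainAnnotation("HR3", 242, 252),
        DomainAnnotation("homeodomain", 258, 320),
    ],
    "PBX1": [
        DomainAnnotation("PBC-A", 38, 112),
        DomainAnnotation("PBC-B", 126, 213),
        DomainAnnotation("homeodomain", 233, 295),
    ],
    "MEIS1": [
        DomainAnnotation("HR1", 64, 91),
        DomainAnnotation("HR2", 140, 165),
        DomainAnnotation("homeodomain", 272, 334),
    ],
}
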