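"""Cross-link identification parsing, curation, residue mapping and collapse.

The pipeline consumes search-engine identifications of BS3 lysine–lysine
cross-linked peptides (pLink-2-style delimited exports, or the compact
``PEPTIDEA(i)-PEPTIDEB(j)`` notation used in printed summary tables), applies
the manual-curation rules (E-value cutoff, consecutive fragment-ion runs,
majority of peaks assigned), maps in-peptide link positions to absolute
1-based residues, classifies each link as inter-protein, intra-protein or
loop (both linked residues on one peptide), and collapses redundant
spectrum-level evidence into unique residue-pair cross-links with replicate
support.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .proteinmodel import ProteinRecord

__all__ = [
    "SpectrumAnnotation",
    "PeptideIdentification",
    "CrossLink",
    "PlinkDialect",
    "parse_plink_table",
    "parse_compact_table",
    "curate_identifications",
    "map_to_residues",
    "infer_peptide_offsets",
    "classify_link",
    "collapse_redundant",
    "aggregate_replicates",
]


class TableParseError(ValueError):
    """A malformed identifications table row, reported with its line number."""


class MappingError(ValueError):
    """Peptide cannot be placed unambiguously on the assigned protein."""


@dataclass(frozen=True)
class SpectrumAnnotation:
    """Matched fragment-ion ordinals for one spectrum.

    Ordinals are 1-based fragment indices (b1, b2, ... / y1, y2, ...) per
    peptide; ``n_peaks_assigned``/``n_peaks_total`` summarize overall
    spectrum annotation coverage.
    """

    matched_b_a: tuple[int, ...] = ()
    matched_y_a: tuple[int, ...] = ()
    matched_b_b: tuple[int, ...] = ()
    matched_y_b: tuple[int, ...] = ()
    n_peaks_total: int = 0
    n_peaks_assigned: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks_assigned > self.n_peaks_total:
            raise ValueError("assigned peaks exceed total peaks")
        for name in ("matched_b_a", "matched_y_a", "matched_b_b", "matched_y_b"):
            vals = getattr(self, name)
            object.__setattr__(self, name, tuple(sorted(set(vals))))


def longest_run(ordinals: Sequence[int]) -> int:
    """Length of the longest run of consecutive integers."""
    best = run = 0
    prev = None
    for x in sorted(set(ordinals)):
        run = run + 1 if prev is not None and x == prev + 1 else 1
        best = max(best, run)
        prev = x
    return best


@dataclass(frozen=True)
class PeptideIdentification:
    """One search-engine record: a cross-linked peptide pair or a looped peptide.

    For a pair, ``peptide_a``/``pos_a`` and ``peptide_b``/``pos_b`` describe
    the two peptides and the 1-based in-peptide positions of the linked
    residues. For a looped peptide ``peptide_b`` is ``None`` and ``pos_a``,
    ``pos_b`` are the two link positions within ``peptide_a``.
    ``residue_a``/``residue_b`` are the claimed absolute positions in the
    full-length protein, when the source table supplies them.
    """

    peptide_a: str
    pos_a: int
    protein_a: str
    peptide_b: str | None
    pos_b: int
    protein_b: str
    residue_a: int | None = None
    residue_b: int | None = None
    evalue: float | None = None
    replicate: str = "R1"
    ions: SpectrumAnnotation | None = None
    allow_nterm: bool = False
    mapped: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.pos_a <= len(self.peptide_a):
            raise ValueError(f"pos_a {self.pos_a} outside peptide {self.peptide_a!r}")
        if self.is_loop:
            if not 1 <= self.pos_b <= len(self.peptide_a):
                raise ValueError(
                    f"loop pos_b {self.pos_b} outside peptide {self.peptide_a!r}"
                )
            if self.pos_a == self.pos_b:
                raise ValueError("loop link positions must differ")
            if self.protein_a != self.protein_b:
                raise ValueError("loop record must assign a single protein")
        else:
            if not 1 <= self.pos_b <= len(self.peptide_b):
                raise ValueError(f"pos_b {self.pos_b} outside peptide {self.peptide_b!r}")
        if self.evalue is not None and self.evalue <= 0:
            raise ValueError("evalue must be positive")
        for pep, pos in self.linked_sites():
            aa = pep[pos - 1]
            if aa != "K" and not (self.allow_nterm and pos == 1):
                raise ValueError(
                    f"linked residue {aa!r} at position {pos} of {pep!r} is not K"
                )

    @property
    def is_loop(self) -> bool:
        return self.peptide_b is None

    def linked_sites(self) -> list[tuple[str, int]]:
        if self.is_loop:
            return [(self.peptide_a, self.pos_a), (self.peptide_a, self.pos_b)]
        return [(self.peptide_a, self.pos_a), (self.peptide_b, self.pos_b)]


@dataclass
class CrossLink:
    """A redundancy-collapsed residue-level cross-link.

    Canonically ordered so that (A, ra, B, rb) and (B, rb, A, ra) compare
    equal; ``link_class`` is one of ``inter``, ``intra``, ``loop``.
    """

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    link_class: str
    replicate_support: frozenset[str] = frozenset()
    best_evalue: float | None = None
    evidence: list[PeptideIdentification] = field(default_factory=list)

    @property
    def both_replicates(self) -> bool:
        return len(self.replicate_support) >= 2

    @property
    def key(self) -> tuple:
        return (self.protein_a, self.residue_a, self.protein_b, self.residue_b,
                self.link_class)


# ---------------------------------------------------------------------------
# Parsing

@dataclass(frozen=True)
class PlinkDialect:
    """Column map for a delimited identifications export.

    Defaults cover a generic pLink-2-style long format; remap the names for
    other dialects. ``peptide_b`` may be empty in a row, denoting a looped
    peptide with both positions on peptide A.
    """

    delimiter: str = "\t"
    peptide_a: str = "peptide_a"
    pos_a: str = "pos_a"
    protein_a: str = "protein_a"
    peptide_b: str = "peptide_b"
    pos_b: str = "pos_b"
    protein_b: str = "protein_b"
    residue_a: str = "residue_a"
    residue_b: str = "residue_b"
    evalue: str = "evalue"
    replicate: str = "replicate"


def parse_plink_table(
    path, dialect: PlinkDialect = PlinkDialect(), allow_nterm: bool = False
) -> list[PeptideIdentification]:
    """Read a delimited identifications table into records.

    Required columns (per ``dialect``): peptides, positions and protein
    assignments; absolute residues, E-value and replicate are optional.
    Row-level problems raise :class:`TableParseError` with the line number.
    """
    records: list[PeptideIdentification] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            return []
        required = [dialect.peptide_a, dialect.pos_a, dialect.protein_a]
        for col in required:
            if col not in reader.fieldnames:
                raise TableParseError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_row_to_record(row, dialect, allow_nterm))
            except (ValueError, KeyError) as exc:
                raise TableParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def _row_to_record(
    row: Mapping[str, str], d: PlinkDialect, allow_nterm: bool
) -> PeptideIdentification:
    def opt(col, conv):
        raw = (row.get(col) or "").strip()
        return conv(raw) if raw else None

    peptide_b = (row.get(d.peptide_b) or "").strip() or None
    return PeptideIdentification(
        peptide_a=row[d.peptide_a].strip(),
        pos_a=int(row[d.pos_a]),
        protein_a=row[d.protein_a].strip(),
        peptide_b=peptide_b,
        pos_b=int(row[d.pos_b]),
        protein_b=(row.get(d.protein_b) or "").strip() or row[d.protein_a].strip(),
        residue_a=opt(d.residue_a, int),
        residue_b=opt(d.residue_b, int),
        evalue=opt(d.evalue, float),
        replicate=(row.get(d.replicate) or "").strip() or "R1",
        allow_nterm=allow_nterm,
    )


_SITE = re.compile(r"^\s*(?P<prot>[^()\s]+)\s*\((?P<r1>\d+)\)(?:\((?P<r2>\d+)\))?\s*$")
_PEP = re.compile(r"^\s*(?P<seq>[A-Za-z]+)\((?P<p1>\d+)\)(?:\((?P<p2>\d+)\))?\s*$")


def parse_compact_notation(
    crosslink: str, peptides: str, replicate: str = "R1", allow_nterm: bool = False
) -> PeptideIdentification:
    """Parse one row of the compact summary notation.

    Pair rows read ``PROTA(ra)-PROTB(rb)`` / ``PEPA(i)-PEPB(j)``; looped
    rows read ``PROT(r1)(r2)`` / ``PEP(i)(j)``.
    """
    xl = crosslink.replace(" ", "")
    loop_m = _SITE.match(xl)
    if loop_m and loop_m.group("r2"):
        pep_m = _PEP.match(peptides.replace(" ", ""))
        if not pep_m or not pep_m.group("p2"):
            raise ValueError(f"loop cross-link {crosslink!r} needs a two-position "
                             f"peptide, got {peptides!r}")
        prot = loop_m.group("prot")
        return PeptideIdentification(
            peptide_a=pep_m.group("seq").upper(),
            pos_a=int(pep_m.group("p1")),
            pos_b=int(pep_m.group("p2")),
            peptide_b=None,
            protein_a=prot,
            protein_b=prot,
            residue_a=int(loop_m.group("r1")),
            residue_b=int(loop_m.group("r2")),
            replicate=replicate,
            allow_nterm=allow_nterm,
        )
    try:
        site_a, site_b = _split_pair(xl)
        pep_a, pep_b = _split_pair(peptides.replace(" ", ""))
    except ValueError as exc:
        raise ValueError(f"cannot parse {crosslink!r} / {peptides!r}: {exc}") from exc
    ma, mb = _SITE.match(site_a), _SITE.match(site_b)
    pa, pb = _PEP.match(pep_a), _PEP.match(pep_b)
    if not (ma and mb and pa and pb):
        raise ValueError(f"cannot parse {crosslink!r} / {peptides!r}")
    return PeptideIdentification(
        peptide_a=pa.group("seq").upper(),
        pos_a=int(pa.group("p1")),
        protein_a=ma.group("prot"),
        peptide_b=pb.group("seq").upper(),
        pos_b=int(pb.group("p1")),
        protein_b=mb.group("prot"),
        residue_a=int(ma.group("r1")),
        residue_b=int(mb.group("r1")),
        replicate=replicate,
        allow_nterm=allow_nterm,
    )


def _split_pair(text: str) -> tuple[str, str]:
    """Split ``X(i)-Y(j)`` on the dash between the two halves."""
    for i, ch in enumerate(text):
        if ch == "-" and text[:i].count("(") == text[:i].count(")") and "(" in text[:i]:
            return text[:i], text[i + 1:]
    raise ValueError("no pair separator found")


def parse_compact_table(path, allow_nterm: bool = False) -> list[PeptideIdentification]:
    """Read a TSV with columns ``crosslink``, ``peptides`` and optional
    ``replicates`` (``;``-separated labels; one record is emitted per label)."""
    records: list[PeptideIdentification] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        for lineno, row in enumerate(reader, start=2):
            try:
                labels = [s for s in (row.get("replicates") or "").split(";") if s]
                for rep in labels or ["R1"]:
                    records.append(
                        parse_compact_notation(
                            row["crosslink"], row["peptides"], rep, allow_nterm
                        )
                    )
            except (ValueError, KeyError) as exc:
                raise TableParseError(f"{path}:{lineno}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Curation

@dataclass
class CurationResult:
    kept: list[PeptideIdentification]
    rejected: list[tuple[PeptideIdentification, str]]
    uncurated: list[PeptideIdentification] = field(default_factory=list)


def curate_identifications(
    records: Iterable[PeptideIdentification],
    evalue_max: float = 1e-3,
    min_consecutive: int = 4,
    majority_fraction: float = 0.5,
    permissive: bool = False,
) -> CurationResult:
    """Apply the manual-curation rules to spectrum-level identifications.

    A record is kept iff its E-value is strictly below ``evalue_max``, each
    cross-linked peptide shows at least ``min_consecutive`` consecutive
    matched ordinals within its b series or within its y series (series are
    not mixed), and the assigned fraction of spectrum peaks strictly exceeds
    ``majority_fraction``. Records lacking ion annotations are rejected
    unless ``permissive``, in which case they are kept but listed separately
    as uncurated.
    """
    result = CurationResult(kept=[], rejected=[])
    for rec in records:
        if rec.evalue is None or rec.ions is None:
            if permissive:
                result.kept.append(rec)
                result.uncurated.append(rec)
            else:
                result.rejected.append((rec, "missing-annotation"))
            continue
        if not rec.evalue < evalue_max:
            result.rejected.append((rec, "evalue"))
            continue
        ions = rec.ions
        runs_a = max(longest_run(ions.matched_b_a), longest_run(ions.matched_y_a))
        if rec.is_loop:
            ok_ions = runs_a >= min_consecutive
        else:
            runs_b = max(longest_run(ions.matched_b_b), longest_run(ions.matched_y_b))
            ok_ions = runs_a >= min_consecutive and runs_b >= min_consecutive
        if not ok_ions:
            result.rejected.append((rec, "consecutive-ions"))
            continue
        if ions.n_peaks_total <= 0 or not (
            ions.n_peaks_assigned / ions.n_peaks_total > majority_fraction
        ):
            result.rejected.append((rec, "majority-assigned"))
            continue
        result.kept.append(rec)
    return result


# ---------------------------------------------------------------------------
# Residue mapping

def _find_occurrences(sequence: str, peptide: str) -> list[int]:
    """1-based start offsets of every occurrence of ``peptide``."""
    starts, i = [], sequence.find(peptide)
    while i != -1:
        starts.append(i + 1)
        i = sequence.find(peptide, i + 1)
    return starts


def _locate(protein: ProteinRecord, peptide: str, pos: int,
            claimed: int | None) -> int:
    occurrences = _find_occurrences(protein.sequence, peptide)
    if not occurrences:
        raise MappingError(f"peptide {peptide!r} not found in {protein.name}")
    if len(occurrences) == 1:
        absolute = occurrences[0] + pos - 1
        if claimed is not None and claimed != absolute:
            raise MappingError(
                f"{protein.name}: claimed residue {claimed} disagrees with "
                f"computed {absolute} for {peptide!r}({pos})"
            )
        return absolute
    if claimed is None:
        raise MappingError(
            f"peptide {peptide!r} occurs at {len(occurrences)} offsets in "
            f"{protein.name} and no claimed residue disambiguates"
        )
    if claimed - pos + 1 not in occurrences:
        raise MappingError(
            f"{protein.name}: claimed residue {claimed} matches no occurrence "
            f"of {peptide!r}"
        )
    return claimed


def map_to_residues(
    record: PeptideIdentification,
    proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord] | None = None,
) -> PeptideIdentification:
    """Resolve absolute 1-based residues for both linked positions.

    With protein sequences available, each peptide is located in its
    assigned protein (absolute = peptide start + in-peptide position − 1)
    and any claimed residue from the source table is verified against the
    computed one; multiple occurrences are resolved via the claimed residue.
    Without sequences, the claimed residues are adopted as-is (the linked
    position having already been checked to be a lysine at construction).
    """
    if proteins is not None and not isinstance(proteins, Mapping):
        proteins = {p.name: p for p in proteins}

    def resolve(protein_name: str, peptide: str, pos: int, claimed: int | None) -> int:
        if proteins is not None and protein_name in proteins:
            return _locate(proteins[protein_name], peptide, pos, claimed)
        if claimed is None:
            raise MappingError(
                f"no sequence for {protein_name} and no claimed residue"
            )
        return claimed

    if record.is_loop:
        ra = resolve(record.protein_a, record.peptide_a, record.pos_a, record.residue_a)
        rb = resolve(record.protein_a, record.peptide_a, record.pos_b, record.residue_b)
        if ra - record.pos_a != rb - record.pos_b:
            raise MappingError(
                f"loop positions of {record.peptide_a!r} imply different starts"
            )
    else:
        ra = resolve(record.protein_a, record.peptide_a, record.pos_a, record.residue_a)
        rb = resolve(record.protein_b, record.peptide_b, record.pos_b, record.residue_b)
    return replace(record, residue_a=ra, residue_b=rb, mapped=True)


@dataclass
class OffsetAudit:
    """Implied peptide start offsets and any internal contradictions."""

    offsets: dict[tuple[str, str], int]
    contradictions: list[tuple[str, str, list[int]]]


def infer_peptide_offsets(records: Iterable[PeptideIdentification]) -> OffsetAudit:
    """Audit claimed absolute residues for internal consistency.

    Every (protein, peptide, in-peptide position, absolute residue) tuple
    implies a start offset ``residue − pos + 1``; all records sharing a
    (protein, peptide) key must imply a single offset. Overlapping but
    distinct peptides legitimately imply different offsets.
    """
    implied: dict[tuple[str, str], set[int]] = {}
    for rec in records:
        sites: list[tuple[str, str, int, int | None]] = []
        if rec.is_loop:
            sites = [(rec.protein_a, rec.peptide_a, rec.pos_a, rec.residue_a),
                     (rec.protein_a, rec.peptide_a, rec.pos_b, rec.residue_b)]
        else:
            sites = [(rec.protein_a, rec.peptide_a, rec.pos_a, rec.residue_a),
                     (rec.protein_b, rec.peptide_b, rec.pos_b, rec.residue_b)]
        for prot, pep, pos, residue in sites:
            if residue is None:
                continue
            implied.setdefault((prot, pep), set()).add(residue - pos + 1)
    offsets = {k: next(iter(v)) for k, v in implied.items() if len(v) == 1}
    contradictions = [(k[0], k[1], sorted(v)) for k, v in sorted(implied.items())
                      if len(v) > 1]
    return OffsetAudit(offsets=offsets, contradictions=contradictions)


# ---------------------------------------------------------------------------
# Classification and collapse

def classify_link(record: PeptideIdentification) -> str:
    """``loop`` for single-peptide records, ``inter`` across proteins, else ``intra``."""
    if record.is_loop:
        return "loop"
    return "inter" if record.protein_a != record.protein_b else "intra"


def _canonical_key(record: PeptideIdentification) -> tuple:
    if record.residue_a is None or record.residue_b is None:
        raise MappingError("record must be mapped before collapsing")
    a = (record.protein_a, record.residue_a)
    b = (record.protein_b, record.residue_b)
    lo, hi = sorted([a, b])
    return (lo[0], lo[1], hi[0], hi[1], classify_link(record))


def collapse_redundant(records: Iterable[PeptideIdentification]) -> list[CrossLink]:
    """Collapse spectrum-level records into unique residue-pair cross-links.

    Uniqueness is at the residue-pair level, with the two sites canonically
    ordered (so symmetric duplicates merge); loop links key on their
    unordered position pair within one protein. Evidence is retained and the
    best (minimum) E-value reported.
    """
    groups: dict[tuple, list[PeptideIdentification]] = {}
    order: list[tuple] = []
    for rec in records:
        key = _canonical_key(rec)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    links = []
    for key in order:
        evidence = groups[key]
        evalues = [r.evalue for r in evidence if r.evalue is not None]
        links.append(
            CrossLink(
                protein_a=key[0], residue_a=key[1],
                protein_b=key[2], residue_b=key[3],
                link_class=key[4],
                replicate_support=frozenset(r.replicate for r in evidence),
                best_evalue=min(evalues) if evalues else None,
                evidence=evidence,
            )
        )
    return links


def aggregate_replicates(links: Iterable[CrossLink]) -> list[CrossLink]:
    """Recompute replicate support from the retained evidence.

    The ``both_replicates`` flag (support in at least two biological
    replicates, drawn bold in linear maps) is monotone: adding evidence can
    only set it, never unset it.
    """
    out = []
    for link in links:
        support = frozenset(r.replicate for r in link.evidence) | link.replicate_support
        out.append(replace_link(link, replicate_support=support))
    return out


def replace_link(link: CrossLink, **kwargs) -> CrossLink:
    params = dict(
        protein_a=link.protein_a, residue_a=link.residue_a,
        protein_b=link.protein_b, residue_b=link.residue_b,
        link_class=link.link_class, replicate_support=link.replicate_support,
        best_evalue=link.best_evalue, evidence=link.evidence,
    )
    params.update(kwargs)
    return CrossLink(**params)
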