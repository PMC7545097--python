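"""Cross-link summaries, linear-map SVG rendering and table export."""

from __future__ import annotations

import csv
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .proteinmodel import ProteinRecord
from .xlink_core import CrossLink, PeptideIdentification

__all__ = [
    "LinkSummary",
    "summarize_counts",
    "render_linear_map",
    "export_link_table",
    "read_link_table",
]

SVG_NS = "http://www.w3.org/2000/svg"


@dataclass
class LinkSummary:
    """Per-class and per-protein(-pair) counts of non-redundant links."""

    n_total: int
    by_class: dict[str, int]
    inter_by_pair: dict[tuple[str, str], int]
    intra_by_protein: dict[str, int]
    loop_by_protein: dict[str, int]
    both_replicate_links: list[CrossLink] = field(default_factory=list)
    domain_matrix: pd.DataFrame | None = None


def summarize_counts(
    links: Sequence[CrossLink],
    proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord] | None = None,
) -> LinkSummary:
    """Count collapsed links per class, protein pair and (optionally) domain pair.

    The class counts partition the input: inter + intra + loop = total.
    With annotated proteins supplied, a symmetric domain-pair contact matrix
    is built from each link's residue-to-domain lookup.
    """
    if proteins is not None and not isinstance(proteins, Mapping):
        proteins = {p.name: p for p in proteins}
    by_class = {"inter": 0, "intra": 0, "loop": 0}
    inter_by_pair: dict[tuple[str, str], int] = {}
    intra_by_protein: dict[str, int] = {}
    loop_by_protein: dict[str, int] = {}
    for link in links:
        by_class[link.link_class] += 1
        if link.link_class == "inter":
            pair = tuple(sorted([link.protein_a, link.protein_b]))
            inter_by_pair[pair] = inter_by_pair.get(pair, 0) + 1
        elif link.link_class == "intra":
            intra_by_protein[link.protein_a] = intra_by_protein.get(link.protein_a, 0) + 1
        else:
            loop_by_protein[link.protein_a] = loop_by_protein.get(link.protein_a, 0) + 1
    matrix = None
    if proteins is not None:
        pairs = []
        for link in links:
            da = _domain_of(proteins, link.protein_a, link.residue_a)
            db = _domain_of(proteins, link.protein_b, link.residue_b)
            pairs.append(tuple(sorted([f"{link.protein_a}:{da}", f"{link.protein_b}:{db}"])))
        labels = sorted({d for p in pairs for d in p})
        matrix = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for a, b in pairs:
            matrix.loc[a, b] += 1
            if a != b:
                matrix.loc[b, a] += 1
    return LinkSummary(
        n_total=len(links),
        by_class=by_class,
        inter_by_pair=inter_by_pair,
        intra_by_protein=intra_by_protein,
        loop_by_protein=loop_by_protein,
        both_replicate_links=[l for l in links if l.both_replicates],
        domain_matrix=matrix,
    )


def _domain_of(proteins, name, residue) -> str:
    if name in proteins:
        try:
            return proteins[name].domain_of(residue)
        except IndexError:
            return "out-of-range"
    return "unknown"


@dataclass(frozen=True)
class MapStyle:
    """Visual configuration for the linear cross-link map."""

    width: int = 900
    bar_height: int = 18
    bar_gap: int = 140
    margin: int = 40
    px_per_residue: float | None = None
    stroke: str = "#555555"
    bold_stroke_width: float = 2.5
    thin_stroke_width: float = 1.0
    class_colors: Mapping[str, str] = None  # type: ignore[assignment]
    domain_colors: Mapping[str, str] = None  # type: ignore[assignment]

    def color_for_class(self, link_class: str) -> str:
        defaults = {"inter": "#1f77b4", "intra": "#d62728", "loop": "#2ca02c"}
        if self.class_colors:
            defaults.update(self.class_colors)
        return defaults.get(link_class, self.stroke)


def render_linear_map(
    links: Sequence[CrossLink],
    proteins: Sequence[ProteinRecord],
    style: MapStyle = MapStyle(),
) -> str:
    """Draw proteins as horizontal bars with domain blocks and links as arcs.

    Inter-protein arcs span between the protein bars; intra and loop arcs
    bow above their protein. Links supported by both biological replicates
    are drawn with a heavier stroke. The layout is deterministic for a
    fixed input order; arc elements carry ``class="arc <link_class>"`` so
    the drawing is machine-countable.
    """
    order = {p.name: i for i, p in enumerate(proteins)}
    for link in links:
        if link.protein_a not in order or link.protein_b not in order:
            missing = {link.protein_a, link.protein_b} - set(order)
            raise KeyError(f"link references unknown protein(s) {sorted(missing)}")
    longest = max(len(p) for p in proteins)
    scale = style.px_per_residue or (style.width - 2 * style.margin) / longest

    svg = ET.Element("svg", xmlns=SVG_NS, width=str(style.width))
    height = style.margin * 2 + len(proteins) * (style.bar_height + style.bar_gap)
    svg.set("height", str(height))
    meta = ET.SubElement(svg, "metadata")
    meta.text = ("domain blocks use approximate default boundaries; "
                 "bold arcs = links found in both biological replicates")

    def bar_y(name: str) -> float:
        return style.margin + style.bar_gap / 2 + order[name] * (
            style.bar_height + style.bar_gap)

    def x_of(name: str, residue: int) -> float:
        return style.margin + (residue - 0.5) * scale

    for p in proteins:
        y = bar_y(p.name)
        ET.SubElement(
            svg, "rect", x=str(style.margin), y=str(y),
            width=str(len(p) * scale), height=str(style.bar_height),
            fill="#dddddd", stroke="#333333",
        ).set("class", "protein-bar")
        label = ET.SubElement(svg, "text", x=str(style.margin),
                              y=str(y + style.bar_height + 14))
        label.text = p.name
        palette = ["#ffd92f", "#8da0cb", "#fc8d62", "#66c2a5", "#e78ac3"]
        for i, dom in enumerate(p.domains):
            color = (style.domain_colors or {}).get(dom.label, palette[i % len(palette)])
            block = ET.SubElement(
                svg, "rect", x=str(x_of(p.name, dom.start) - 0.5 * scale), y=str(y),
                width=str((dom.end - dom.start + 1) * scale),
                height=str(style.bar_height), fill=color, stroke="#333333",
            )
            block.set("class", "domain-block")
            title = ET.SubElement(block, "title")
            title.text = f"{dom.label} {dom.start}-{dom.end} (approximate)"

    for link in links:
        ya, yb = bar_y(link.protein_a), bar_y(link.protein_b)
        xa = x_of(link.protein_a, link.residue_a)
        xb = x_of(link.protein_b, link.residue_b)
        if link.protein_a == link.protein_b:
            # arc above the bar, height proportional to sequence distance
            rise = 12 + 0.35 * abs(xb - xa)
            d = f"M {xa:.1f} {ya:.1f} Q {(xa + xb) / 2:.1f} {ya - rise:.1f} {xb:.1f} {ya:.1f}"
        else:
            top, bot = (ya, yb) if ya < yb else (yb, ya)
            x_top, x_bot = (xa, xb) if ya < yb else (xb, xa)
            d = (f"M {x_top:.1f} {top + style.bar_height:.1f} "
                 f"Q {(xa + xb) / 2:.1f} {(top + bot) / 2:.1f} {x_bot:.1f} {bot:.1f}")
        path = ET.SubElement(svg, "path", d=d, fill="none",
                             stroke=style.color_for_class(link.link_class))
        path.set("class", f"arc {link.link_class}")
        path.set(
            "stroke-width",
            str(style.bold_stroke_width if link.both_replicates
                else style.thin_stroke_width),
        )
        title = ET.SubElement(path, "title")
        title.text = (f"{link.protein_a}(K{link.residue_a})-"
                      f"{link.protein_b}(K{link.residue_b}) [{link.link_class}]")
    return ET.tostring(svg, encoding="unicode")


def count_arcs(svg_text: str, link_class: str | None = None) -> int:
    """Count arc elements in a rendered map, optionally filtered by class."""
    root = ET.fromstring(svg_text)
    n = 0
    for el in root.iter(f"{{{SVG_NS}}}path"):
        classes = (el.get("class") or "").split()
        if "arc" in classes and (link_class is None or link_class in classes):
            n += 1
    return n


LINK_TABLE_COLUMNS = [
    "protein_a", "residue_a", "protein_b", "residue_b",
    "link_class", "replicates", "best_evalue", "n_evidence",
]


def export_link_table(links: Iterable[CrossLink], path) -> None:
    """Write collapsed links to a TSV with a stable column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(LINK_TABLE_COLUMNS)
        for link in links:
            writer.writerow([
                link.protein_a, link.residue_a, link.protein_b, link.residue_b,
                link.link_class, ";".join(sorted(link.replicate_support)),
                "" if link.best_evalue is None else repr(link.best_evalue),
                len(link.evidence),
            ])


def read_link_table(path) -> list[CrossLink]:
    """Read a TSV produced by :func:`export_link_table` (evidence is not
    round-tripped; replicate support and counts are)."""
    links = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            links.append(CrossLink(
                protein_a=row["protein_a"], residue_a=int(row["residue_a"]),
                protein_b=row["protein_b"], residue_b=int(row["residue_b"]),
                link_class=row["link_class"],
                replicate_support=frozenset(
                    s for s in row["replicates"].split(";") if s),
                best_evalue=float(row["best_evalue"]) if row["best_evalue"] else None,
            ))
    return links
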