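"""Vertical linear pathway diagram rendering (plain text and SVG).

The current path is drawn top-to-bottom in step order. Each step optionally
shows the linking reaction's equation, EC number, enzymes and genes, pathway
links, side metabolites, and compound structures (as SMILES strings), all
independently toggleable. Precursor/successor candidate lists are shown per
step, at the path ends only, or not at all; each candidate is tagged with its
connection class (unidirectional / bidirectional / spontaneous / multiple).

Every rendered element carries a stable machine-readable anchor id — written
as ``[@anchor]`` tokens in text output and as ``id`` attributes in SVG — so
that element presence and ordering are testable. Anchor grammar:
``step.<i>.metab.<qid>``, ``step.<i>.rxn.<qid>``, ``step.<i>.count``,
``step.<i>.ec``, ``step.<i>.enzymes``, ``step.<i>.genes``,
``step.<i>.pathways``, ``step.<i>.side``, ``step.<i>.smiles``,
``step.<i>.pre.<qid>`` and ``step.<i>.suc.<qid>``, where ``<qid>`` is the
percent-encoded metabolite or reaction id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from urllib.parse import quote, unquote
from xml.etree import ElementTree as ET

from .model import Network, Reaction
from .neighborhood import (
    ConnectionClass,
    Orientation,
    Side,
    linking_reactions,
    neighborhood,
    side_metabolites,
    classify_connection,
)

__all__ = [
    "CandidatesMode",
    "DisplaySettings",
    "OutputFormat",
    "RenderedDiagram",
    "render",
    "candidate_panel",
    "extract_anchors",
    "metabolite_sequence",
]


class CandidatesMode(Enum):
    ALL_STEPS = "A"
    ENDS_ONLY = "E"
    NONE = "N"


class OutputFormat(Enum):
    TEXT = "text"
    SVG = "svg"


#: Text-mode letter codes and SVG colors for each connection class.
CLASS_CODES: dict[ConnectionClass, str] = {
    ConnectionClass.UNIDIRECTIONAL: "U",
    ConnectionClass.BIDIRECTIONAL: "B",
    ConnectionClass.SPONTANEOUS: "S",
    ConnectionClass.MULTIPLE: "M",
}
CLASS_COLORS: dict[ConnectionClass, str] = {
    ConnectionClass.UNIDIRECTIONAL: "#444444",
    ConnectionClass.BIDIRECTIONAL: "#1f77b4",
    ConnectionClass.SPONTANEOUS: "#2ca02c",
    ConnectionClass.MULTIPLE: "#ff7f0e",
}


@dataclass
class DisplaySettings:
    """Which diagram elements are visible.

    Defaults match a fully annotated display: side metabolites, enzymes and
    genes, EC numbers, and pathway links on; structures off; candidate lists
    at every step. ``candidate_limit`` truncates long candidate lists with an
    explicit "+N more" marker.
    """

    show_side_metabolites: bool = True
    show_enzymes_genes: bool = True
    show_ec: bool = True
    show_structures: bool = False
    candidates_mode: CandidatesMode = CandidatesMode.ALL_STEPS
    show_pathway_links: bool = True
    candidate_limit: int = 10

    _FLAGS = (
        "show_side_metabolites",
        "show_enzymes_genes",
        "show_ec",
        "show_structures",
        "show_pathway_links",
    )

    def to_code(self) -> str:
        """Compact, link-embeddable encoding, e.g. ``11101A10``."""
        bits = "".join("1" if getattr(self, f) else "0" for f in self._FLAGS)
        return f"{bits}{self.candidates_mode.value}{self.candidate_limit}"

    @classmethod
    def from_code(cls, code: str) -> "DisplaySettings":
        m = re.fullmatch(r"([01]{5})([AEN])(\d+)", code)
        if not m:
            raise ValueError(f"bad display-settings code {code!r}")
        bits, mode, limit = m.groups()
        kwargs = {f: bits[i] == "1" for i, f in enumerate(cls._FLAGS)}
        return cls(
            candidates_mode=CandidatesMode(mode),
            candidate_limit=int(limit),
            **kwargs,
        )


@dataclass
class RenderedDiagram:
    format: OutputFormat
    content: str
    legend: dict[ConnectionClass, str] = field(default_factory=dict)


_ANCHOR_TEXT_RE = re.compile(r"\[@([^\]\s]+)\]")
_METAB_ANCHOR_RE = re.compile(r"^step\.(\d+)\.metab\.(.+)$")


def _anchor(step: int, kind: str, ident: str | None = None) -> str:
    if ident is None:
        return f"step.{step}.{kind}"
    return f"step.{step}.{kind}.{quote(ident, safe='')}"


def extract_anchors(diagram: RenderedDiagram) -> list[str]:
    """All anchor ids in document order, for either output format."""
    if diagram.format is OutputFormat.TEXT:
        return _ANCHOR_TEXT_RE.findall(diagram.content)
    root = ET.fromstring(diagram.content)
    return [el.get("id") for el in root.iter() if el.get("id")]


def metabolite_sequence(diagram: RenderedDiagram) -> list[str]:
    """Main-path metabolite ids, in rendered step order."""
    hits = []
    for anchor in extract_anchors(diagram):
        m = _METAB_ANCHOR_RE.match(anchor)
        if m:
            hits.append((int(m.group(1)), unquote(m.group(2))))
    return [mid for _, mid in sorted(hits, key=lambda t: t[0])]


# ---------------------------------------------------------------------------
# Shared per-step element assembly. Both renderers consume the same element
# stream so their anchor sets agree by construction.
# ---------------------------------------------------------------------------

@dataclass
class _Element:
    anchor: str
    text: str
    kind: str  # metab | rxn | annotation | candidate | count
    color: str | None = None


def _candidate_elements(
    network: Network, step: int, focal: str, side: Side, limit: int
) -> list[_Element]:
    nb = neighborhood(network, focal)
    entries = nb.precursors if side is Side.PRECURSOR else nb.successors
    kind = "pre" if side is Side.PRECURSOR else "suc"
    label = "precursors" if side is Side.PRECURSOR else "successors"
    out: list[_Element] = []
    for entry in entries[:limit]:
        cls = classify_connection(network, focal, entry.neighbor_id, side)
        met = network.metabolites[entry.neighbor_id]
        extra = f" ({len(entry.reactions)} reactions)" if len(entry.reactions) > 1 else ""
        out.append(
            _Element(
                _anchor(step, kind, entry.neighbor_id),
                f"+ [{CLASS_CODES[cls]}] {met.name}{extra}",
                "candidate",
                CLASS_COLORS[cls],
            )
        )
    hidden = len(entries) - limit
    if hidden > 0:
        out.append(_Element(f"step.{step}.{kind}.more", f"+{hidden} more", "candidate"))
    if out:
        out.insert(0, _Element(f"step.{step}.{kind}", f"{label}:", "candidate"))
    return out


def _step_elements(session, settings: DisplaySettings) -> list[list[_Element]]:
    """One element list per path step, in step order."""
    network: Network = session.network
    path = session.current
    last = len(path.steps) - 1
    blocks: list[list[_Element]] = []
    for i, step in enumerate(path.steps):
        met = network.metabolites[step.metabolite_id]
        block: list[_Element] = []

        show_cands = settings.candidates_mode is CandidatesMode.ALL_STEPS or (
            settings.candidates_mode is CandidatesMode.ENDS_ONLY and i in (0, last)
        )
        if show_cands:
            block.extend(
                _candidate_elements(
                    network, i, met.id, Side.PRECURSOR, settings.candidate_limit
                )
            )

        block.append(_Element(_anchor(i, "metab", met.id), met.name, "metab"))
        if settings.show_structures and met.smiles:
            block.append(
                _Element(_anchor(i, "smiles"), f"structure: {met.smiles}", "annotation")
            )

        if step.successor_reaction is not None and i < last:
            rxn = network.reactions[step.successor_reaction]
            nxt = path.steps[i + 1].metabolite_id
            linking = linking_reactions(network, met.id, nxt)
            if len(linking) > 1:
                block.append(
                    _Element(
                        _anchor(i, "count"),
                        f"{len(linking)} reactions (showing {rxn.id})",
                        "count",
                    )
                )
            block.append(
                _Element(_anchor(i, "rxn", rxn.id), f"{rxn.id}: {rxn.equation}", "rxn")
            )
            if settings.show_ec and rxn.ec_number:
                block.append(
                    _Element(_anchor(i, "ec"), f"EC {rxn.ec_number}", "annotation")
                )
            if settings.show_enzymes_genes and (rxn.enzymes or rxn.genes):
                parts = []
                if rxn.enzymes:
                    parts.append("enzymes: " + ", ".join(rxn.enzymes))
                if rxn.genes:
                    parts.append("genes: " + ", ".join(rxn.genes))
                block.append(_Element(_anchor(i, "enzymes"), "; ".join(parts), "annotation"))
            if settings.show_pathway_links and rxn.pathways:
                block.append(
                    _Element(
                        _anchor(i, "pathways"),
                        "pathways: " + ", ".join(rxn.pathways),
                        "annotation",
                    )
                )
            if settings.show_side_metabolites:
                orient = step.selected_orientation or Orientation.FORWARD
                co_in, co_out = side_metabolites(rxn, met.id, nxt, orient)
                if co_in or co_out:
                    names = lambda ids: ", ".join(
                        network.metabolites[m].name for m in ids
                    )
                    text = "side"
                    if co_in:
                        text += f" reactants: {names(co_in)}"
                    if co_out:
                        text += f"{';' if co_in else ''} products: {names(co_out)}"
                    block.append(_Element(_anchor(i, "side"), text, "annotation"))

        if show_cands:
            block.extend(
                _candidate_elements(
                    network, i, met.id, Side.SUCCESSOR, settings.candidate_limit
                )
            )
        blocks.append(block)
    return blocks


_LEGEND = {cls: f"{code}={cls.value}" for cls, code in CLASS_CODES.items()}


def _render_text(session, blocks: list[list[_Element]]) -> str:
    lines = [f"network: {session.network.id}", f"path: {len(blocks)} step(s)", ""]
    for i, block in enumerate(blocks):
        for el in block:
            if el.kind == "metab":
                lines.append(f"[@{el.anchor}] ({i}) {el.text}")
            elif el.kind == "candidate":
                lines.append(f"    [@{el.anchor}] {el.text}")
            else:
                lines.append(f"    [@{el.anchor}] | {el.text}")
        if i < len(blocks) - 1:
            lines.append("    v")
    lines.append("")
    lines.append("legend: " + "  ".join(_LEGEND[c] for c in ConnectionClass))
    return "\n".join(lines) + "\n"


def _render_svg(session, blocks: list[list[_Element]]) -> str:
    line_h = 18
    n_lines = sum(len(b) for b in blocks) + len(blocks) + 6
    height = n_lines * line_h + 20
    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": "760",
            "height": str(height),
            "font-family": "sans-serif",
            "font-size": "13",
        },
    )
    title = ET.SubElement(svg, "text", {"x": "10", "y": "18", "font-weight": "bold"})
    title.text = f"network: {session.network.id}"
    y = 40
    for i, block in enumerate(blocks):
        group = ET.SubElement(svg, "g", {"id": f"step-group-{i}"})
        for el in block:
            attrs = {"id": el.anchor, "y": str(y)}
            if el.kind == "metab":
                attrs.update({"x": "40", "font-weight": "bold"})
            elif el.kind == "candidate":
                attrs.update({"x": "80", "fill": el.color or "#888888"})
            else:
                attrs.update({"x": "60", "fill": "#333333"})
            node = ET.SubElement(group, "text", attrs)
            node.text = el.text
            y += line_h
        if i < len(blocks) - 1:  # arrow to the next step
            ET.SubElement(
                svg,
                "line",
                {
                    "x1": "45",
                    "y1": str(y - 8),
                    "x2": "45",
                    "y2": str(y + 6),
                    "stroke": "#444444",
                },
            )
            ET.SubElement(
                svg,
                "polygon",
                {
                    "points": f"41,{y + 4} 49,{y + 4} 45,{y + 12}",
                    "fill": "#444444",
                },
            )
            y += line_h
    legend = ET.SubElement(svg, "g", {"id": "legend"})
    x = 10
    y += line_h
    for cls in ConnectionClass:
        node = ET.SubElement(
            legend,
            "text",
            {"x": str(x), "y": str(y), "fill": CLASS_COLORS[cls]},
        )
        node.text = _LEGEND[cls]
        x += 180
    return ET.tostring(svg, encoding="unicode", xml_declaration=True)


def render(
    session,
    settings: DisplaySettings | None = None,
    format: OutputFormat = OutputFormat.TEXT,
) -> RenderedDiagram:
    """Render the session's current path as a vertical pathway diagram.

    ``settings=None`` uses the session's own display settings. Main-path
    metabolites appear top-to-bottom in step order in both formats; toggling
    a single settings flag changes only the elements that flag governs.
    """
    if settings is None:
        settings = session.settings
    blocks = _step_elements(session, settings)
    if format is OutputFormat.TEXT:
        content = _render_text(session, blocks)
    else:
        content = _render_svg(session, blocks)
    return RenderedDiagram(format, content, dict(_LEGEND))


def candidate_panel(network: Network, metabolite_id: str) -> dict:
    """Detail summary for one metabolite: every reaction that connects to it
    with equation, EC number, enzymes, genes and pathways.

    Works for any metabolite, including ubiquitous ones — the currency
    omission applies to neighbor lists, not to direct queries.
    """
    met = network.require_metabolite(metabolite_id)

    def record(rxn: Reaction) -> dict:
        return {
            "id": rxn.id,
            "equation": rxn.equation,
            "ec_number": rxn.ec_number,
            "enzymes": list(rxn.enzymes),
            "genes": list(rxn.genes),
            "pathways": list(rxn.pathways),
            "spontaneous": rxn.spontaneous,
            "direction": rxn.direction.value,
        }

    return {
        "metabolite": {
            "id": met.id,
            "name": met.name,
            "smiles": met.smiles,
            "is_ubiquitous": met.is_ubiquitous,
        },
        "reactions": [
            record(r)
            for r in sorted(network.reactions_of(metabolite_id), key=lambda r: r.id)
        ],
    }
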