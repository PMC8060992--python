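"""Domain model for metabolic reaction networks.

A :class:`Network` is an indexed collection of :class:`Metabolite` and
:class:`Reaction` objects. Reactions carry two participant sides (``left`` and
``right``), a :class:`Direction`, and the annotations a curator attaches to a
reaction in a pathway database: EC number, catalyzing enzymes and genes,
pathway membership, and a spontaneous flag.

Two on-disk carriers are supported:

* a native JSON format (``network-format-v1``) that is lossless for every
  field, including annotations SBML core cannot express;
* SBML Level 3 Version 1 core, the community standard, where annotations not
  expressible in core are carried in XHTML notes and restored best-effort.
"""

from __future__ import annotations

import html
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Direction",
    "Metabolite",
    "Reaction",
    "Network",
    "MetnavError",
    "SchemaError",
    "DanglingReferenceError",
    "UnknownMetaboliteError",
    "DEFAULT_UBIQUITOUS_NAMES",
    "load_native",
    "write_native",
    "load_sbml",
    "write_sbml",
]

NATIVE_FORMAT = "network-format-v1"

#: Currency molecules excluded from neighbor lists by default when the input
#: carrier has no explicit flags (e.g. plain SBML). Matched case-insensitively
#: against metabolite ids and display names; fully overridable per network.
DEFAULT_UBIQUITOUS_NAMES = frozenset(
    {"water", "h2o", "h", "h+", "proton", "phosphate", "pi"}
)


class MetnavError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(MetnavError):
    """An input document does not conform to the expected format."""


class DanglingReferenceError(SchemaError):
    """A reaction references a metabolite id absent from the network."""


class UnknownMetaboliteError(MetnavError, KeyError):
    """A metabolite id was queried that does not exist in the network."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return self.args[0] if self.args else ""


class Direction(Enum):
    """Direction in which a reaction is considered to proceed.

    ``REVERSIBLE`` and ``UNSPECIFIED`` reactions contribute connections in
    both orientations; they are distinguished because a database may record
    that directionality is genuinely unknown rather than known-bidirectional.
    """

    LEFT_TO_RIGHT = "LEFT_TO_RIGHT"
    RIGHT_TO_LEFT = "RIGHT_TO_LEFT"
    REVERSIBLE = "REVERSIBLE"
    UNSPECIFIED = "UNSPECIFIED"


_ARROWS = {
    Direction.LEFT_TO_RIGHT: "->",
    Direction.RIGHT_TO_LEFT: "<-",
    Direction.REVERSIBLE: "<=>",
    Direction.UNSPECIFIED: "<?>",
}


@dataclass
class Metabolite:
    """A small-molecule node of the network."""

    id: str
    name: str = ""
    smiles: str | None = None
    is_ubiquitous: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("metabolite id must be non-empty")
        if not self.name:
            self.name = self.id


def _fmt_coeff(coeff: float) -> str:
    if coeff == int(coeff):
        return str(int(coeff))
    return repr(coeff)


@dataclass
class Reaction:
    """A biochemical reaction with annotations.

    ``left`` and ``right`` are lists of ``(metabolite_id, coefficient)``
    pairs with strictly positive coefficients. Stoichiometry is stored and
    round-tripped but plays no role in neighborhood computation, which is
    defined purely by side membership.
    """

    id: str
    left: list[tuple[str, float]]
    right: list[tuple[str, float]]
    direction: Direction = Direction.LEFT_TO_RIGHT
    equation: str = ""
    ec_number: str | None = None
    enzymes: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    pathways: list[str] = field(default_factory=list)
    spontaneous: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("reaction id must be non-empty")
        self.left = [(m, float(c)) for m, c in self.left]
        self.right = [(m, float(c)) for m, c in self.right]
        for mid, coeff in [*self.left, *self.right]:
            if coeff <= 0:
                raise SchemaError(
                    f"reaction {self.id!r}: coefficient for {mid!r} must be > 0"
                )

    @property
    def left_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.left)

    @property
    def right_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.right)

    def synthesize_equation(self, names: Mapping[str, str] | None = None) -> str:
        """Build a human-readable equation string from the participants.

        Deterministic: participants appear in stored order, coefficients of 1
        are suppressed, and the arrow reflects :attr:`direction`.
        """

        def side(parts: list[tuple[str, float]]) -> str:
            terms = []
            for mid, coeff in parts:
                label = names.get(mid, mid) if names else mid
                terms.append(label if coeff == 1 else f"{_fmt_coeff(coeff)} {label}")
            return " + ".join(terms)

        return f"{side(self.left)} {_ARROWS[self.direction]} {side(self.right)}"


class Network:
    """An indexed, validated collection of metabolites and reactions.

    Participant references are resolved at construction time: a reaction
    naming an unknown metabolite raises :class:`DanglingReferenceError`
    immediately, never at query time. The set of ubiquitous (currency)
    metabolite ids is derived from the ``is_ubiquitous`` flags and may be
    replaced wholesale with :meth:`set_ubiquitous`.
    """

    def __init__(
        self,
        id: str,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction] = (),
    ) -> None:
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise SchemaError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            self.add_reaction(rxn)
        # per-focal neighborhood cache; populated lazily by the neighborhood
        # module, purely an optimization (cached == uncached is tested)
        self._neighborhood_cache: dict[str, object] = {}

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise SchemaError(f"duplicate reaction id {rxn.id!r}")
        for mid in (*rxn.left_ids, *rxn.right_ids):
            if mid not in self.metabolites:
                raise DanglingReferenceError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
        if not rxn.equation:
            rxn.equation = rxn.synthesize_equation(
                {m.id: m.name for m in self.metabolites.values()}
            )
        self.reactions[rxn.id] = rxn
        self._neighborhood_cache = {}
        self._participation = None

    @property
    def ubiquitous_ids(self) -> frozenset[str]:
        return frozenset(
            m.id for m in self.metabolites.values() if m.is_ubiquitous
        )

    def set_ubiquitous(self, ids: Iterable[str]) -> None:
        """Replace the ubiquitous set; unknown ids are rejected."""
        ids = set(ids)
        unknown = ids - self.metabolites.keys()
        if unknown:
            raise UnknownMetaboliteError(
                f"ubiquitous ids not in network: {sorted(unknown)}"
            )
        for met in self.metabolites.values():
            met.is_ubiquitous = met.id in ids
        self._neighborhood_cache = {}

    def require_metabolite(self, mid: str) -> Metabolite:
        try:
            return self.metabolites[mid]
        except KeyError:
            raise UnknownMetaboliteError(
                f"unknown metabolite {mid!r} in network {self.id!r}"
            ) from None

    _participation: dict[str, list[str]] | None = None

    def reactions_of(self, mid: str) -> list[Reaction]:
        """All reactions in which ``mid`` participates on either side."""
        self.require_metabolite(mid)
        if self._participation is None:
            index: dict[str, list[str]] = {}
            for rxn in self.reactions.values():
                for pid in {*rxn.left_ids, *rxn.right_ids}:
                    index.setdefault(pid, []).append(rxn.id)
            self._participation = index
        return [self.reactions[r] for r in self._participation.get(mid, [])]

    # -- structural equality (used by round-trip tests) -------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.id == other.id
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
        )

    def __repr__(self) -> str:
        return (
            f"Network({self.id!r}, {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions)"
        )


# ---------------------------------------------------------------------------
# Native JSON format (network-format-v1): lossless carrier for all fields.
# The JSON Schema document lives in schemas/network-format-v1.json.
# ---------------------------------------------------------------------------

def _require(obj: Mapping, key: str, where: str):
    if key not in obj:
        raise SchemaError(f"{where}: missing required key {key!r}")
    return obj[key]


def network_to_dict(network: Network) -> dict:
    return {
        "format": NATIVE_FORMAT,
        "id": network.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                **({"smiles": m.smiles} if m.smiles is not None else {}),
                "is_ubiquitous": m.is_ubiquitous,
            }
            for m in network.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "left": [[m, c] for m, c in r.left],
                "right": [[m, c] for m, c in r.right],
                "direction": r.direction.value,
                "equation": r.equation,
                **({"ec_number": r.ec_number} if r.ec_number is not None else {}),
                "enzymes": list(r.enzymes),
                "genes": list(r.genes),
                "pathways": list(r.pathways),
                "spontaneous": r.spontaneous,
            }
            for r in network.reactions.values()
        ],
    }


def network_from_dict(doc: Mapping) -> Network:
    if not isinstance(doc, Mapping):
        raise SchemaError("network document must be a JSON object")
    fmt = _require(doc, "format", "document")
    if fmt != NATIVE_FORMAT:
        raise SchemaError(f"unsupported format {fmt!r}; expected {NATIVE_FORMAT!r}")
    mets = []
    for entry in _require(doc, "metabolites", "document"):
        mets.append(
            Metabolite(
                id=_require(entry, "id", "metabolite"),
                name=entry.get("name", ""),
                smiles=entry.get("smiles"),
                is_ubiquitous=bool(entry.get("is_ubiquitous", False)),
            )
        )
    rxns = []
    for entry in _require(doc, "reactions", "document"):
        rid = _require(entry, "id", "reaction")
        try:
            direction = Direction(entry.get("direction", "LEFT_TO_RIGHT"))
        except ValueError:
            raise SchemaError(
                f"reaction {rid!r}: invalid direction {entry.get('direction')!r}"
            ) from None
        rxns.append(
            Reaction(
                id=rid,
                left=[(m, c) for m, c in _require(entry, "left", f"reaction {rid!r}")],
                right=[(m, c) for m, c in _require(entry, "right", f"reaction {rid!r}")],
                direction=direction,
                equation=entry.get("equation", ""),
                ec_number=entry.get("ec_number"),
                enzymes=list(entry.get("enzymes", [])),
                genes=list(entry.get("genes", [])),
                pathways=list(entry.get("pathways", [])),
                spontaneous=bool(entry.get("spontaneous", False)),
            )
        )
    return Network(_require(doc, "id", "document"), mets, rxns)


def load_native(path: str | Path) -> Network:
    """Load a network from a native-format JSON file (UTF-8)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such network file: {path}")
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    return network_from_dict(doc)


def write_native(network: Network, path: str | Path) -> None:
    """Write a network as native-format JSON, re-loadable losslessly."""
    text = json.dumps(network_to_dict(network), ensure_ascii=False, indent=1)
    Path(path).write_text(text + "\n", encoding="utf-8")


def dumps_native(network: Network) -> str:
    return json.dumps(network_to_dict(network), ensure_ascii=False, indent=1) + "\n"


def loads_native(text: str) -> Network:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    return network_from_dict(doc)


# ---------------------------------------------------------------------------
# SBML Level 3 Version 1 core. Annotations SBML core cannot express are
# carried in XHTML notes as a single JSON payload and restored on load.
# ---------------------------------------------------------------------------

_NOTES_KEY = "metnav-annotations"
_NOTES_RE = re.compile(_NOTES_KEY + r":\s*(\{.*\})", re.DOTALL)


def _make_notes(payload: dict) -> str:
    body = html.escape(json.dumps(payload, ensure_ascii=False), quote=False)
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">'
        f"<p>{_NOTES_KEY}: {body}</p></body>"
    )


def _read_notes(element) -> dict:
    if not element.isSetNotes():
        return {}
    match = _NOTES_RE.search(element.getNotesString())
    if not match:
        return {}
    try:
        return json.loads(html.unescape(match.group(1)))
    except json.JSONDecodeError:
        return {}


def _default_ubiquitous(met: Metabolite) -> bool:
    return (
        met.id.lower() in DEFAULT_UBIQUITOUS_NAMES
        or met.name.lower() in DEFAULT_UBIQUITOUS_NAMES
    )


def load_sbml(path: str | Path) -> Network:
    """Load a network from an SBML L3 core document.

    ``reversible="true"`` maps to :attr:`Direction.REVERSIBLE` and
    ``reversible="false"`` to :attr:`Direction.LEFT_TO_RIGHT`, unless a
    notes payload written by :func:`write_sbml` records the original
    direction. Boundary/exchange species are retained as ordinary
    metabolites. Species matching the default currency list are marked
    ubiquitous when no notes flag is present.
    """
    import libsbml

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such SBML file: {path}")
    doc = libsbml.readSBMLFromString(path.read_text(encoding="utf-8"))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SchemaError(f"{path}: SBML parse failure: {first.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise SchemaError(f"{path}: document contains no model")
    if model.getNumSpecies() == 0:
        raise SchemaError(f"{path}: model has zero species")
    net_id = _read_notes(model).get("id") or model.getId() or path.stem

    mets = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        notes = _read_notes(sp)
        met = Metabolite(
            id=notes.get("id", sp.getId()),
            name=sp.getName() or "",
            smiles=notes.get("smiles"),
        )
        if "is_ubiquitous" in notes:
            met.is_ubiquitous = bool(notes["is_ubiquitous"])
        else:
            met.is_ubiquitous = _default_ubiquitous(met)
        mets.append(met)

    rxns = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        notes = _read_notes(rx)
        left = [
            (rx.getReactant(j).getSpecies(), rx.getReactant(j).getStoichiometry())
            for j in range(rx.getNumReactants())
        ]
        right = [
            (rx.getProduct(j).getSpecies(), rx.getProduct(j).getStoichiometry())
            for j in range(rx.getNumProducts())
        ]
        if "direction" in notes:
            direction = Direction(notes["direction"])
        elif rx.getReversible():
            direction = Direction.REVERSIBLE
        else:
            direction = Direction.LEFT_TO_RIGHT
        # species ids may have been sanitized on export; map back via notes
        id_map = notes.get("participant_ids", {})
        left = [(id_map.get(m, m), c) for m, c in left]
        right = [(id_map.get(m, m), c) for m, c in right]
        rxns.append(
            Reaction(
                id=notes.get("id", rx.getId()),
                left=left,
                right=right,
                direction=direction,
                equation=notes.get("equation", ""),
                ec_number=notes.get("ec_number"),
                enzymes=list(notes.get("enzymes", [])),
                genes=list(notes.get("genes", [])),
                pathways=list(notes.get("pathways", [])),
                spontaneous=bool(notes.get("spontaneous", False)),
            )
        )
    return Network(net_id, mets, rxns)


_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _sid(raw: str) -> str:
    """Sanitize an arbitrary id into a valid SBML SId."""
    if _SID_RE.match(raw):
        return raw
    out = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not out or not re.match(r"[A-Za-z_]", out[0]):
        out = "x_" + out
    return out


def write_sbml(network: Network, path: str | Path) -> None:
    """Write a network as SBML L3V1 core.

    Direction semantics not expressible as the SBML ``reversible`` boolean
    (``UNSPECIFIED``, ``RIGHT_TO_LEFT``) and all extended annotations are
    recorded in notes so :func:`load_sbml` can restore them.
    """
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(_sid(network.id))
    if _sid(network.id) != network.id:
        model.setNotes(_make_notes({"id": network.id}))
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    sid_of: dict[str, str] = {}
    used: set[str] = set()
    for met in network.metabolites.values():
        sid = _sid(met.id)
        while sid in used:
            sid += "_"
        used.add(sid)
        sid_of[met.id] = sid
        sp = model.createSpecies()
        sp.setId(sid)
        sp.setName(met.name)
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        payload: dict = {"is_ubiquitous": met.is_ubiquitous}
        if met.smiles is not None:
            payload["smiles"] = met.smiles
        if sid != met.id:
            payload["id"] = met.id
        sp.setNotes(_make_notes(payload))

    used_r: set[str] = set()
    for rxn in network.reactions.values():
        rid = _sid(rxn.id)
        while rid in used_r or rid in used:
            rid += "_"
        used_r.add(rid)
        rx = model.createReaction()
        rx.setId(rid)
        rx.setReversible(
            rxn.direction in (Direction.REVERSIBLE, Direction.UNSPECIFIED)
        )
        rx.setFast(False)
        for mid, coeff in rxn.left:
            ref = rx.createReactant()
            ref.setSpecies(sid_of[mid])
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
        for mid, coeff in rxn.right:
            ref = rx.createProduct()
            ref.setSpecies(sid_of[mid])
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
        payload = {
            "direction": rxn.direction.value,
            "equation": rxn.equation,
            "enzymes": rxn.enzymes,
            "genes": rxn.genes,
            "pathways": rxn.pathways,
            "spontaneous": rxn.spontaneous,
        }
        if rxn.ec_number is not None:
            payload["ec_number"] = rxn.ec_number
        if rid != rxn.id:
            payload["id"] = rxn.id
        renamed = {
            sid_of[m]: m
            for m in {*rxn.left_ids, *rxn.right_ids}
            if sid_of[m] != m
        }
        if renamed:
            payload["participant_ids"] = renamed
        rx.setNotes(_make_notes(payload))

    Path(path).write_text(
        libsbml.writeSBMLToString(doc), encoding="utf-8"
    )
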