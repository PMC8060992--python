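"""Precursor/successor neighborhoods of a metabolite.

The metabolic neighborhood of a focal metabolite *M* collects every
metabolite *P* for which some reaction has *P* on an effective reactant side
and *M* on the corresponding product side (the precursors), and symmetrically
every *S* reachable with *M* as reactant (the successors). Reversible and
unspecified-direction reactions contribute both orientations, so the same
neighbor may legitimately appear in both lists. Ubiquitous currency
metabolites (water, H+, phosphate, ...) are omitted from neighbor lists —
but not from side-metabolite listings, where they remain legitimate reaction
participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .model import Direction, MetnavError, Network, Reaction

__all__ = [
    "Orientation",
    "Side",
    "ConnectionClass",
    "NeighborEntry",
    "Neighborhood",
    "NotConnectedError",
    "effective_orientations",
    "sides_for",
    "effective_sides",
    "neighborhood",
    "linking_reactions",
    "classify_connection",
    "side_metabolites",
]


class Orientation(Enum):
    """Which side of a reaction acts as the reactant side.

    ``FORWARD``: left side consumed, right side produced. ``REVERSE``: the
    opposite. Reversible/unspecified reactions admit both.
    """

    FORWARD = "F"
    REVERSE = "R"


class Side(Enum):
    """Which neighbor list a connection belongs to, relative to the focal."""

    PRECURSOR = "precursor"
    SUCCESSOR = "successor"


class ConnectionClass(Enum):
    """Display coding for the link between a focal metabolite and a neighbor.

    Precedence when several could apply: MULTIPLE (more than one linking
    reaction — a property of the reaction set, so it dominates), then
    SPONTANEOUS, then BIDIRECTIONAL (reversible or unspecified direction),
    else UNIDIRECTIONAL.
    """

    UNIDIRECTIONAL = "unidirectional"
    BIDIRECTIONAL = "bidirectional"
    SPONTANEOUS = "spontaneous"
    MULTIPLE = "multiple"


class NotConnectedError(MetnavError):
    """The queried pair is not connected on the stated side."""


@dataclass(frozen=True)
class NeighborEntry:
    """One neighbor plus every reaction linking it to the focal metabolite
    in the relevant direction (sorted by reaction id; never empty)."""

    neighbor_id: str
    reactions: tuple[str, ...]


@dataclass(frozen=True)
class Neighborhood:
    focal_id: str
    precursors: tuple[NeighborEntry, ...]
    successors: tuple[NeighborEntry, ...]

    def entry(self, side: Side, neighbor_id: str) -> NeighborEntry:
        entries = self.precursors if side is Side.PRECURSOR else self.successors
        for e in entries:
            if e.neighbor_id == neighbor_id:
                return e
        raise NotConnectedError(
            f"{neighbor_id!r} is not a {side.value} of {self.focal_id!r}"
        )

    def has(self, side: Side, neighbor_id: str) -> bool:
        entries = self.precursors if side is Side.PRECURSOR else self.successors
        return any(e.neighbor_id == neighbor_id for e in entries)


def effective_orientations(reaction: Reaction) -> tuple[Orientation, ...]:
    if reaction.direction is Direction.LEFT_TO_RIGHT:
        return (Orientation.FORWARD,)
    if reaction.direction is Direction.RIGHT_TO_LEFT:
        return (Orientation.REVERSE,)
    return (Orientation.FORWARD, Orientation.REVERSE)


def sides_for(reaction: Reaction, orientation: Orientation) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(reactant-side ids, product-side ids) under the given orientation."""
    if orientation is Orientation.FORWARD:
        return reaction.left_ids, reaction.right_ids
    return reaction.right_ids, reaction.left_ids


def effective_sides(reaction: Reaction) -> set[tuple[frozenset[str], frozenset[str]]]:
    """The set of (reactants, products) id-set pairs the reaction can realize.

    A one-directional reaction yields a single pair; reversible and
    unspecified-direction reactions yield both assignments.
    """
    return {
        (frozenset(r), frozenset(p))
        for r, p in (
            sides_for(reaction, o) for o in effective_orientations(reaction)
        )
    }


def _compute(network: Network, focal_id: str) -> Neighborhood:
    ubiq = network.ubiquitous_ids
    pre: dict[str, set[str]] = {}
    suc: dict[str, set[str]] = {}
    for rxn in network.reactions_of(focal_id):
        for orient in effective_orientations(rxn):
            reactants, products = sides_for(rxn, orient)
            if focal_id in products:
                for p in reactants:
                    if p != focal_id and p not in ubiq:
                        pre.setdefault(p, set()).add(rxn.id)
            if focal_id in reactants:
                for s in products:
                    if s != focal_id and s not in ubiq:
                        suc.setdefault(s, set()).add(rxn.id)

    def ordered(table: dict[str, set[str]]) -> tuple[NeighborEntry, ...]:
        key = lambda mid: (network.metabolites[mid].name, mid)
        return tuple(
            NeighborEntry(mid, tuple(sorted(table[mid])))
            for mid in sorted(table, key=key)
        )

    return Neighborhood(focal_id, ordered(pre), ordered(suc))


def neighborhood(network: Network, metabolite_id: str) -> Neighborhood:
    """Compute (and cache) the neighborhood of ``metabolite_id``.

    Entries are sorted by neighbor display name then id; each entry lists
    every linking reaction. The focal metabolite is never its own neighbor,
    and ubiquitous metabolites never appear. Caching is per focal metabolite
    and has no semantic effect.
    """
    network.require_metabolite(metabolite_id)
    cached = network._neighborhood_cache.get(metabolite_id)
    if cached is None:
        cached = _compute(network, metabolite_id)
        network._neighborhood_cache[metabolite_id] = cached
    return cached  # type: ignore[return-value]


def linking_reactions(
    network: Network, reactant_id: str, product_id: str
) -> tuple[str, ...]:
    """All reactions linking ``reactant_id`` → ``product_id`` in some
    effective orientation, sorted by id.

    Unlike neighbor lists, this is not subject to the currency omission: a
    path may legitimately start at a ubiquitous metabolite, and its links
    are still queryable.
    """
    network.require_metabolite(product_id)
    out = []
    for rxn in network.reactions_of(reactant_id):
        for orient in effective_orientations(rxn):
            reactants, products = sides_for(rxn, orient)
            if reactant_id in reactants and product_id in products:
                out.append(rxn.id)
                break
    return tuple(sorted(out))


def classify_connection(
    network: Network, focal_id: str, neighbor_id: str, side: Side
) -> ConnectionClass:
    """Classify the focal↔neighbor connection on the stated side.

    Depends only on the multiset of linking reactions: more than one linking
    reaction is MULTIPLE; a single spontaneous reaction is SPONTANEOUS; a
    single reversible/unspecified reaction is BIDIRECTIONAL; otherwise
    UNIDIRECTIONAL.
    """
    entry = neighborhood(network, focal_id).entry(side, neighbor_id)
    if len(entry.reactions) > 1:
        return ConnectionClass.MULTIPLE
    rxn = network.reactions[entry.reactions[0]]
    if rxn.spontaneous:
        return ConnectionClass.SPONTANEOUS
    if rxn.direction in (Direction.REVERSIBLE, Direction.UNSPECIFIED):
        return ConnectionClass.BIDIRECTIONAL
    return ConnectionClass.UNIDIRECTIONAL


def side_metabolites(
    reaction: Reaction, main_in: str, main_out: str, orientation: Orientation
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Co-reactants and co-products of a displayed step.

    Under ``orientation``, ``main_in`` must sit on the effective reactant
    side and ``main_out`` on the effective product side. The returned lists
    are the remaining participants of each side, in stored order; ubiquitous
    metabolites ARE included here (the currency omission applies only to
    neighbor lists).
    """
    if orientation not in effective_orientations(reaction):
        raise NotConnectedError(
            f"reaction {reaction.id!r} does not admit orientation {orientation.value}"
        )
    reactants, products = sides_for(reaction, orientation)
    if main_in not in reactants:
        raise NotConnectedError(
            f"{main_in!r} is not on the reactant side of {reaction.id!r} "
            f"under orientation {orientation.value}"
        )
    if main_out not in products:
        raise NotConnectedError(
            f"{main_out!r} is not on the product side of {reaction.id!r} "
            f"under orientation {orientation.value}"
        )
    co_reactants = tuple(m for m in reactants if m != main_in)
    co_products = tuple(m for m in products if m != main_out)
    return co_reactants, co_products
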