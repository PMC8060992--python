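"""The interactive exploration state machine.

A session holds one linear path — an ordered list of steps, each a metabolite
plus an optional successor reaction linking it to the next step — together
with a history of previously displayed paths and the display settings.
Operations mirror the exploration gestures: extend the path at either end,
replace a portion anchored at an interior metabolite (the displaced path is
saved to history), pick which of several linking reactions is displayed,
restore a previous path, and serialize the whole state to a shareable link
string.

Cycles are allowed: a metabolite may appear more than once in a path, since
forbidding repeats would silently block legal biochemistry such as futile
cycles.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from urllib.parse import quote, unquote

from .model import MetnavError, Network
from .neighborhood import (
    NotConnectedError,
    Orientation,
    Side,
    effective_orientations,
    linking_reactions,
    neighborhood,
    sides_for,
)
from .render import DisplaySettings

__all__ = [
    "PathStep",
    "Path",
    "ExplorerSession",
    "LinkError",
    "NetworkMismatchError",
    "start_session",
    "add_metabolite",
    "select_reaction",
    "restore_previous",
    "validate_path",
    "encode_link",
    "decode_link",
]

LINK_VERSION = "v1"


class LinkError(MetnavError):
    """A link string is malformed or cannot be decoded."""


class NetworkMismatchError(LinkError):
    """A link string was produced against a different network."""


@dataclass
class PathStep:
    metabolite_id: str
    successor_reaction: str | None = None
    selected_orientation: Orientation | None = None


@dataclass
class Path:
    """An ordered, non-empty list of steps. A single-metabolite path is the
    legal starting state; the last step carries no successor reaction."""

    steps: list[PathStep]

    def __post_init__(self) -> None:
        if not self.steps:
            raise MetnavError("a path must contain at least one step")

    @property
    def metabolite_ids(self) -> list[str]:
        return [s.metabolite_id for s in self.steps]

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class ExplorerSession:
    network: Network
    current: Path
    previous_paths: list[Path] = field(default_factory=list)
    settings: DisplaySettings = field(default_factory=DisplaySettings)


def start_session(network: Network, start_id: str) -> ExplorerSession:
    """Begin exploration at ``start_id``: a one-step path, empty history,
    default display settings."""
    network.require_metabolite(start_id)
    return ExplorerSession(network, Path([PathStep(start_id)]))


def _link_orientation(
    network: Network, reaction_id: str, reactant: str, product: str
) -> Orientation:
    """First effective orientation placing ``reactant``→``product``.

    Deterministic tie-break: FORWARD is tried before REVERSE, so a reversible
    reaction with both assignments valid always resolves the same way.
    """
    rxn = network.reactions[reaction_id]
    for orient in effective_orientations(rxn):
        reactants, products = sides_for(rxn, orient)
        if reactant in reactants and product in products:
            return orient
    raise NotConnectedError(
        f"reaction {reaction_id!r} does not link {reactant!r} -> {product!r}"
    )


def _linked_step(
    network: Network, reactant: str, product: str, reaction_id: str
) -> PathStep:
    return PathStep(
        reactant,
        successor_reaction=reaction_id,
        selected_orientation=_link_orientation(network, reaction_id, reactant, product),
    )


def add_metabolite(
    session: ExplorerSession,
    anchor_index: int,
    neighbor_id: str,
    side: Side,
    reaction_id: str | None = None,
) -> ExplorerSession:
    """Add ``neighbor_id`` to the path at the step ``anchor_index``.

    A successor added at the last step or a precursor added at the first step
    extends the path in that direction. At any other anchor the operation is
    a replacement: the portion of the path on the far side of the anchor is
    discarded (downstream for a successor, upstream for a precursor), the new
    step is attached, and the displaced path is saved to history. When
    several reactions link the pair and none is specified, the
    lexicographically smallest reaction id is used.
    """
    path = session.current
    if not 0 <= anchor_index < len(path):
        raise MetnavError(
            f"anchor index {anchor_index} out of range for path of length {len(path)}"
        )
    anchor_id = path.steps[anchor_index].metabolite_id
    entry = neighborhood(session.network, anchor_id).entry(side, neighbor_id)
    if reaction_id is None:
        reaction_id = min(entry.reactions)
    elif reaction_id not in entry.reactions:
        raise NotConnectedError(
            f"reaction {reaction_id!r} does not link {anchor_id!r} and "
            f"{neighbor_id!r} on the {side.value} side"
        )

    old = copy.deepcopy(path)
    if side is Side.SUCCESSOR:
        new_steps = path.steps[: anchor_index + 1]
        new_steps[-1] = _linked_step(session.network, anchor_id, neighbor_id, reaction_id)
        new_steps.append(PathStep(neighbor_id))
        extension = anchor_index == len(path) - 1
    else:
        new_steps = [_linked_step(session.network, neighbor_id, anchor_id, reaction_id)]
        new_steps.extend(path.steps[anchor_index:])
        extension = anchor_index == 0

    new_path = Path(new_steps)
    if not extension:
        if _paths_equal(new_path, old):
            return session  # no-op replacement: keep history duplicate-free
        session.previous_paths.insert(0, old)
    session.current = new_path
    return session


def _paths_equal(a: Path, b: Path) -> bool:
    return a.steps == b.steps


def select_reaction(
    session: ExplorerSession, step_index: int, reaction_id: str
) -> ExplorerSession:
    """Choose which of several linking reactions is displayed for the step
    from ``step_index`` to the next step. Idempotent; topology unchanged."""
    path = session.current
    if not 0 <= step_index < len(path) - 1:
        raise MetnavError(
            f"step {step_index} has no successor link in a path of length {len(path)}"
        )
    step = path.steps[step_index]
    next_id = path.steps[step_index + 1].metabolite_id
    if reaction_id not in linking_reactions(
        session.network, step.metabolite_id, next_id
    ):
        raise NotConnectedError(
            f"reaction {reaction_id!r} does not link {step.metabolite_id!r} "
            f"and {next_id!r}"
        )
    step.successor_reaction = reaction_id
    step.selected_orientation = _link_orientation(
        session.network, reaction_id, step.metabolite_id, next_id
    )
    return session


def restore_previous(session: ExplorerSession, history_index: int) -> ExplorerSession:
    """Swap the current path with a history entry (most recent first).

    A swap rather than a copy: restoring the same slot twice returns to the
    original state, supporting switching back and forth with bounded memory.
    """
    if not 0 <= history_index < len(session.previous_paths):
        raise MetnavError(
            f"history index {history_index} out of range "
            f"({len(session.previous_paths)} previous paths)"
        )
    session.current, session.previous_paths[history_index] = (
        session.previous_paths[history_index],
        session.current,
    )
    return session


def validate_path(network: Network, path: Path) -> list[str]:
    """Check a path against a network; returns human-readable violations.

    Empty iff every metabolite resolves, every adjacent pair is linked by its
    recorded reaction in its recorded orientation, and the last step carries
    no successor reaction.
    """
    violations: list[str] = []
    for i, step in enumerate(path.steps):
        if step.metabolite_id not in network.metabolites:
            violations.append(f"step {i}: unknown metabolite {step.metabolite_id!r}")
    for i, step in enumerate(path.steps[:-1]):
        nxt = path.steps[i + 1].metabolite_id
        if step.successor_reaction is None:
            violations.append(
                f"step {i}: missing successor reaction to {nxt!r}"
            )
            continue
        rxn = network.reactions.get(step.successor_reaction)
        if rxn is None:
            violations.append(
                f"step {i}: unknown reaction {step.successor_reaction!r}"
            )
            continue
        orient = step.selected_orientation
        if orient is None or orient not in effective_orientations(rxn):
            violations.append(
                f"step {i}: reaction {rxn.id!r} does not admit the recorded "
                f"orientation"
            )
            continue
        reactants, products = sides_for(rxn, orient)
        if step.metabolite_id not in reactants or nxt not in products:
            violations.append(
                f"step {i}: reaction {rxn.id!r} does not link "
                f"{step.metabolite_id!r} -> {nxt!r} in the recorded orientation"
            )
    last = path.steps[-1]
    if last.successor_reaction is not None:
        violations.append(
            f"step {len(path) - 1}: dangling successor reaction "
            f"{last.successor_reaction!r} on the last step"
        )
    return violations


# ---------------------------------------------------------------------------
# Link strings: v1;<network-id>;<met>,<rxn*O>,<met>,...;<settings>
# Every id is percent-encoded with no safe characters, so the separators
# ';' ',' '*' (all escaped inside data) are unambiguous. The orientation
# marker after '*' is F or R. Stable across runs: no timestamps, no hashes.
# ---------------------------------------------------------------------------

def _q(raw: str) -> str:
    return quote(raw, safe="")


def encode_link(session: ExplorerSession) -> str:
    """Serialize the current path, reaction selections, and settings to a
    URL-safe string. Deterministic: equal sessions yield equal links."""
    tokens: list[str] = []
    for step in session.current.steps:
        tokens.append(_q(step.metabolite_id))
        if step.successor_reaction is not None:
            orient = step.selected_orientation or Orientation.FORWARD
            tokens.append(f"{_q(step.successor_reaction)}*{orient.value}")
    return ";".join(
        [
            LINK_VERSION,
            _q(session.network.id),
            ",".join(tokens),
            session.settings.to_code(),
        ]
    )


def decode_link(network: Network, link: str) -> ExplorerSession:
    """Rebuild a session from a link string against ``network``.

    The network id must match the one recorded in the link, and the decoded
    path must validate against the network (a reaction removed since the
    link was generated is reported by id).
    """
    parts = link.split(";")
    if len(parts) != 4:
        raise LinkError(f"malformed link: expected 4 ';'-separated fields, got {len(parts)}")
    version, net_token, path_token, settings_token = parts
    if version != LINK_VERSION:
        raise LinkError(f"unsupported link version {version!r}")
    net_id = unquote(net_token)
    if net_id != network.id:
        raise NetworkMismatchError(
            f"link was generated for network {net_id!r}, not {network.id!r}"
        )
    if not path_token:
        raise LinkError("malformed link: empty path")

    steps: list[PathStep] = []
    pending: tuple[str, Orientation] | None = None
    for i, token in enumerate(path_token.split(",")):
        if i % 2 == 0:
            step = PathStep(unquote(token))
            if pending is not None:
                steps[-1].successor_reaction = pending[0]
                steps[-1].selected_orientation = pending[1]
                pending = None
            steps.append(step)
        else:
            rxn_part, sep, orient_part = token.partition("*")
            if not sep or orient_part not in ("F", "R"):
                raise LinkError(f"malformed link: bad reaction token {token!r}")
            pending = (unquote(rxn_part), Orientation(orient_part))
    if pending is not None:
        raise LinkError("malformed link: path ends with a reaction token")

    path = Path(steps)
    violations = validate_path(network, path)
    if violations:
        raise LinkError(
            "link does not validate against network "
            f"{network.id!r}: " + "; ".join(violations)
        )
    try:
        settings = DisplaySettings.from_code(settings_token)
    except ValueError as exc:
        raise LinkError(f"malformed link: {exc}") from None
    return ExplorerSession(network, path, settings=settings)
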