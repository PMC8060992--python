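"""Path state machine: extension, replacement, history, selection,
restoration, validation, and link-string serialization."""

import random

import pytest
from hypothesis import given, settings as hsettings, strategies as st

from metnav import (
    DisplaySettings,
    LinkError,
    Metabolite,
    MetnavError,
    Network,
    NetworkMismatchError,
    NotConnectedError,
    Orientation,
    Reaction,
    Side,
    add_metabolite,
    decode_link,
    encode_link,
    linking_reactions,
    neighborhood,
    restore_previous,
    select_reaction,
    start_session,
    validate_path,
)
from metnav.fixtures import FixtureSpec, generate_network
from metnav.session import Path, PathStep


def path_ids(session):
    return session.current.metabolite_ids


def make_abc(chain_network):
    """Session with current path A -> B -> C."""
    s = start_session(chain_network, "A")
    add_metabolite(s, 0, "B", Side.SUCCESSOR)
    add_metabolite(s, 1, "C", Side.SUCCESSOR)
    return s


def test_start_session(chain_network):
    s = start_session(chain_network, "A")
    assert path_ids(s) == ["A"]
    assert s.previous_paths == []
    assert validate_path(chain_network, s.current) == []


def test_extension_at_ends_never_touches_history(chain_network):
    s = make_abc(chain_network)
    assert path_ids(s) == ["A", "B", "C"]
    assert s.previous_paths == []
    add_metabolite(s, 2, "D", Side.SUCCESSOR)  # successor of last: extend
    assert path_ids(s) == ["A", "B", "C", "D"]
    assert s.previous_paths == []


def test_replacement_downstream_saves_history(chain_network):
    s = make_abc(chain_network)
    add_metabolite(s, 1, "D", Side.SUCCESSOR)  # successor of intermediate B
    assert path_ids(s) == ["A", "B", "D"]
    assert [p.metabolite_ids for p in s.previous_paths] == [["A", "B", "C"]]
    assert validate_path(chain_network, s.current) == []


def test_replacement_upstream_saves_history(chain_network):
    s = make_abc(chain_network)
    add_metabolite(s, 1, "P", Side.PRECURSOR)  # precursor of intermediate B
    assert path_ids(s) == ["P", "B", "C"]
    assert [p.metabolite_ids for p in s.previous_paths] == [["A", "B", "C"]]
    assert validate_path(chain_network, s.current) == []


def test_prepend_at_first_step_is_extension(chain_network):
    s = start_session(chain_network, "B")
    add_metabolite(s, 0, "A", Side.PRECURSOR)
    assert path_ids(s) == ["A", "B"]
    assert s.previous_paths == []
    assert s.current.steps[0].successor_reaction == "RAB"


def test_noop_replacement_leaves_history_untouched(chain_network):
    s = make_abc(chain_network)
    add_metabolite(s, 1, "C", Side.SUCCESSOR, "RBC")  # rebuilds A,B,C exactly
    assert path_ids(s) == ["A", "B", "C"]
    assert s.previous_paths == []


def test_add_rejects_unconnected_neighbor(chain_network):
    s = make_abc(chain_network)
    with pytest.raises(NotConnectedError):
        add_metabolite(s, 2, "A", Side.SUCCESSOR)
    assert path_ids(s) == ["A", "B", "C"]  # unchanged on error


def test_add_rejects_bad_anchor(chain_network):
    s = make_abc(chain_network)
    with pytest.raises(MetnavError, match="anchor"):
        add_metabolite(s, 5, "D", Side.SUCCESSOR)


def test_default_reaction_is_lexicographically_smallest(chain_network):
    s = start_session(chain_network, "B")
    add_metabolite(s, 0, "D", Side.SUCCESSOR)
    assert s.current.steps[0].successor_reaction == "RBD"


def test_select_reaction_changes_link_only():
    mets = [Metabolite("X"), Metabolite("Y")]
    rxns = [
        Reaction("R5", [("X", 1)], [("Y", 1)]),
        Reaction("R9", [("X", 1)], [("Y", 1)]),
    ]
    net = Network("n", mets, rxns)
    s = start_session(net, "X")
    add_metabolite(s, 0, "Y", Side.SUCCESSOR)
    assert s.current.steps[0].successor_reaction == "R5"  # default
    select_reaction(s, 0, "R9")
    assert s.current.steps[0].successor_reaction == "R9"
    assert path_ids(s) == ["X", "Y"]
    select_reaction(s, 0, "R9")  # idempotent
    assert s.current.steps[0].successor_reaction == "R9"
    with pytest.raises(MetnavError):
        select_reaction(s, 0, "Rabsent")
    assert s.current.steps[0].successor_reaction == "R9"


def test_restore_swaps_and_is_involutive(chain_network):
    s = make_abc(chain_network)
    add_metabolite(s, 1, "D", Side.SUCCESSOR)  # history: [A,B,C]
    restore_previous(s, 0)
    assert path_ids(s) == ["A", "B", "C"]
    assert [p.metabolite_ids for p in s.previous_paths] == [["A", "B", "D"]]
    restore_previous(s, 0)
    assert path_ids(s) == ["A", "B", "D"]
    assert [p.metabolite_ids for p in s.previous_paths] == [["A", "B", "C"]]


def test_restore_empty_history_raises(chain_network):
    s = start_session(chain_network, "A")
    with pytest.raises(MetnavError, match="history"):
        restore_previous(s, 0)


def test_cycles_are_allowed():
    mets = [Metabolite(x) for x in "AB"]
    rxns = [
        Reaction("R1", [("A", 1)], [("B", 1)]),
        Reaction("R2", [("B", 1)], [("A", 1)]),
    ]
    net = Network("cycle", mets, rxns)
    s = start_session(net, "A")
    add_metabolite(s, 0, "B", Side.SUCCESSOR)
    add_metabolite(s, 1, "A", Side.SUCCESSOR)
    assert path_ids(s) == ["A", "B", "A"]
    assert validate_path(net, s.current) == []


# -- validate_path ---------------------------------------------------------


def test_validate_flags_wrong_orientation(chain_network):
    path = Path(
        [
            PathStep("B", "RAB", Orientation.FORWARD),  # RAB goes A->B, not B->A
            PathStep("A"),
        ]
    )
    violations = validate_path(chain_network, path)
    assert any("RAB" in v for v in violations)


def test_validate_flags_dangling_terminal_reaction(chain_network):
    path = Path([PathStep("A", "RAB", Orientation.FORWARD)])
    violations = validate_path(chain_network, path)
    assert any("dangling" in v for v in violations)


def test_validate_flags_unknown_ids(chain_network):
    path = Path([PathStep("A", "Rghost", Orientation.FORWARD), PathStep("GHOST")])
    violations = validate_path(chain_network, path)
    assert any("Rghost" in v for v in violations)
    assert any("GHOST" in v for v in violations)


# -- link serialization ----------------------------------------------------


def test_link_round_trip_simple(chain_network):
    s = make_abc(chain_network)
    s.settings.show_ec = False
    link = encode_link(s)
    s2 = decode_link(chain_network, link)
    assert s2.current == s.current
    assert s2.settings == s.settings
    assert s2.previous_paths == []  # history is not part of the link


def test_link_deterministic(chain_network):
    assert encode_link(make_abc(chain_network)) == encode_link(make_abc(chain_network))


def test_link_network_mismatch_names_network(chain_network, toy_network):
    link = encode_link(make_abc(chain_network))
    with pytest.raises(NetworkMismatchError, match="chain"):
        decode_link(toy_network, link)


def test_link_truncated_is_malformed(chain_network):
    link = encode_link(make_abc(chain_network))
    with pytest.raises(LinkError):
        decode_link(chain_network, link[: len(link) // 2])
    with pytest.raises(LinkError):
        decode_link(chain_network, "")


def test_link_with_removed_reaction_names_it(chain_network):
    link = encode_link(make_abc(chain_network))
    smaller = Network(
        "chain",
        [Metabolite(x) for x in "ABCDP"],
        [Reaction("RAB", [("A", 1)], [("B", 1)])],  # RBC removed
    )
    with pytest.raises(LinkError, match="RBC"):
        decode_link(smaller, link)


@hsettings(derandomize=True)
@given(
    st.builds(
        DisplaySettings,
        show_side_metabolites=st.booleans(),
        show_enzymes_genes=st.booleans(),
        show_ec=st.booleans(),
        show_structures=st.booleans(),
        show_pathway_links=st.booleans(),
        candidate_limit=st.integers(min_value=0, max_value=999),
    )
)
def test_settings_code_round_trip(settings):
    assert DisplaySettings.from_code(settings.to_code()) == settings


@hsettings(max_examples=50, derandomize=True)
@given(
    ids=st.lists(
        st.text(min_size=1, max_size=8).filter(lambda s: s.strip()),
        min_size=2, max_size=2, unique=True,
    ),
    rxn_id=st.text(min_size=1, max_size=8),
)
def test_link_round_trip_survives_hostile_ids(ids, rxn_id):
    """Percent-encoding keeps ids containing ';', ',', '*' or '%' safe."""
    a, b = ids
    net = Network(
        "net;with,separators*%",
        [Metabolite(a), Metabolite(b)],
        [Reaction(rxn_id, [(a, 1)], [(b, 1)])],
    )
    s = start_session(net, a)
    add_metabolite(s, 0, b, Side.SUCCESSOR)
    s2 = decode_link(net, encode_link(s))
    assert s2.current == s.current


# -- random operation sequences (state-machine soundness) ------------------


def random_walk(network, rng, n_ops=8):
    """Drive a session with random valid add/select/restore operations,
    checking validity after every single operation."""
    start = rng.choice(sorted(network.metabolites))
    session = start_session(network, start)
    replacements = 0
    for _ in range(n_ops):
        ops = ["add"]
        if len(session.current) > 1:
            ops.append("select")
        if session.previous_paths:
            ops.append("restore")
        op = rng.choice(ops)
        if op == "add":
            anchor = rng.randrange(len(session.current))
            nb = neighborhood(network, session.current.steps[anchor].metabolite_id)
            side = rng.choice([Side.PRECURSOR, Side.SUCCESSOR])
            entries = nb.precursors if side is Side.PRECURSOR else nb.successors
            if not entries:
                continue
            entry = rng.choice(entries)
            rxn = rng.choice(entry.reactions) if rng.random() < 0.5 else None
            before = len(session.previous_paths)
            old_ids = list(session.current.metabolite_ids)
            extension = (side is Side.SUCCESSOR and anchor == len(session.current) - 1) or (
                side is Side.PRECURSOR and anchor == 0
            )
            add_metabolite(session, anchor, entry.neighbor_id, side, rxn)
            after = len(session.previous_paths)
            if extension:
                assert after == before  # pure end-extensions never touch history
            elif session.current.metabolite_ids != old_ids:
                assert after == before + 1  # every replacement grows history by one
                replacements += 1
        elif op == "select":
            idx = rng.randrange(len(session.current) - 1)
            step = session.current.steps[idx]
            candidates = linking_reactions(
                network, step.metabolite_id, session.current.steps[idx + 1].metabolite_id
            )
            select_reaction(session, idx, rng.choice(candidates))
        else:
            restore_previous(session, rng.randrange(len(session.previous_paths)))
        assert validate_path(network, session.current) == []
    for prev in session.previous_paths:
        assert validate_path(network, prev) == []
    return session, replacements


def test_random_operation_sequences_stay_valid():
    net = generate_network(FixtureSpec(n_metabolites=40, n_reactions=120, seed=11))
    rng = random.Random(2024)
    total_repl = 0
    for _ in range(200):
        _, repl = random_walk(net, rng)
        total_repl += repl
    assert total_repl > 0  # the walk does exercise replacement


def test_random_walk_links_round_trip():
    net = generate_network(FixtureSpec(n_metabolites=40, n_reactions=120, seed=5))
    rng = random.Random(99)
    for _ in range(100):
        session, _ = random_walk(net, rng, n_ops=6)
        again = decode_link(net, encode_link(session))
        assert again.current == session.current
        assert again.settings == session.settings
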