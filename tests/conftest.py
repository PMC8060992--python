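import pytest

from metnav import Direction, Metabolite, Network, Reaction


def brute_force_neighborhoods(network):
    """Independent oracle: one global pass over all (reaction, effective
    side) pairs, accumulating precursor/successor maps for every metabolite.

    Returns (pre, suc): dicts mapping focal id -> {neighbor id -> set of
    linking reaction ids}. Deliberately a different algorithm from the
    library's per-focal indexed scan.
    """
    pre = {m: {} for m in network.metabolites}
    suc = {m: {} for m in network.metabolites}
    ubiq = network.ubiquitous_ids
    for rxn in network.reactions.values():
        pairs = []
        if rxn.direction in (
            Direction.LEFT_TO_RIGHT, Direction.REVERSIBLE, Direction.UNSPECIFIED
        ):
            pairs.append((rxn.left_ids, rxn.right_ids))
        if rxn.direction in (
            Direction.RIGHT_TO_LEFT, Direction.REVERSIBLE, Direction.UNSPECIFIED
        ):
            pairs.append((rxn.right_ids, rxn.left_ids))
        for reactants, products in pairs:
            for r in reactants:
                for p in products:
                    if r == p:
                        continue
                    if r not in ubiq:
                        pre[p].setdefault(r, set()).add(rxn.id)
                    if p not in ubiq:
                        suc[r].setdefault(p, set()).add(rxn.id)
    return pre, suc


def neighborhood_as_maps(nb):
    """Library Neighborhood -> the oracle's map shape, for comparison."""
    return (
        {e.neighbor_id: set(e.reactions) for e in nb.precursors},
        {e.neighbor_id: set(e.reactions) for e in nb.successors},
    )


@pytest.fixture
def toy_network():
    """A small hand-built network used across modules.

    R1: A + water -> B        (irreversible, spontaneous=False)
    R2: B <-> C               (reversible)
    R3: B -> D                (irreversible)
    R4: C -> D + phosphate    (irreversible, spontaneous)
    R5: B -> D                (second B->D link, makes the pair MULTIPLE)
    water and phosphate are ubiquitous.
    """
    mets = [
        Metabolite("A", "alanine-like"),
        Metabolite("B", "beta-compound", smiles="CCO"),
        Metabolite("C", "gamma-compound"),
        Metabolite("D", "delta-compound"),
        Metabolite("water", "water", is_ubiquitous=True),
        Metabolite("phosphate", "phosphate", is_ubiquitous=True),
    ]
    rxns = [
        Reaction("R1", [("A", 1), ("water", 1)], [("B", 1)],
                 ec_number="1.1.1.1", enzymes=["enzA"], genes=["genA"],
                 pathways=["toy-pathway"]),
        Reaction("R2", [("B", 1)], [("C", 1)], direction=Direction.REVERSIBLE,
                 ec_number="2.2.2.2"),
        Reaction("R3", [("B", 1)], [("D", 1)], ec_number="3.3.3.3"),
        Reaction("R4", [("C", 1)], [("D", 1), ("phosphate", 1)],
                 spontaneous=True),
        Reaction("R5", [("B", 1)], [("D", 1)]),
    ]
    return Network("toy", mets, rxns)


@pytest.fixture
def chain_network():
    """A -> B -> C -> D chain plus P -> B, used for path-machine tests.

    RAB: A -> B; RBC: B -> C; RCD: C -> D; RBD: B -> D; RPB: P -> B.
    """
    mets = [Metabolite(x) for x in "ABCDP"]
    rxns = [
        Reaction("RAB", [("A", 1)], [("B", 1)]),
        Reaction("RBC", [("B", 1)], [("C", 1)]),
        Reaction("RCD", [("C", 1)], [("D", 1)]),
        Reaction("RBD", [("B", 1)], [("D", 1)]),
        Reaction("RPB", [("P", 1)], [("B", 1)]),
    ]
    return Network("chain", mets, rxns)
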