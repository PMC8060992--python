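"""Seeded synthetic metabolic networks.

The generator emulates the shape of a curated reaction network at desk
scale: reactions draw a handful of participants per side, a configurable
fraction are reversible, a small fraction proceed spontaneously (and then
carry no enzyme or gene), a few percent of metabolites are currency
molecules, and reactions carry synthetic EC numbers, enzyme/gene names and
pathway memberships. It does not emulate real stoichiometric structure,
compartments, or the heavy-tailed degree distribution of genome-scale
models; it exists to exercise the neighborhood and path machinery under
controlled, reproducible conditions.

All randomness flows from a single :class:`random.Random` seeded per spec:
the same spec always yields a byte-identical network serialization.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model import Direction, Metabolite, MetnavError, Network, Reaction

__all__ = ["FixtureSpec", "generate_network"]

_PATHWAY_POOL = [
    "glycolysis-like",
    "tca-like",
    "amino-acid-biosynthesis",
    "nucleotide-salvage",
    "fatty-acid-oxidation",
    "pentose-shunt",
    "one-carbon-pool",
    "cofactor-assembly",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic network; same seed ⇒ identical network."""

    n_metabolites: int = 200
    n_reactions: int = 500
    p_reversible: float = 0.3
    p_spontaneous: float = 0.05
    ubiquitous_fraction: float = 0.05
    max_participants_per_side: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_reversible", "p_spontaneous", "ubiquitous_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MetnavError(f"{name} must be in [0, 1], got {v}")
        if self.n_metabolites <= 0 or self.n_reactions < 0:
            raise MetnavError("counts must be positive")
        if self.max_participants_per_side <= 0:
            raise MetnavError("max_participants_per_side must be positive")
        if 2 * self.max_participants_per_side > self.n_metabolites:
            raise MetnavError(
                "infeasible spec: a reaction could need "
                f"{2 * self.max_participants_per_side} distinct participants but "
                f"only {self.n_metabolites} metabolites exist"
            )


def _ec(rng: random.Random) -> str:
    return ".".join(
        str(rng.randint(1, hi)) for hi in (6, 20, 20, 150)
    )


def generate_network(spec: FixtureSpec) -> Network:
    """Generate a random annotated network per ``spec``.

    Each reaction samples its left and right participants jointly without
    replacement (sides are disjoint), 1..max per side. Direction is
    REVERSIBLE with probability ``p_reversible``, else LEFT_TO_RIGHT.
    Spontaneous reactions carry no enzymes or genes.
    """
    rng = random.Random(spec.seed)
    width = len(str(spec.n_metabolites))
    mets = [
        Metabolite(id=f"M{i:0{width}d}", name=f"cpd-{i}")
        for i in range(spec.n_metabolites)
    ]
    n_ubiq = round(spec.ubiquitous_fraction * spec.n_metabolites)
    for met in rng.sample(mets, n_ubiq):
        met.is_ubiquitous = True

    network = Network(f"synthetic-{spec.seed}", mets)
    met_ids = [m.id for m in mets]
    rwidth = len(str(max(spec.n_reactions, 1)))
    for j in range(spec.n_reactions):
        n_left = rng.randint(1, spec.max_participants_per_side)
        n_right = rng.randint(1, spec.max_participants_per_side)
        chosen = rng.sample(met_ids, n_left + n_right)
        left = [(m, float(rng.choice((1, 1, 1, 2)))) for m in chosen[:n_left]]
        right = [(m, float(rng.choice((1, 1, 1, 2)))) for m in chosen[n_left:]]
        direction = (
            Direction.REVERSIBLE
            if rng.random() < spec.p_reversible
            else Direction.LEFT_TO_RIGHT
        )
        spontaneous = rng.random() < spec.p_spontaneous
        rid = f"R{j:0{rwidth}d}"
        if spontaneous:
            enzymes, genes, ec = [], [], None
        else:
            n_enz = rng.randint(1, 2)
            enzymes = [f"enzyme-{rid}-{k}" for k in range(n_enz)]
            genes = [f"gene{rid.lower()}{chr(ord('A') + k)}" for k in range(n_enz)]
            ec = _ec(rng)
        network.add_reaction(
            Reaction(
                id=rid,
                left=left,
                right=right,
                direction=direction,
                ec_number=ec,
                enzymes=enzymes,
                genes=genes,
                pathways=rng.sample(_PATHWAY_POOL, rng.randint(0, 2)),
                spontaneous=spontaneous,
            )
        )
    return network
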