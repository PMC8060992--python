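# metnav

Interactive exploration of metabolic reaction networks, for systems
biologists who want to walk a network one reaction at a time rather than
through predefined pathways.

A metabolic network is a bipartite structure of metabolites and reactions.
For a focal metabolite *M*, metnav computes its **metabolic neighborhood**:

- the **precursors** — every metabolite *P* such that some reaction has *P*
  on an effective reactant side and *M* on the corresponding product side;
- the **successors** — every *S* reachable with *M* as reactant and *S* as
  product.

Reversible and unspecified-direction reactions contribute both orientations,
so a neighbor connected only by a reversible reaction appears in *both*
lists. Ubiquitous **currency metabolites** (water, H⁺, phosphate, …)
participate in so many reactions that they would drown the lists; they are
omitted from neighbor lists but remain visible as side metabolites of a
displayed reaction. Each neighbor entry records every linking reaction with
its equation, EC number, enzymes, genes and pathways, and each connection is
classified for display coding as *unidirectional*, *bidirectional*,
*spontaneous*, or *multiple* (more than one linking reaction).

On top of the neighborhood computation sits a small state machine: the user
builds a single **linear path**, extending it at either end, replacing a
portion anchored at an interior metabolite (the displaced path goes to a
restorable history), and choosing which of several linking reactions is
displayed. The session serializes to a shareable link string
(`LINKFORMAT.md`) and renders as a vertical pathway diagram in plain text or
SVG (`RENDERING.md`).

Networks are read and written in SBML Level 3 core (topology +
reversibility; extended annotations carried in notes) and in a lossless
native JSON format (`schemas/network-format-v1.json`).

## Worked example

```python
from metnav import *

net = generate_network(FixtureSpec(n_metabolites=20, n_reactions=30, seed=1))
nb = neighborhood(net, "M01")
print("suc:", [(e.neighbor_id, e.reactions) for e in nb.successors])

s = start_session(net, "M01")
add_metabolite(s, 0, "M02", Side.SUCCESSOR)     # M02 is a successor of M01
add_metabolite(s, 1, "M00", Side.SUCCESSOR)
print(encode_link(s))
print(render(s, DisplaySettings(candidates_mode=CandidatesMode.NONE)).content)
```

prints (abridged):

```
suc: [('M11', ('R11',)), ('M12', ('R03',)), ..., ('M02', ('R10', 'R13')), ...]
v1;synthetic-1;M01,R10*F,M02,R20*F,M00;11101A10
network: synthetic-1
path: 3 step(s)

[@step.0.metab.M01] (0) cpd-1
    [@step.0.count] | 2 reactions (showing R10)
    [@step.0.rxn.R10] | R10: cpd-4 + cpd-6 + cpd-1 -> cpd-9 + 2 cpd-2
    [@step.0.ec] | EC 5.7.19.118
    [@step.0.enzymes] | enzymes: enzyme-R10-0; genes: gener10A
    [@step.0.side] | side reactants: cpd-4, cpd-6; products: cpd-9
    v
[@step.1.metab.M02] (1) cpd-2
    ...
[@step.2.metab.M00] (2) cpd-0

legend: U=unidirectional  B=bidirectional  S=spontaneous  M=multiple
```

Reading it: the successor list of `M01` names every metabolite one reaction
step downstream with the reactions that get there — `M02` is reachable by
two reactions (`R10`, `R13`), so the diagram's first step lists the count
and shows the selected one. The link string on line 2 fully encodes the
3-step path and display settings and can be decoded against the same
network with `decode_link`. The `[@...]` tokens are stable anchors that make
the diagram machine-checkable.

The same session from the shell:

```sh
metnav gen-fixture --seed 1 --metabolites 20 --reactions 30 -o net.json
metnav neighbors net.json M01
metnav explore net.json --start M01     # REPL: fwd M02, fwd M00, link, quit
metnav render net.json --link 'v1;synthetic-1;M01,R10*F,M02,R20*F,M00;11101A10' --svg path.svg
```

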