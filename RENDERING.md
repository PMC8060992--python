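# Rendering contract

Both output formats draw the current path as a **vertical linear pathway
diagram**: main-path metabolites top-to-bottom in step order, each step
followed by its linking reaction and the annotations enabled in
`DisplaySettings`.

## Anchors

Every rendered element carries a stable machine-readable anchor id:

- text output: `[@anchor]` tokens at the start of each element's line;
- SVG output: the `id` attribute of the element.

Anchor grammar (`<qid>` = percent-encoded id, `urllib.parse.quote(id, safe="")`):

| anchor                  | element                                      |
|-------------------------|----------------------------------------------|
| `step.<i>.metab.<qid>`  | main-path metabolite of step *i*             |
| `step.<i>.rxn.<qid>`    | displayed reaction linking step *i* to *i+1* |
| `step.<i>.count`        | reaction count when >1 reactions link the pair |
| `step.<i>.ec`           | EC number line (gated by `show_ec`)          |
| `step.<i>.enzymes`      | enzymes/genes line (`show_enzymes_genes`)    |
| `step.<i>.pathways`     | pathway links line (`show_pathway_links`)    |
| `step.<i>.side`         | side metabolites line (`show_side_metabolites`) |
| `step.<i>.smiles`       | structure (SMILES) line (`show_structures`)  |
| `step.<i>.pre[.<qid>]`  | precursor candidate list / one candidate     |
| `step.<i>.suc[.<qid>]`  | successor candidate list / one candidate     |
| `step.<i>.pre.more` / `step.<i>.suc.more` | "+N more" truncation marker |

`metnav.metabolite_sequence(diagram)` recovers the main-path metabolite ids
in step order from either format; `metnav.extract_anchors(diagram)` returns
all anchors in document order.

## Connection-class legend

Candidate entries are tagged with the class of their connection to the
focal metabolite. The class precedence is multiple > spontaneous >
bidirectional > unidirectional.

| class          | text code | SVG color |
|----------------|-----------|-----------|
| unidirectional | `U`       | `#444444` |
| bidirectional  | `B`       | `#1f77b4` |
| spontaneous    | `S`       | `#2ca02c` |
| multiple       | `M`       | `#ff7f0e` |

## Candidates modes

- `ALL_STEPS` — precursor and successor candidate lists at every step
  (default).
- `ENDS_ONLY` — candidate lists only at the first and last step.
- `NONE` — no candidate lists.

Long candidate lists are truncated at `candidate_limit` entries with an
explicit `+N more` marker. Side-metabolite lines include ubiquitous
(currency) compounds; the currency omission applies only to candidate
lists. Layout metrics (spacing, fonts, arrowheads) are not part of the
contract; ordering and element presence are.
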