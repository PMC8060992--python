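# Link string format (version `v1`)

A link string is a compact, URL-safe, deterministic serialization of an
exploration session's current path, reaction selections, and display
settings. It is produced by `metnav.encode_link()` (or the REPL `link`
command) and consumed by `metnav.decode_link()` (or `metnav render --link`).

## Grammar

```
link     := "v1" ";" network ";" path ";" settings
network  := pct(network-id)
path     := met (  "," rxn "," met )*
met      := pct(metabolite-id)
rxn      := pct(reaction-id) "*" orientation
orientation := "F" | "R"
settings := flags mode limit
flags    := five "0"/"1" characters, in order:
            show_side_metabolites, show_enzymes_genes, show_ec,
            show_structures, show_pathway_links
mode     := "A" (candidates at all steps) | "E" (ends only) | "N" (none)
limit    := decimal candidate-list truncation limit
```

`pct(x)` is percent-encoding with **no** safe characters
(`urllib.parse.quote(x, safe="")`), so the structural separators `;`, `,`
and `*` can never occur inside an encoded id. The orientation marker says
which effective side assignment of the reaction is in use: `F` — left side
consumed, right side produced; `R` — the opposite.

## Example

```
v1;synthetic-1;M01,R11*F,M11;11101A10
```

Network `synthetic-1`, path `M01 → M11` via reaction `R11` used in its
forward orientation; all display elements on except compound structures,
candidates shown at every step, candidate lists truncated at 10.

## Guarantees

- Stable across runs: no timestamps or hashes; equal sessions give equal
  links.
- `decode_link(network, encode_link(session))` reproduces the path, the
  per-step reaction selections, and the display settings exactly.
- Decoding validates against the supplied network: a mismatched network id,
  a truncated string, or a reaction no longer present all raise a
  `LinkError` naming the offending element. The previous-paths history is
  not part of the link.
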