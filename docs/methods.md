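# Methods

## Scope and data model

The toolkit models the definition-harvesting stage of collaborative ICD
authoring. Its unit of work is the **definition entry**: a piece of
definition text (textual or structured), attached to one ICD category code,
with source metadata (a source-scheme tag such as `DBpedia`, `SNOMED CT` or
`UMLS/MSH2008_2008_02_04`; a UMLS CUI; optionally a SNOMED concept id).
ICD codes are opaque strings — block ranges such as `N17-N19` are themselves
categories and receive no range arithmetic. All strings are NFC-normalized
and compared case-sensitively; every domain type validates its invariants at
construction and raises rather than repairs.

The ICD-11 content model is carried as a packaged 13-row schema
(index, name). The loader enforces a contiguous `1..N` index sequence, so a
truncated or duplicated schema fails loudly rather than silently shifting
parameter meanings.

## Expression grammar

Short canonical forms are parsed with a hand-written recursive-descent
parser over the flat compositional-grammar subset

```
expr            := concept ("+" concept)* (":" refinement-part)?
refinement-part := (group | attr-pair) ("," (group | attr-pair))*
group           := "{" attr-pair ("," attr-pair)* "}"
attr-pair       := concept "=" concept
concept         := sctid ("|" term "|")?
```

Whitespace between tokens is ignored; term text between pipes is verbatim
(trimmed), so phrases like `Sudden onset AND/OR short duration` survive
unaltered. Nested refinements (a value that is itself refined) are rejected:
short canonical forms are flat by construction, and a value followed by `:`
is reported as a parse error with its character offset, as are unbalanced
`|`/`{`, a missing `=`, and a missing concept id. Concepts written without
an embedded term fall back to a caller-supplied sctid→term lookup, else the
sctid doubles as the term.

Serialization is canonical (single spaces around `: = , +`, groups emitted
before ungrouped pairs, terms always emitted), which gives two exploitable
properties: `parse ∘ serialize` is the identity on the expression structure,
and equal structures produce byte-identical text.

## Verbalization

The rendering rules are deliberately minimal — a supertype clause
(`is a T`, multiple foci joined as `and a T₂`), one clause per refinement
(`that has A of V`, the last of two or more taking `and`), groups flattened
in textual order before ungrouped pairs, semantic tags stripped from every
term, sentence mode = outline lines joined by spaces plus a period. A single
refinement keeps `that`; `and` marks only a true final clause among several.
No aggregation, pronouns or fluent-NL smoothing is attempted: the goal is a
faithful, deterministic rendering of the logical definition, not polished
prose.

Profiling maps each rendered clause to a content-model facet through a small
configurable attribute→tag table (defaults: Associated morphology →
Morphology, Finding site → Anatomical site, Clinical course → Temporal,
Causative agent → Causal); the supertype clause contributes `Supertype`,
unknown attributes surface as `Other:<attribute>` rather than being dropped.
The default table reproduces the tags of the worked examples; it is a
configuration default, not a claim about any authority's complete mapping.

## Linking semantics

LOD disease records are filtered with genuine SPARQL join semantics over an
rdflib graph: a subject must be typed `dbo:Disease` and carry label,
abstract, MeSH id and Wikipedia link in the requested language (language
matching is primary-subtag: requesting `en` accepts `en-GB`), and the result
is the DISTINCT set of projected value tuples. Feeding the filter a TSV dump
converts rows to the same graph shape first, so both input formats share one
code path.

Linking fans out across every crosswalk chain (MeSH → CUI → ICD-10 for LOD
records, sctid → CUI → ICD-10 for canonical forms) and then collapses on
`(icd_code, ontology_id, definition_text)`: the same text from the same
source attached to the same category is one entry no matter how many CUI
chains reached it, with the smallest `(term_id, sct_id)` surviving as the
entry's metadata. This collapse rule is the only one that is simultaneously
order-independent, deterministic, and conservative on distinct
`(code, text)` pairs. No rollup from 4-character ICD codes to 3-character
categories is performed.

Coverage statistics (source records, distinct MeSH ids, reachable CUIs,
linked categories, linked sctids, total entries) are computed once per run
and are required to equal an index-free brute-force nested-loop recount;
that oracle lives with the fixture generator and in the test suite, not in
the linker.

## RDF rendering and queries

One named graph (`http://who.int/icd`) carries everything. Each category
contributes `icd:icdCode` and (when known) `rdfs:label`; each entry hangs
off a fresh blank node via `icd:definitionPrefilled` with `icd:label`,
`icd:ontologyId`, `icd:termId` and, for structured definitions, `icd:sctId`.
Hierarchy links are emitted in both directions
(`DIRECT-SUBCLASSES`/`DIRECT-SUPERCLASSES`), with parentless categories
attached under the `icd:ICDCategory` root — exactly the shape the chapter
query joins on, so a category missing its back-link is (correctly) not a
chapter.

Turtle emission is a custom deterministic serializer (sorted subjects and
predicates, blank nodes labeled `_:b0000, _:b0001, …` in emission order,
terms escaped via rdflib), so equal graphs give byte-identical files;
parsing, SPARQL evaluation and isomorphism checking are delegated to rdflib.
Query results are re-sorted in Python by Unicode codepoint rather than
trusting any engine collation. The test suite cross-checks rdflib's
isomorphism against an exhaustive blank-node bijection search on
fixture-sized graphs, including single-triple perturbations.

## Synthetic data

The generator fabricates a coherent mini-terminology from one integer seed:
a concept pool with expressions drawn over a configurable attribute
vocabulary (refinement counts uniform in a configurable range, defaults
0–4, ~25% of refined expressions grouped, ~10% dual-focus), a crosswalk of
configurable size whose rows link MeSH ids, ICD codes and sctids with
probabilities 0.7/0.8/0.6 by default (every row keeps at least one link),
a LOD dump with a configurable language mix (defaults `en`/`de`, so
language filtering always has something to exclude) and ~10% exact-duplicate
rows to exercise DISTINCT, a pre-keyed definition table restricted to ICD
codes present in the crosswalk, and a two-level hierarchy. CUIs are drawn
from a pool about half the crosswalk size, so multi-chain fan-in (several
CUIs bridging the same link) occurs routinely. Identifier ranges are
unmistakably synthetic: sctids 100000–999999, CUIs `C9……`, MeSH ids `M9……`.

What the generator does **not** emulate: real terminology scale and
skew (the test bundles are tens of rows, not tens of thousands), lexical
variation between source definitions of the same disease, partial or noisy
crosswalk rows beyond random absence, and multilingual abstracts beyond the
language tag. Passing tests therefore demonstrate correctness of the
parsing/linking/export machinery and its invariants — not that real-world
coverage statistics would match any particular published magnitude, which
depends on licensed terminology releases.

Each bundle ships a manifest of expected coverage statistics computed by a
brute-force join over the raw rows (no indices), giving every end-to-end
test an independent oracle.

## Determinism and problem sizes

Every random draw flows from one `random.Random(seed)`; bundle files are
written in list order with sorted N-Triples, so identical seeds give
bit-identical bundles. The pipeline report isolates the timestamp in a
single field and echoes the configuration without output paths, so two runs
of the same seed produce identical reports modulo that field. Test and
acceptance problem sizes (bundles of 6–15 concepts, 12–25 crosswalk rows,
100 seeded bundles, 500 expression draws) were chosen to exercise every
fan-out/dedup/filter branch while keeping the whole suite in seconds.

## Known limitations

* Only flat (non-nested) expressions are supported; long normal forms,
  subsumption, and expression algebra are out of scope.
* Profiling applies to structured definitions only; free-text definitions
  are carried but not profiled.
* The Turtle emitter covers the vocabulary subset the toolkit itself
  produces; arbitrary RDF (datatyped literals beyond strings, RDF lists)
  round-trips through rdflib's parser but is not emitted.
* Named-graph support is a per-graph IRI tag; cross-graph queries and
  SPARQL Update are not provided.
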