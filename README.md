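# icddef

Tooling for assembling candidate **textual definitions of ICD categories**
from heterogeneous terminology sources. Authoring a written definition for
every category of the International Classification of Diseases is a large
collaborative effort; much of the raw material already exists — encyclopedic
disease abstracts published as linked open data, textual definitions carried
by UMLS source vocabularies, and the description-logic definitions of
SNOMED CT. This package integrates the three:

1. **Verbalization** — SNOMED CT *short canonical forms* (the maximally
   decomposed, redundancy-free view of a concept: proximal supertype(s) plus
   defining attribute–value refinements) are parsed from compositional-grammar
   expressions and rendered into structured human-readable definitions with a
   small set of grammatical rules.
2. **Crosswalk linking** — definitions are anchored to ICD-10 category codes
   through UMLS Concept Unique Identifiers (CUIs): LOD disease records via
   their MeSH id (MeSH → CUI → ICD-10), SNOMED concepts via their sctid
   (sctid → CUI → ICD-10), UMLS-style textual definitions directly by code.
3. **RDF export and querying** — the integrated result becomes a named RDF
   graph (`http://who.int/icd`) in the ICD authoring vocabulary
   (`icd:icdCode`, `icd:definitionPrefilled`, `icd:ontologyId`, `icd:termId`,
   `icd:sctId`, `DIRECT-SUBCLASSES`/`DIRECT-SUPERCLASSES`), serialized as
   Turtle and queryable through the standard authoring contracts (chapter
   listing, per-category definition retrieval).

Each rendered definition is also profiled against the 13 main parameters of
the ICD-11 *content model* (Textual Definitions, Body System/Structure
Description, Temporal Properties, ...), making visible which facets of a
category a definition actually covers.

The package is aimed at terminology engineers and ontologists who need an
offline, reproducible version of this harvesting pipeline: every input
(canonical table, crosswalk, LOD dump, definition table, hierarchy) is a
plain TSV or N-Triples file, and a seeded generator fabricates synthetic
terminologies with known expected statistics for testing.

## The verbalization rules

For a subject term *S*, focus concepts *T₁…Tₘ* and refinements
*(A₁,V₁)…(Aₖ,Vₖ)*:

* supertype clause — `is a T₁` (or `is a T₁ and a T₂ …`);
* refinement clauses — `that has Aᵢ of Vᵢ`, with the final clause of two or
  more taking `and` instead of `that`;
* sentence mode joins subject and clauses with spaces and a terminal period;
  outline mode puts the subject and each clause on its own line;
* fully-specified-name semantic tags (`… (disorder)`) are stripped first.

## Worked example

Verbalizing the short canonical form of *Acute myocardial infarction*:

```sh
icddef verbalize --mode outline \
  --expr "100001 |Disease| : 100002 |Clinical course| = 100003 |Sudden onset AND/OR short duration| , 100004 |Associated morphology| = 100005 |Acute infarct| , 100006 |Finding site| = 100007 |Myocardium structure|" \
  --subject "Acute myocardial infarction"
```

prints the structured definition, one clause per line:

```
Acute myocardial infarction
is a Disease
that has Clinical course of Sudden onset AND/OR short duration
that has Associated morphology of Acute infarct
and has Finding site of Myocardium structure
```

Running the whole pipeline on the bundled worked-example fixture and querying
the exported graph:

```sh
icddef run --in-paper --out demo
icddef query --graph demo/graph.ttl --code A19
icddef chapters --graph demo/graph.ttl
```

The run prints its coverage statistics:

```json
{
  "n_definition_entries": 12,
  "n_distinct_cuis": 2,
  "n_distinct_mesh": 2,
  "n_icd_categories_linked": 4,
  "n_sctids_linked": 3,
  "n_source_records": 2
}
```

i.e. 2 English LOD disease records (2 distinct MeSH ids reaching 2 CUIs) plus
the other sources yield 12 integrated definition entries over 4 ICD
categories, 3 of them backed by SNOMED CT concepts. The two case-study
categories, `I35.0` (aortic valve stenosis) and `N17-N19` (renal failure),
each end up with 5 definition entries — one LOD abstract, three UMLS-style
textual definitions and one verbalized SNOMED CT structured definition. The
`query` command returns the definition row for *A19 – Miliary tuberculosis*
with its source scheme (`UMLS/MSH2008_2008_02_04`) and CUI (`C0041321`);
`chapters` lists the chapter labels and codes in label order.

`icddef fixtures generate --seed N --out DIR` writes a synthetic bundle plus
a `manifest.json` of expected coverage statistics computed by an independent
brute-force join, and `icddef run --seed N --out DIR` runs the pipeline on
such a bundle deterministically.

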