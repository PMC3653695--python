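"""RDF rendering of integrated ICD content, Turtle I/O and query contracts.

Integrated categories and their definition entries are rendered as triples in
the named graph ``http://who.int/icd`` using the ICD authoring vocabulary::

    icd:<code>  icd:icdCode "<code>" ;
                rdfs:label "<label>" ;
                icd:definitionPrefilled _:bNNNN .
    _:bNNNN     icd:label "<definition text>" ;
                icd:ontologyId "<source scheme>" ;
                icd:termId "<CUI>" ;
                icd:sctId "<sctid>" .

Hierarchy links use ``DIRECT-SUBCLASSES`` / ``DIRECT-SUPERCLASSES`` under the
``http://who.int/icd/vocab/resource/`` namespace; top-level categories hang
off the ``icd:ICDCategory`` root so the chapter query finds them.

Graphs are rdflib Graphs wrapped with their named-graph IRI.  Turtle parsing,
SPARQL evaluation and isomorphism come from rdflib; Turtle *emission* is a
small deterministic serializer so equal graphs always produce identical text
and blank nodes keep their ``_:b``-prefixed 4-digit-counter labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import rdflib
from rdflib import BNode, Literal, URIRef
from rdflib.compare import isomorphic as _rdflib_isomorphic

from .core import DefinitionEntry, ICDCategory, IcddefError

__all__ = [
    "ICD",
    "ICDVOCAB",
    "ICD_GRAPH_IRI",
    "TripleGraph",
    "TurtleParseError",
    "category_to_triples",
    "build_graph",
    "serialize_turtle",
    "parse_turtle",
    "isomorphic",
    "query_chapters",
    "query_definition",
]

ICD = rdflib.Namespace("http://who.int/icd#")
ICDVOCAB = rdflib.Namespace("http://who.int/icd/vocab/resource/")
RDFS = rdflib.RDFS
ICD_GRAPH_IRI = "http://who.int/icd"

PREFIXES = (("icd", str(ICD)), ("icdv", str(ICDVOCAB)), ("rdfs", str(RDFS)))


class TurtleParseError(IcddefError, ValueError):
    """Malformed Turtle input; carries a 1-based line number when known."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


@dataclass
class TripleGraph:
    """An RDF graph tagged with the named-graph IRI it belongs to."""

    graph_iri: str = ICD_GRAPH_IRI
    graph: rdflib.Graph = field(default_factory=rdflib.Graph)

    def __len__(self) -> int:
        return len(self.graph)

    def triples(self) -> list[tuple]:
        return sorted(self.graph, key=lambda t: tuple(term.n3() for term in t))


class _BNodeCounter:
    """Deterministic blank-node minting: _:b0000, _:b0001, ..."""

    def __init__(self, start: int = 0):
        self.n = start

    def fresh(self) -> BNode:
        node = BNode(f"b{self.n:04d}")
        self.n += 1
        return node


def _add_category(
    g: rdflib.Graph,
    cat: ICDCategory,
    entries: Iterable[DefinitionEntry],
    counter: _BNodeCounter,
    root_parent: bool = False,
) -> None:
    subject = ICD[cat.code]
    g.add((subject, ICD.icdCode, Literal(cat.code)))
    if cat.label:
        g.add((subject, RDFS.label, Literal(cat.label)))
    for entry in entries:
        if entry.icd_code != cat.code:
            raise ValueError(
                f"entry for {entry.icd_code!r} attached to category {cat.code!r}"
            )
        b = counter.fresh()
        g.add((subject, ICD.definitionPrefilled, b))
        g.add((b, ICD.label, Literal(entry.definition_text)))
        g.add((b, ICD.ontologyId, Literal(entry.ontology_id)))
        if entry.term_id:
            g.add((b, ICD.termId, Literal(entry.term_id)))
        if entry.sct_id:
            g.add((b, ICD.sctId, Literal(entry.sct_id)))
    parent = ICD[cat.parent_code] if cat.parent_code else (ICD.ICDCategory if root_parent else None)
    if parent is not None:
        g.add((parent, ICDVOCAB["DIRECT-SUBCLASSES"], subject))
        g.add((subject, ICDVOCAB["DIRECT-SUPERCLASSES"], parent))
    for child in cat.children_codes:
        g.add((subject, ICDVOCAB["DIRECT-SUBCLASSES"], ICD[child]))
        g.add((ICD[child], ICDVOCAB["DIRECT-SUPERCLASSES"], subject))


def category_to_triples(
    cat: ICDCategory,
    entries: Iterable[DefinitionEntry],
    counter_start: int = 0,
) -> TripleGraph:
    """Render one category and its definition entries as an RDF graph.

    Each entry gets a fresh blank node carrying the definition text, source
    scheme, CUI and (when present) sctid.  An rdfs:label triple is emitted
    whenever the category label is known.  Entries whose code differs from
    the category's raise ValueError.
    """
    tg = TripleGraph()
    _add_category(tg.graph, cat, entries, _BNodeCounter(counter_start))
    return tg


def build_graph(
    categories: Iterable[ICDCategory],
    entries_by_code: Mapping[str, list[DefinitionEntry]],
) -> TripleGraph:
    """Render a full category set (with hierarchy) into one named graph.

    Categories without a parent are attached under the ``icd:ICDCategory``
    root, which makes them chapters for :func:`query_chapters`.  Blank-node
    labels are minted from one shared counter in iteration order.
    """
    tg = TripleGraph()
    counter = _BNodeCounter()
    cats = sorted(categories, key=lambda c: c.code)
    known = {c.code for c in cats}
    for cat in cats:
        _add_category(tg.graph, cat, entries_by_code.get(cat.code, []), counter, root_parent=True)
    # entries for codes absent from the hierarchy still get a bare category
    for code in sorted(set(entries_by_code) - known):
        label = next((e.icd_label for e in entries_by_code[code] if e.icd_label), "")
        bare = ICDCategory(code=code, label=label)
        _add_category(tg.graph, bare, entries_by_code[code], counter, root_parent=True)
    return tg


# ---------------------------------------------------------------------------
# Turtle serialization (deterministic) and parsing (rdflib)

_LOCAL_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_.-]*")


def _qname(term: URIRef) -> str:
    s = str(term)
    for prefix, ns in PREFIXES:
        if s.startswith(ns):
            local = s[len(ns):]
            if local and _LOCAL_RE.fullmatch(local) and not local.endswith("."):
                return f"{prefix}:{local}"
    return term.n3()


def _term_str(term) -> str:
    if isinstance(term, URIRef):
        return _qname(term)
    return term.n3()  # BNode -> _:label, Literal -> escaped quoted form


def serialize_turtle(tg: TripleGraph) -> str:
    """Serialize deterministically: prefix block, then subject-sorted triples.

    Equal graphs (same triples, same blank-node labels) yield byte-identical
    text.  Predicates within a subject are grouped with ";", objects with ",".
    """
    lines = [f"@prefix {p}: <{ns}> ." for p, ns in PREFIXES]
    lines.append("")
    subjects: dict[str, dict[str, list[str]]] = {}
    bnode_subj: set[str] = set()
    for s, p, o in tg.graph:
        s_str = _term_str(s)
        if isinstance(s, BNode):
            bnode_subj.add(s_str)
        subjects.setdefault(s_str, {}).setdefault(_term_str(p), []).append(_term_str(o))
    # IRI subjects first, then blank nodes, each in codepoint order
    ordered = sorted((s for s in subjects if s not in bnode_subj)) + sorted(bnode_subj)
    for s_str in ordered:
        preds = subjects[s_str]
        pred_lines = []
        for p_str in sorted(preds):
            objs = " , ".join(sorted(preds[p_str]))
            pred_lines.append(f"{p_str} {objs}")
        body = " ;\n    ".join(pred_lines)
        lines.append(f"{s_str} {body} .")
    return "\n".join(lines) + "\n"


def parse_turtle(text: str, graph_iri: str = ICD_GRAPH_IRI) -> TripleGraph:
    """Parse Turtle text into a TripleGraph; syntax errors carry line numbers."""
    g = rdflib.Graph()
    try:
        g.parse(data=text, format="turtle")
    except Exception as exc:
        line = getattr(exc, "lines", None)  # BadSyntax: 0-based newline count
        if isinstance(line, int):
            line += 1
        elif isinstance(exc, IndexError):  # truncated at end of input
            line = text.count("\n") + 1
        raise TurtleParseError(f"malformed Turtle: {exc}", line) from exc
    return TripleGraph(graph_iri=graph_iri, graph=g)


def isomorphic(a: TripleGraph, b: TripleGraph) -> bool:
    """Graph equality up to blank-node renaming."""
    return _rdflib_isomorphic(a.graph, b.graph)


# ---------------------------------------------------------------------------
# Query contracts

_CHAPTERS_QUERY = """
SELECT DISTINCT ?label ?code WHERE {
    <http://who.int/icd#ICDCategory>
        <http://who.int/icd/vocab/resource/DIRECT-SUBCLASSES> ?child .
    ?child <http://who.int/icd/vocab/resource/DIRECT-SUPERCLASSES> ?parent .
    ?child rdfs:label ?label .
    ?child <http://who.int/icd#icdCode> ?code .
}
"""

_DEFINITION_QUERY = """
SELECT DISTINCT ?label ?definitionContent ?ontologyId ?termId WHERE {
    ?cat <http://who.int/icd#definitionPrefilled> ?prefilledDefinition .
    ?cat rdfs:label ?label .
    ?prefilledDefinition <http://who.int/icd#label> ?definitionContent ;
        <http://who.int/icd#ontologyId> ?ontologyId ;
        <http://who.int/icd#termId> ?termId .
}
"""


def query_chapters(tg: TripleGraph) -> list[tuple[str, str]]:
    """All (label, code) chapter rows, distinct, in label codepoint order.

    A chapter is a direct subclass of ``icd:ICDCategory`` that also links
    back via ``DIRECT-SUPERCLASSES``; subjects lacking the back-link, a
    label or a code are excluded (join semantics).
    """
    rows = {(str(r.label), str(r.code)) for r in tg.graph.query(_CHAPTERS_QUERY)}
    return sorted(rows)


def query_definition(tg: TripleGraph, code: str) -> list[tuple[str, str, str, str]]:
    """Definition rows (label, definitionContent, ontologyId, termId) of *code*.

    One row per prefilled-definition blank node of the category, distinct;
    an unknown code yields an empty result.
    """
    rows = {
        (str(r.label), str(r.definitionContent), str(r.ontologyId), str(r.termId))
        for r in tg.graph.query(_DEFINITION_QUERY, initBindings={"cat": ICD[code]})
    }
    return sorted(rows)
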