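import itertools

import pytest
import rdflib
from rdflib import BNode, Literal

from icddef.core import DefinitionEntry, ICDCategory
from icddef.rdf import (
    ICD,
    ICDVOCAB,
    TripleGraph,
    TurtleParseError,
    build_graph,
    category_to_triples,
    isomorphic,
    parse_turtle,
    query_chapters,
    query_definition,
    serialize_turtle,
)

RDFS = rdflib.RDFS

AMI_SENTENCE = (
    "Acute myocardial infarction is a Disease that has Clinical course of "
    "Sudden onset AND/OR short duration that has Associated morphology of "
    "Acute infarct and has Finding site of Myocardium structure."
)

I21_ENTRY = DefinitionEntry(
    icd_code="I21",
    definition_text=AMI_SENTENCE,
    ontology_id="SNOMED CT",
    term_id="C0155626",
    sct_id="57054005",
    definition_type="structured",
)


def brute_force_isomorphic(g1: rdflib.Graph, g2: rdflib.Graph) -> bool:
    """Exhaustive blank-node bijection search (feasible at fixture scale)."""
    if len(g1) != len(g2):
        return False
    b1 = sorted({t for triple in g1 for t in triple if isinstance(t, BNode)})
    b2 = sorted({t for triple in g2 for t in triple if isinstance(t, BNode)})
    if len(b1) != len(b2):
        return False
    triples1 = set(g1)
    for perm in itertools.permutations(b2):
        mapping = dict(zip(b1, perm))

        def sub(t):
            return mapping.get(t, t) if isinstance(t, BNode) else t

        if {(sub(s), sub(p), sub(o)) for s, p, o in triples1} == set(g2):
            return True
    return False


def expected_i21_graph(bnode_label="b0672", with_label=True) -> TripleGraph:
    """The worked-example triple set, built directly with rdflib."""
    g = rdflib.Graph()
    b = BNode(bnode_label)
    g.add((ICD["I21"], ICD.icdCode, Literal("I21")))
    if with_label:
        g.add((ICD["I21"], RDFS.label, Literal("I21. Acute myocardial infarction")))
    g.add((ICD["I21"], ICD.definitionPrefilled, b))
    g.add((b, ICD.label, Literal(AMI_SENTENCE)))
    g.add((b, ICD.ontologyId, Literal("SNOMED CT")))
    g.add((b, ICD.termId, Literal("C0155626")))
    g.add((b, ICD.sctId, Literal("57054005")))
    return TripleGraph(graph=g)


class TestCategoryToTriples:
    def test_i21_worked_example(self):
        cat = ICDCategory(code="I21", label="I21. Acute myocardial infarction")
        tg = category_to_triples(cat, [I21_ENTRY])
        assert len(tg) == 7
        assert isomorphic(tg, expected_i21_graph())

    def test_label_omitted_when_unknown(self):
        tg = category_to_triples(ICDCategory(code="I21"), [I21_ENTRY])
        assert len(tg) == 6
        assert isomorphic(tg, expected_i21_graph(with_label=False))

    def test_category_without_entries(self):
        tg = category_to_triples(ICDCategory(code="A19", label="A19. Miliary tuberculosis"), [])
        triples = set(tg.graph)
        assert (ICD["A19"], ICD.icdCode, Literal("A19")) in triples
        assert len(tg) == 2  # icdCode + rdfs:label only

    def test_entries_get_distinct_fresh_blank_nodes(self):
        e2 = I21_ENTRY.model_copy(update={"definition_text": "Another text."})
        tg = category_to_triples(ICDCategory(code="I21"), [I21_ENTRY, e2])
        bnodes = {o for _, p, o in tg.graph if p == ICD.definitionPrefilled}
        assert len(bnodes) == 2

    def test_code_mismatch_rejected(self):
        with pytest.raises(ValueError, match="attached to category"):
            category_to_triples(ICDCategory(code="I22"), [I21_ENTRY])

    def test_hierarchy_links_are_bidirectional(self):
        cat = ICDCategory(code="I21", parent_code="I00-I99")
        g = category_to_triples(cat, []).graph
        assert (ICD["I00-I99"], ICDVOCAB["DIRECT-SUBCLASSES"], ICD["I21"]) in g
        assert (ICD["I21"], ICDVOCAB["DIRECT-SUPERCLASSES"], ICD["I00-I99"]) in g


class TestTurtleRoundTrip:
    def test_empty_graph_serializes_to_prefixes_only(self):
        text = serialize_turtle(TripleGraph())
        assert all(
            line.startswith("@prefix") or not line.strip() for line in text.splitlines()
        )
        assert len(parse_turtle(text)) == 0

    def test_worked_example_roundtrip_isomorphic(self):
        tg = expected_i21_graph()
        back = parse_turtle(serialize_turtle(tg))
        assert isomorphic(tg, back)
        assert len(back) == len(tg)  # triple count preserved exactly

    def test_serialization_is_deterministic(self):
        cat = ICDCategory(code="I21", label="x")
        a = serialize_turtle(category_to_triples(cat, [I21_ENTRY]))
        b = serialize_turtle(category_to_triples(cat, [I21_ENTRY]))
        assert a == b

    def test_blank_node_labels_are_counter_based(self):
        text = serialize_turtle(category_to_triples(ICDCategory(code="I21"), [I21_ENTRY]))
        assert "_:b0000" in text

    def test_malformed_turtle_reports_line(self):
        with pytest.raises(TurtleParseError) as exc:
            parse_turtle('@prefix icd: <http://who.int/icd#> .\nicd:I21 icd:icdCode "I21"')
        assert exc.value.line is not None

    def test_literal_escaping_survives_roundtrip(self):
        tricky = 'Text with "quotes", a \\ backslash\nand a newline.'
        e = I21_ENTRY.model_copy(update={"definition_text": tricky})
        tg = category_to_triples(ICDCategory(code="I21"), [e])
        back = parse_turtle(serialize_turtle(tg))
        assert isomorphic(tg, back)


class TestIsomorphism:
    def test_differing_only_in_blank_node_labels(self):
        assert isomorphic(expected_i21_graph("b0672"), expected_i21_graph("b9999"))

    def test_symmetric(self):
        a, b = expected_i21_graph(), expected_i21_graph("zzz")
        assert isomorphic(a, b) and isomorphic(b, a)

    def test_agrees_with_brute_force_bijection_oracle(self):
        a = expected_i21_graph()
        b = expected_i21_graph("other")
        assert brute_force_isomorphic(a.graph, b.graph)
        assert isomorphic(a, b) == brute_force_isomorphic(a.graph, b.graph)

    def test_single_triple_perturbations_detected(self):
        base = expected_i21_graph()
        for triple in sorted(base.graph, key=str):
            mutated = rdflib.Graph()
            for t in base.graph:
                mutated.add(t)
            mutated.remove(triple)
            s, p, _ = triple
            mutated.add((s, p, Literal("perturbed")))
            m = TripleGraph(graph=mutated)
            assert not isomorphic(base, m)
            assert not brute_force_isomorphic(base.graph, mutated)


def _chapter_graph():
    cats = [
        ICDCategory(code="A00-B99", label="Certain infectious and parasitic diseases"),
        ICDCategory(code="I00-I99", label="Diseases of the circulatory system"),
        ICDCategory(code="I21", label="I21. Acute myocardial infarction",
                    parent_code="I00-I99"),
    ]
    return build_graph(cats, {"I21": [I21_ENTRY]})


class TestQueries:
    def test_chapters_empty_graph(self):
        assert query_chapters(TripleGraph()) == []

    def test_chapters_ordered_by_label(self):
        rows = query_chapters(_chapter_graph())
        assert rows == [
            ("Certain infectious and parasitic diseases", "A00-B99"),
            ("Diseases of the circulatory system", "I00-I99"),
        ]
        assert rows == sorted(rows)  # codepoint order oracle

    def test_chapter_without_backlink_excluded(self):
        tg = _chapter_graph()
        tg.graph.remove((ICD["A00-B99"], ICDVOCAB["DIRECT-SUPERCLASSES"], None))
        assert [code for _, code in query_chapters(tg)] == ["I00-I99"]

    def test_definition_rows_for_known_code(self):
        rows = query_definition(_chapter_graph(), "I21")
        assert rows == [
            (
                "I21. Acute myocardial infarction",
                AMI_SENTENCE,
                "SNOMED CT",
                "C0155626",
            )
        ]

    def test_unknown_code_yields_empty(self):
        assert query_definition(_chapter_graph(), "Z99") == []

    def test_row_count_equals_prefilled_triples(self):
        entries = [
            I21_ENTRY.model_copy(update={"definition_text": f"Text {i}."}) for i in range(4)
        ]
        tg = build_graph([ICDCategory(code="I21", label="x")], {"I21": entries})
        n_prefilled = len(list(tg.graph.triples((None, ICD.definitionPrefilled, None))))
        assert len(query_definition(tg, "I21")) == n_prefilled == 4
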