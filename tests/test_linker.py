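import io

import rdflib

from icddef.core import CrosswalkRecord, DBpediaDiseaseRecord
from icddef.expressions import load_canonical_table
from icddef.fixtures import GeneratorConfig, brute_force_manifest, generate
from icddef.linker import (
    DBO,
    FOAF,
    coverage_stats,
    dedupe_entries,
    filter_disease_records,
    index_crosswalk,
    link_lod_definitions,
    link_structured_definitions,
    load_crosswalk_table,
    lod_rows_to_graph,
)

from conftest import AMI_EXPR

RDFS = rdflib.RDFS


def _disease_graph():
    """One dbo:Disease subject with full en properties plus a de abstract."""
    g = rdflib.Graph()
    s = rdflib.URIRef("http://example.org/d1")
    w = rdflib.URIRef("http://en.wikipedia.org/wiki/D1")
    g.add((s, rdflib.RDF.type, DBO.Disease))
    g.add((s, RDFS.label, rdflib.Literal("Disease one", lang="en")))
    g.add((s, DBO.abstract, rdflib.Literal("Abstract one.", lang="en")))
    g.add((s, DBO.abstract, rdflib.Literal("Zusammenfassung eins.", lang="de")))
    g.add((s, DBO.meshId, rdflib.Literal("M900010")))
    g.add((w, FOAF.primaryTopic, s))
    return g, s


class TestFilterDiseaseRecords:
    def test_complete_subject_yields_one_record(self):
        g, _ = _disease_graph()
        recs = filter_disease_records(g, "en")
        assert len(recs) == 1
        assert recs[0].abstract == "Abstract one."
        assert recs[0].mesh_id == "M900010"

    def test_extra_language_abstract_does_not_duplicate(self):
        g, _ = _disease_graph()
        assert len(filter_disease_records(g, "en")) == 1
        # requesting "de": the label exists only in English, so the join fails
        assert filter_disease_records(g, "de") == []
        s = rdflib.URIRef("http://example.org/d1")
        g.add((s, RDFS.label, rdflib.Literal("Krankheit eins", lang="de")))
        assert [r.abstract for r in filter_disease_records(g, "de")] == [
            "Zusammenfassung eins."
        ]

    def test_regional_variant_matches_primary_subtag(self):
        g = rdflib.Graph()
        s = rdflib.URIRef("http://example.org/d2")
        g.add((s, rdflib.RDF.type, DBO.Disease))
        g.add((s, RDFS.label, rdflib.Literal("Disease two", lang="en-GB")))
        g.add((s, DBO.abstract, rdflib.Literal("Abstract two.", lang="en-GB")))
        g.add((s, DBO.meshId, rdflib.Literal("M900011")))
        g.add((rdflib.URIRef("http://w/d2"), FOAF.primaryTopic, s))
        assert len(filter_disease_records(g, "en")) == 1

    def test_subject_missing_a_property_is_excluded(self):
        g, s = _disease_graph()
        g.remove((s, DBO.meshId, None))
        assert filter_disease_records(g, "en") == []

    def test_untyped_subject_is_excluded(self):
        g, s = _disease_graph()
        g.remove((s, rdflib.RDF.type, DBO.Disease))
        assert filter_disease_records(g, "en") == []

    def test_identical_tuples_collapse_to_one_record(self):
        rows = [
            {"label": "A", "abstract": "B", "meshId": "M1",
             "wikipediaLink": "http://w/a", "lang": "en"},
        ]
        g = lod_rows_to_graph(rows * 1)
        # two subjects, same projected tuple
        g2 = lod_rows_to_graph(rows + rows)
        assert len(filter_disease_records(g, "en")) == 1
        assert len(filter_disease_records(g2, "en")) == 1


class TestIndexCrosswalk:
    def test_empty(self):
        idx = index_crosswalk([])
        assert idx.mesh_to_cuis == {} and idx.cui_to_icd == {} and idx.cui_to_sct == {}

    def test_single_record(self):
        idx = index_crosswalk(
            [CrosswalkRecord(cui="C1", mesh_id="M1", icd10_code="I21", sctid="57054005")]
        )
        assert idx.mesh_to_cuis == {"M1": {"C1"}}
        assert idx.cui_to_icd == {"C1": {"I21"}}
        assert idx.cui_to_sct == {"C1": {"57054005"}}
        assert idx.sct_to_cuis == {"57054005": {"C1"}}

    def test_multi_mapping_preserved(self):
        idx = index_crosswalk(
            [
                CrosswalkRecord(cui="C1", icd10_code="I21"),
                CrosswalkRecord(cui="C1", icd10_code="I22"),
            ]
        )
        assert idx.cui_to_icd["C1"] == {"I21", "I22"}


def _record(mesh="M1", abstract="Text."):
    return DBpediaDiseaseRecord(
        label="L", abstract=abstract, mesh_id=mesh,
        wikipedia_link="http://w/l", lang="en",
    )


class TestLinkLod:
    def test_single_chain(self):
        idx = index_crosswalk([CrosswalkRecord(cui="C1", mesh_id="M1", icd10_code="I21")])
        entries = link_lod_definitions([_record()], idx)
        assert len(entries) == 1
        e = entries[0]
        assert (e.icd_code, e.ontology_id, e.term_id, e.definition_text) == (
            "I21", "DBpedia", "C1", "Text.",
        )
        assert e.definition_type == "textual"

    def test_unmapped_mesh_yields_nothing(self):
        idx = index_crosswalk([CrosswalkRecord(cui="C1", mesh_id="M2", icd10_code="I21")])
        assert link_lod_definitions([_record(mesh="M1")], idx) == []

    def test_fanout_to_two_cuis_same_code_collapses(self):
        idx = index_crosswalk(
            [
                CrosswalkRecord(cui="C1", mesh_id="M1", icd10_code="I21"),
                CrosswalkRecord(cui="C2", mesh_id="M1", icd10_code="I21"),
            ]
        )
        entries = link_lod_definitions([_record()], idx)
        assert len(entries) == 1
        assert entries[0].term_id == "C1"  # smallest CUI survives

    def test_order_invariance(self):
        recs = [_record(mesh="M1", abstract="A."), _record(mesh="M2", abstract="B.")]
        cw = [
            CrosswalkRecord(cui="C2", mesh_id="M1", icd10_code="I21"),
            CrosswalkRecord(cui="C1", mesh_id="M2", icd10_code="I22"),
        ]
        fwd = link_lod_definitions(recs, index_crosswalk(cw))
        rev = link_lod_definitions(list(reversed(recs)), index_crosswalk(list(reversed(cw))))
        assert fwd == rev


class TestLinkStructured:
    HEADER = "CONCEPTID\tFULLYSPECIFIEDNAME\tCANONICALEXPRESSION\n"

    def test_worked_example_chain(self):
        canon, _ = load_canonical_table(
            io.StringIO(self.HEADER + f"57054005\tAcute myocardial infarction (disorder)\t{AMI_EXPR}\n")
        )
        idx = index_crosswalk(
            [CrosswalkRecord(cui="C0155626", mesh_id="M1", icd10_code="I21", sctid="57054005")]
        )
        entries = link_structured_definitions(canon, idx)
        assert len(entries) == 1
        e = entries[0]
        assert e.icd_code == "I21"
        assert e.ontology_id == "SNOMED CT"
        assert e.term_id == "C0155626"
        assert e.sct_id == "57054005"
        assert e.definition_type == "structured"
        assert e.definition_text.startswith("Acute myocardial infarction is a Disease")

    def test_sctid_absent_from_crosswalk(self):
        canon, _ = load_canonical_table(
            io.StringIO(self.HEADER + "111\tThing (disorder)\t1 |Disease|\n")
        )
        idx = index_crosswalk([CrosswalkRecord(cui="C1", icd10_code="I21")])
        assert link_structured_definitions(canon, idx) == []

    def test_two_concepts_to_same_code_stay_distinct(self):
        canon, _ = load_canonical_table(
            io.StringIO(
                self.HEADER
                + "111\tThing one (disorder)\t1 |Disease|\n"
                + "222\tThing two (disorder)\t1 |Disease|\n"
            )
        )
        idx = index_crosswalk(
            [
                CrosswalkRecord(cui="C1", icd10_code="I21", sctid="111"),
                CrosswalkRecord(cui="C2", icd10_code="I21", sctid="222"),
            ]
        )
        entries = link_structured_definitions(canon, idx)
        assert len(entries) == 2  # distinct rendered texts
        assert {e.sct_id for e in entries} == {"111", "222"}


class TestCoverageStats:
    def test_empty_inputs(self):
        stats = coverage_stats([], [], index_crosswalk([]))
        assert stats.model_dump() == {
            "n_source_records": 0,
            "n_distinct_mesh": 0,
            "n_distinct_cuis": 0,
            "n_icd_categories_linked": 0,
            "n_sctids_linked": 0,
            "n_definition_entries": 0,
        }

    def test_matches_brute_force_oracle_on_seeded_bundles(self):
        from conftest import run_linking

        for seed in range(20):
            cfg = GeneratorConfig(seed=seed, n_concepts=8, n_crosswalk=16, n_lod_records=8)
            bundle = generate(cfg)
            records, entries, idx = run_linking(bundle)
            stats = coverage_stats(records, entries, idx)
            assert stats.model_dump() == brute_force_manifest(bundle)["coverage"]

    def test_dedup_preserves_distinct_code_text_pairs(self):
        cfg = GeneratorConfig(seed=3, n_concepts=10, n_crosswalk=30, n_lod_records=15)
        bundle = generate(cfg)
        idx = index_crosswalk(load_crosswalk_table(
            [dict(zip(("cui", "mesh_id", "icd10_code", "sctid"), row)) for row in bundle.crosswalk_rows]
        ))
        g = lod_rows_to_graph(bundle.lod_rows)
        records = filter_disease_records(g, "en")
        raw = []
        for rec in records:
            for cui in sorted(idx.mesh_to_cuis.get(rec.mesh_id, ())):
                for code in sorted(idx.cui_to_icd.get(cui, ())):
                    raw.append((code, rec.abstract))
        entries = link_lod_definitions(records, idx)
        assert {(e.icd_code, e.definition_text) for e in entries} == set(raw)


def test_dedupe_tie_break_is_order_independent():
    from icddef.core import DefinitionEntry

    a = DefinitionEntry(icd_code="I21", definition_text="T", ontology_id="DBpedia",
                        term_id="C2", definition_type="textual")
    b = DefinitionEntry(icd_code="I21", definition_text="T", ontology_id="DBpedia",
                        term_id="C1", definition_type="textual")
    assert dedupe_entries([a, b]) == dedupe_entries([b, a]) == [b]
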