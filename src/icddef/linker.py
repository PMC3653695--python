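"""Link disease definitions from three sources to ICD categories via CUIs.

Three heterogeneous definition sources are integrated:

* linked-open-data disease records (label + abstract + MeSH id), anchored to
  ICD-10 codes through MeSH id -> CUI -> ICD-10 crosswalk chains;
* pre-keyed textual definitions (UMLS-style, already carrying an ICD code);
* SNOMED CT structured definitions, verbalized from short canonical forms and
  anchored through sctid -> CUI -> ICD-10 chains.

Multiplicities fan out (every reachable combination is emitted) and results
are collapsed on (icd_code, ontology_id, definition_text) — the same
definition text from the same source attached to the same category is one
entry regardless of which CUI chain reached it; the surviving entry carries
the smallest CUI.  Linking is therefore invariant to input row order.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import rdflib
from pydantic import BaseModel, ConfigDict

from .core import (
    CrosswalkRecord,
    DBpediaDiseaseRecord,
    DefinitionEntry,
    FormatError,
    SCTExpression,
    TabularSource,
    _rows_from_source,
    lang_matches,
    nfc,
)
from .verbalize import RenderStyle, strip_semantic_tag, verbalize

__all__ = [
    "DBO",
    "FOAF",
    "CoverageStats",
    "CrosswalkIndex",
    "dedupe_entries",
    "filter_disease_records",
    "index_crosswalk",
    "link_lod_definitions",
    "link_structured_definitions",
    "coverage_stats",
    "load_crosswalk_table",
    "load_lod_graph",
    "lod_rows_to_graph",
    "load_definition_table",
    "write_definitions_tsv",
    "read_definitions_tsv",
    "DEFINITION_COLUMNS",
]

DBO = rdflib.Namespace("http://dbpedia.org/ontology/")
FOAF = rdflib.Namespace("http://xmlns.com/foaf/0.1/")
RDFS = rdflib.RDFS

DEFINITION_COLUMNS = (
    "icd_code",
    "icd_label",
    "definition_text",
    "ontology_id",
    "term_id",
    "sct_id",
    "definition_type",
)


class CoverageStats(BaseModel):
    """Coverage of one pipeline run: sources, crosswalk reach, emitted links."""

    model_config = ConfigDict(frozen=True)

    n_source_records: int = 0
    n_distinct_mesh: int = 0
    n_distinct_cuis: int = 0
    n_icd_categories_linked: int = 0
    n_sctids_linked: int = 0
    n_definition_entries: int = 0


@dataclass
class CrosswalkIndex:
    """CUI-anchored lookup indices; multi-mappings are preserved as sets."""

    mesh_to_cuis: dict[str, set[str]] = field(default_factory=dict)
    cui_to_icd: dict[str, set[str]] = field(default_factory=dict)
    cui_to_sct: dict[str, set[str]] = field(default_factory=dict)
    sct_to_cuis: dict[str, set[str]] = field(default_factory=dict)

    def icd_codes(self) -> set[str]:
        out: set[str] = set()
        for codes in self.cui_to_icd.values():
            out |= codes
        return out


def index_crosswalk(records: Iterable[CrosswalkRecord]) -> CrosswalkIndex:
    """Index crosswalk records by MeSH id, CUI and sctid."""
    idx = CrosswalkIndex()
    for rec in records:
        if rec.mesh_id is not None:
            idx.mesh_to_cuis.setdefault(rec.mesh_id, set()).add(rec.cui)
        if rec.icd10_code is not None:
            idx.cui_to_icd.setdefault(rec.cui, set()).add(rec.icd10_code)
        if rec.sctid is not None:
            idx.cui_to_sct.setdefault(rec.cui, set()).add(rec.sctid)
            idx.sct_to_cuis.setdefault(rec.sctid, set()).add(rec.cui)
    return idx


_DISEASE_QUERY = """
SELECT DISTINCT ?label ?abstract ?meshId ?wikipediaLink ?abstractLang WHERE {
    ?s a <http://dbpedia.org/ontology/Disease> .
    ?s rdfs:label ?label .
    ?s <http://dbpedia.org/ontology/abstract> ?abstract .
    ?s <http://dbpedia.org/ontology/meshId> ?meshId .
    ?wikipediaLink <http://xmlns.com/foaf/0.1/primaryTopic> ?s .
    BIND(lang(?abstract) AS ?abstractLang)
}
"""


def filter_disease_records(
    graph: rdflib.Graph, lang: str = "en"
) -> list[DBpediaDiseaseRecord]:
    """Extract disease records in one language from a linked-open-data graph.

    Keeps only subjects typed ``dbo:Disease`` that carry a label, an abstract,
    a MeSH id and a Wikipedia link (join semantics: a subject missing any
    property contributes nothing).  Language filtering matches on the primary
    subtag, so requesting "en" accepts "en" and "en-GB".  The result is the
    distinct set of (label, abstract, meshId, wikipediaLink) value tuples, in
    deterministic sorted order.
    """
    seen: dict[tuple[str, str, str, str], DBpediaDiseaseRecord] = {}
    for row in graph.query(_DISEASE_QUERY):
        label, abstract, mesh, link, abs_lang = row
        label_lang = label.language or ""
        abstract_lang = str(abs_lang) if abs_lang else ""
        if not (lang_matches(label_lang, lang) and lang_matches(abstract_lang, lang)):
            continue
        key = (nfc(str(label)), nfc(str(abstract)), nfc(str(mesh)), str(link))
        if key not in seen:
            seen[key] = DBpediaDiseaseRecord(
                label=key[0],
                abstract=key[1],
                mesh_id=key[2],
                wikipedia_link=key[3],
                lang=abstract_lang,
            )
    return [seen[k] for k in sorted(seen)]


def dedupe_entries(entries: Iterable[DefinitionEntry]) -> list[DefinitionEntry]:
    """Collapse entries sharing (icd_code, ontology_id, definition_text).

    When several CUI chains reach the same definition, the entry with the
    smallest (term_id, sct_id, icd_label) survives — a deterministic,
    order-independent tie-break.  Output is sorted by dedup key.
    """
    best: dict[tuple, DefinitionEntry] = {}
    for e in entries:
        k = e.dedup_key()
        cur = best.get(k)
        if cur is None or (e.term_id, e.sct_id or "", e.icd_label) < (
            cur.term_id,
            cur.sct_id or "",
            cur.icd_label,
        ):
            best[k] = e
    return [best[k] for k in sorted(best)]


def link_lod_definitions(
    records: Iterable[DBpediaDiseaseRecord],
    index: CrosswalkIndex,
    source_tag: str = "DBpedia",
    labels: Optional[Mapping[str, str]] = None,
) -> list[DefinitionEntry]:
    """Attach LOD abstracts to ICD codes through MeSH -> CUI -> ICD-10 chains.

    Every reachable (record, CUI, ICD code) combination is emitted, then
    collapsed by :func:`dedupe_entries`.  Records whose MeSH id is absent
    from the crosswalk yield nothing.
    """
    labels = labels or {}
    out: list[DefinitionEntry] = []
    for rec in records:
        for cui in sorted(index.mesh_to_cuis.get(rec.mesh_id, ())):
            for code in sorted(index.cui_to_icd.get(cui, ())):
                out.append(
                    DefinitionEntry(
                        icd_code=code,
                        icd_label=labels.get(code, ""),
                        definition_text=rec.abstract,
                        ontology_id=source_tag,
                        term_id=cui,
                        definition_type="textual",
                    )
                )
    return dedupe_entries(out)


def link_structured_definitions(
    canon: Mapping[str, tuple[str, SCTExpression]],
    index: CrosswalkIndex,
    labels: Optional[Mapping[str, str]] = None,
) -> list[DefinitionEntry]:
    """Verbalize canonical forms and attach them through sctid -> CUI -> ICD.

    Each concept with a short canonical form is rendered in sentence mode
    (subject = its fully specified name, semantic tag stripped) and linked to
    every ICD code reachable via any CUI holding that sctid.  The source tag
    is fixed to "SNOMED CT" and the sct_id is carried on every entry.
    """
    labels = labels or {}
    style = RenderStyle(mode="sentence")
    out: list[DefinitionEntry] = []
    for sctid in sorted(canon):
        fsn, expr = canon[sctid]
        subject = strip_semantic_tag(fsn) if fsn else sctid
        text = verbalize(expr, subject, style).rendered_text
        for cui in sorted(index.sct_to_cuis.get(sctid, ())):
            for code in sorted(index.cui_to_icd.get(cui, ())):
                out.append(
                    DefinitionEntry(
                        icd_code=code,
                        icd_label=labels.get(code, ""),
                        definition_text=text,
                        ontology_id="SNOMED CT",
                        term_id=cui,
                        sct_id=sctid,
                        definition_type="structured",
                    )
                )
    return dedupe_entries(out)


def coverage_stats(
    records: Iterable[DBpediaDiseaseRecord],
    entries: Iterable[DefinitionEntry],
    index: CrosswalkIndex,
) -> CoverageStats:
    """Count source records, crosswalk reach and emitted definition entries.

    ``n_distinct_cuis`` counts CUIs reachable from the source records' MeSH
    ids; linked-category and linked-sctid counts are over *entries*.  Equals a
    brute-force nested-loop recomputation on the same inputs.
    """
    records = list(records)
    entries = list(entries)
    mesh_ids = {r.mesh_id for r in records}
    cuis: set[str] = set()
    for mesh in mesh_ids:
        cuis |= index.mesh_to_cuis.get(mesh, set())
    icd_codes = {e.icd_code for e in entries}
    crosswalk_codes = index.icd_codes()
    if not icd_codes <= crosswalk_codes:
        raise ValueError(
            f"linked ICD codes not in crosswalk: {sorted(icd_codes - crosswalk_codes)}"
        )
    return CoverageStats(
        n_source_records=len(records),
        n_distinct_mesh=len(mesh_ids),
        n_distinct_cuis=len(cuis),
        n_icd_categories_linked=len(icd_codes),
        n_sctids_linked=len({e.sct_id for e in entries if e.sct_id}),
        n_definition_entries=len(entries),
    )


# ---------------------------------------------------------------------------
# Tabular / RDF I/O


def load_crosswalk_table(source: TabularSource) -> list[CrosswalkRecord]:
    """Load a crosswalk TSV (cui, mesh_id, icd10_code, sctid; blanks allowed)."""
    rows = _rows_from_source(source)
    if rows and "cui" not in rows[0]:
        raise FormatError("crosswalk table requires a 'cui' column")
    out = []
    for row in rows:
        out.append(
            CrosswalkRecord(
                cui=str(row.get("cui") or "").strip(),
                mesh_id=str(row.get("mesh_id") or "").strip() or None,
                icd10_code=str(row.get("icd10_code") or "").strip() or None,
                sctid=str(row.get("sctid") or "").strip() or None,
            )
        )
    return out


def lod_rows_to_graph(rows: Iterable[dict]) -> rdflib.Graph:
    """Build an RDF graph from pre-joined TSV rows of disease records.

    Expected columns: label, abstract, meshId, wikipediaLink, lang.  Each row
    becomes one subject typed ``dbo:Disease`` with language-tagged label and
    abstract, so TSV dumps and N-Triples dumps feed the same filter.
    """
    g = rdflib.Graph()
    for i, row in enumerate(rows):
        s = rdflib.URIRef(f"http://example.org/disease/{i}")
        lang = str(row.get("lang") or "en")
        g.add((s, rdflib.RDF.type, DBO.Disease))
        g.add((s, RDFS.label, rdflib.Literal(str(row["label"]), lang=lang)))
        g.add((s, DBO.abstract, rdflib.Literal(str(row["abstract"]), lang=lang)))
        g.add((s, DBO.meshId, rdflib.Literal(str(row["meshId"]))))
        g.add((rdflib.URIRef(str(row["wikipediaLink"])), FOAF.primaryTopic, s))
    return g


def load_lod_graph(path: Union[str, Path]) -> rdflib.Graph:
    """Load a local LOD dump: N-Triples/Turtle by extension, else record TSV."""
    path = Path(path)
    if path.suffix in {".nt", ".ttl"}:
        g = rdflib.Graph()
        g.parse(path, format="nt" if path.suffix == ".nt" else "turtle")
        return g
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    required = {"label", "abstract", "meshId", "wikipediaLink"}
    if rows and not required.issubset(rows[0].keys()):
        raise FormatError(f"LOD TSV requires columns {sorted(required)}")
    return lod_rows_to_graph(rows)


def load_definition_table(source: TabularSource) -> list[DefinitionEntry]:
    """Load pre-keyed textual definitions (UMLS-style TSV keyed by ICD code)."""
    rows = _rows_from_source(source)
    required = {"icd_code", "definition_text", "ontology_id"}
    if rows and not required.issubset(rows[0].keys()):
        raise FormatError(f"definition table requires columns {sorted(required)}")
    out = []
    for row in rows:
        out.append(
            DefinitionEntry(
                icd_code=str(row.get("icd_code") or "").strip(),
                icd_label=str(row.get("icd_label") or "").strip(),
                definition_text=str(row.get("definition_text") or "").strip(),
                ontology_id=str(row.get("ontology_id") or "").strip(),
                term_id=str(row.get("term_id") or "").strip(),
                sct_id=str(row.get("sct_id") or "").strip() or None,
                definition_type=str(row.get("definition_type") or "textual").strip(),
            )
        )
    return out


def write_definitions_tsv(entries: Iterable[DefinitionEntry], target) -> None:
    """Write entries as a TSV with the standard definition columns."""

    def _write(fh) -> None:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(DEFINITION_COLUMNS)
        for e in entries:
            w.writerow(
                [
                    e.icd_code,
                    e.icd_label,
                    e.definition_text,
                    e.ontology_id,
                    e.term_id,
                    e.sct_id or "",
                    e.definition_type,
                ]
            )

    if isinstance(target, (str, Path)):
        with open(target, "w", newline="", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(target)


def read_definitions_tsv(source: TabularSource) -> list[DefinitionEntry]:
    """Read back a definitions TSV written by :func:`write_definitions_tsv`."""
    return load_definition_table(source)
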