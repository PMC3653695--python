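"""Fixture bundles: the published worked examples and seeded synthetic data.

A fixture bundle holds the five inputs every pipeline stage consumes — a
canonical table of short canonical forms, a CUI crosswalk, a local LOD dump,
a pre-keyed textual-definition table and an ICD hierarchy table — and can
write them to disk in the formats the loaders expect (TSV + N-Triples).

Two constructors are provided:

* :func:`build_in_paper_fixture` — the deterministic worked-example bundle
  around the four ICD categories A19, I21, I35.0 and N17-N19;
* :func:`generate` — a seeded random terminology with controlled overlap
  between crosswalk, LOD dump and canonical table, plus a manifest of
  expected coverage statistics computed by an independent brute-force
  nested-loop join (no use of the linker's indices).

Synthetic identifiers are unmistakably non-real: sctids drawn from
100000-999999, CUIs "C9" + 6 digits, MeSH ids "M9" + 5 digits.  The only
real identifiers are the handful quoted from the published worked examples.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .core import ConceptRef, lang_matches
from .expressions import parse_expression, serialize_expression
from .linker import lod_rows_to_graph
from .verbalize import RenderStyle, strip_semantic_tag, verbalize

__all__ = [
    "FixtureBundle",
    "GeneratorConfig",
    "build_in_paper_fixture",
    "generate",
    "random_expression",
    "DEFAULT_ATTRIBUTES",
]

CANONICAL_HEADER = ("CONCEPTID", "FULLYSPECIFIEDNAME", "CANONICALEXPRESSION")
CROSSWALK_HEADER = ("cui", "mesh_id", "icd10_code", "sctid")
DEFINITION_HEADER = (
    "icd_code",
    "icd_label",
    "definition_text",
    "ontology_id",
    "term_id",
    "sct_id",
    "definition_type",
)
HIERARCHY_HEADER = ("code", "label", "parent_code")
LOD_HEADER = ("label", "abstract", "meshId", "wikipediaLink", "lang")


@dataclass
class FixtureBundle:
    """In-memory fixture tables plus an optional expected-counts manifest."""

    canonical_rows: list[tuple[str, str, str]] = dc_field(default_factory=list)
    crosswalk_rows: list[tuple[str, str, str, str]] = dc_field(default_factory=list)
    lod_rows: list[dict] = dc_field(default_factory=list)
    definition_rows: list[tuple[str, ...]] = dc_field(default_factory=list)
    hierarchy_rows: list[tuple[str, str, str]] = dc_field(default_factory=list)
    manifest: Optional[dict] = None

    def write(self, outdir) -> dict[str, Path]:
        """Write TSV/N-Triples inputs (and manifest.json) into *outdir*."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "canonical": outdir / "canonical.tsv",
            "crosswalk": outdir / "crosswalk.tsv",
            "lod": outdir / "lod.nt",
            "definitions": outdir / "definitions.tsv",
            "hierarchy": outdir / "hierarchy.tsv",
        }
        _write_tsv(paths["canonical"], CANONICAL_HEADER, self.canonical_rows)
        _write_tsv(paths["crosswalk"], CROSSWALK_HEADER, self.crosswalk_rows)
        _write_tsv(paths["definitions"], DEFINITION_HEADER, self.definition_rows)
        _write_tsv(paths["hierarchy"], HIERARCHY_HEADER, self.hierarchy_rows)
        graph = lod_rows_to_graph(self.lod_rows)
        nt_lines = sorted(f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph)
        paths["lod"].write_text("\n".join(nt_lines) + ("\n" if nt_lines else ""), "utf-8")
        if self.manifest is not None:
            paths["manifest"] = outdir / "manifest.json"
            paths["manifest"].write_text(
                json.dumps(self.manifest, indent=2, sort_keys=True) + "\n", "utf-8"
            )
        return paths


def _write_tsv(path: Path, header, rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(list(row))


# ---------------------------------------------------------------------------
# In-paper worked-example bundle

_AMI_EXPR = (
    "100001 |Disease| : "
    "100002 |Clinical course| = 100003 |Sudden onset AND/OR short duration| , "
    "100004 |Associated morphology| = 100005 |Acute infarct| , "
    "100006 |Finding site| = 100007 |Myocardium structure|"
)
_AVS_EXPR = (
    "100001 |Disease| : "
    "100004 |Associated morphology| = 100301 |Stenosis| , "
    "100006 |Finding site| = 100302 |Aortic valve structure|"
)
_RF_EXPR = "100303 |Renal impairment|"

_A19_TEXT = (
    "An acute form of TUBERCULOSIS in which minute tubercles are formed in a "
    "number of organs of the body due to dissemination of the bacilli through "
    "the blood stream."
)
_I35_DBPEDIA = (
    "Aortic valve stenosis (AS) is a type of valvular heart disease "
    "characterized by an abnormal narrowing of the aortic valve opening."
)
_I35_MSH = (
    "A pathological constriction that can occur above (supravalvular stenosis), "
    "below (subvalvular stenosis), or at the AORTIC VALVE. It is characterized "
    "by restricted outflow from the LEFT VENTRICLE into the AORTA."
)
_I35_NCI = (
    "Narrowing of the orifice of the aortic valve or of the supravalvular or "
    "subvalvular regions."
)
_I35_CSP = (
    "Constriction in the opening of the aortic valve or of the supravalvular "
    "or subvalvular regions."
)
_RF_DBPEDIA = (
    "Renal failure or kidney failure (formerly called renal insufficiency) "
    "describes a medical condition in which the kidneys fail to adequately "
    "filter toxins and waste products from the blood. The two forms are acute "
    "and chronic; a number of other diseases or health problems may cause "
    "either form of renal failure to occur. Renal failure is described as a "
    "decrease in the glomerular filtration rate. Biochemically, renal failure "
    "is typically detected by an elevated serum creatinine level. Problems "
    "frequently encountered in kidney malfunction include abnormal fluid "
    "levels in the body, deranged acid levels, abnormal levels of potassium, "
    "calcium, phosphate, and (in the longer term) anemia. Depending on the "
    "cause, hematuria (blood loss in the urine) and proteinuria (protein loss "
    "in the urine) may occur. Long-term kidney problems have significant "
    "repercussions on other diseases, such as cardiovascular disease."
)
_RF_MSH = (
    "A severe irreversible decline in the ability of kidneys to remove wastes, "
    "concentrate URINE, and maintain ELECTROLYTE BALANCE; BLOOD PRESSURE; and "
    "CALCIUM metabolism. Renal failure, either acute (KIDNEY FAILURE, ACUTE) "
    "or chronic (KIDNEY FAILURE, CHRONIC), requires HEMODIALYSIS."
)
_RF_NCI = (
    "Acute or chronic condition, characterized by the inability of the kidneys "
    "to adequately filter the blood substances, resulting in uremia and "
    "electrolyte imbalances. Acute renal failure is usually associated with "
    "oliguria or anuria, hyperkalemia, and pulmonary edema. Chronic renal "
    "failure is irreversible and requires hemodialysis.--2004"
)
_RF_CSP = (
    "Inability of a kidney to excrete metabolites at normal plasma levels "
    "under conditions of normal loading or inability to retain electrolytes "
    "under conditions of normal intake."
)

MSH = "UMLS/MSH2008_2008_02_04"
NCI = "UMLS/NCI2007_05E"
CSP = "UMLS/CSP2006"


def build_in_paper_fixture() -> FixtureBundle:
    """The deterministic worked-example bundle around A19, I21, I35.0, N17-N19.

    After linking, I35.0 and N17-N19 each carry exactly 5 definition entries
    (one LOD abstract, three UMLS-style textual definitions, one verbalized
    SNOMED CT structured definition); A19 carries its single MeSH-sourced
    textual definition and I21 its single SNOMED CT mapping.
    """
    bundle = FixtureBundle(
        canonical_rows=[
            ("57054005", "Acute myocardial infarction (disorder)", _AMI_EXPR),
            ("100101", "Aortic valve stenosis (disorder)", _AVS_EXPR),
            ("100102", "Renal failure syndrome (disorder)", _RF_EXPR),
        ],
        crosswalk_rows=[
            ("C0155626", "M900001", "I21", "57054005"),
            ("C9000001", "M900002", "I35.0", "100101"),
            ("C9000002", "M900003", "N17-N19", "100102"),
            ("C0041321", "M900004", "A19", ""),
        ],
        lod_rows=[
            {
                "label": "Aortic valve stenosis",
                "abstract": _I35_DBPEDIA,
                "meshId": "M900002",
                "wikipediaLink": "http://en.wikipedia.org/wiki/Aortic_valve_stenosis",
                "lang": "en",
            },
            {
                "label": "Renal failure",
                "abstract": _RF_DBPEDIA,
                "meshId": "M900003",
                "wikipediaLink": "http://en.wikipedia.org/wiki/Renal_failure",
                "lang": "en",
            },
            # a non-English record: excluded by the language filter
            {
                "label": "Aortenklappenstenose",
                "abstract": "Die Aortenklappenstenose ist eine Verengung der Aortenklappe.",
                "meshId": "M900002",
                "wikipediaLink": "http://de.wikipedia.org/wiki/Aortenklappenstenose",
                "lang": "de",
            },
        ],
        definition_rows=[
            ("A19", "A19. Miliary tuberculosis", _A19_TEXT, MSH, "C0041321", "", "textual"),
            ("I35.0", "I35.0 Aortic (valve) stenosis", _I35_MSH, MSH, "C9100001", "", "textual"),
            ("I35.0", "I35.0 Aortic (valve) stenosis", _I35_NCI, NCI, "C9100002", "", "textual"),
            ("I35.0", "I35.0 Aortic (valve) stenosis", _I35_CSP, CSP, "C9100003", "", "textual"),
            ("N17-N19", "N17-N19 Renal failure", _RF_MSH, MSH, "C9100004", "", "textual"),
            ("N17-N19", "N17-N19 Renal failure", _RF_NCI, NCI, "C9100005", "", "textual"),
            ("N17-N19", "N17-N19 Renal failure", _RF_CSP, CSP, "C9100006", "", "textual"),
        ],
        hierarchy_rows=[
            ("A00-B99", "Certain infectious and parasitic diseases", ""),
            ("I00-I99", "Diseases of the circulatory system", ""),
            ("N00-N99", "Diseases of the genitourinary system", ""),
            ("A19", "A19. Miliary tuberculosis", "A00-B99"),
            ("I21", "I21. Acute myocardial infarction", "I00-I99"),
            ("I35.0", "I35.0 Aortic (valve) stenosis", "I00-I99"),
            ("N17-N19", "N17-N19 Renal failure", "N00-N99"),
        ],
    )
    bundle.manifest = brute_force_manifest(bundle)
    return bundle


# ---------------------------------------------------------------------------
# Seeded synthetic generator

#: Default attribute vocabulary for generated expressions (synthetic ids).
DEFAULT_ATTRIBUTES: tuple[ConceptRef, ...] = (
    ConceptRef(sctid="410001", term="Associated morphology"),
    ConceptRef(sctid="410002", term="Finding site"),
    ConceptRef(sctid="410003", term="Clinical course"),
    ConceptRef(sctid="410004", term="Causative agent"),
    ConceptRef(sctid="410005", term="Severity"),
    ConceptRef(sctid="410006", term="Interprets"),
)

_ADJECTIVES = ("Acute", "Chronic", "Diffuse", "Focal", "Recurrent", "Transient", "Severe", "Mild")
_NOUNS = ("inflammation", "stenosis", "infarct", "lesion", "obstruction", "degeneration",
          "hypertrophy", "atrophy")
_SITES = ("cardiac structure", "renal structure", "hepatic structure",
          "pulmonary structure", "vascular structure", "osseous structure")
_SUPERTYPE_TERMS = ("Disease", "Disorder of body system", "Clinical finding",
                    "Morphologically abnormal structure (disorder)", "Syndrome")
_SCHEMES = (MSH, NCI, CSP, "UMLS/GO2007_02_01")


class GeneratorConfig(BaseModel):
    """Knobs of the synthetic-terminology generator.

    The link probabilities control how densely the crosswalk bridges MeSH
    ids, ICD-10 codes and sctids, hence how much of each source survives
    linking.  Defaults give a mid-density crosswalk where every stage has
    both linked and orphan records.
    """

    model_config = ConfigDict(frozen=True)

    seed: int
    n_concepts: int = Field(default=30, ge=1)
    n_refinements_range: tuple[int, int] = (0, 4)
    attribute_vocabulary: tuple[ConceptRef, ...] = DEFAULT_ATTRIBUTES
    n_crosswalk: int = Field(default=60, ge=0)
    p_mesh_link: float = Field(default=0.7, ge=0.0, le=1.0)
    p_icd_link: float = Field(default=0.8, ge=0.0, le=1.0)
    p_sct_link: float = Field(default=0.6, ge=0.0, le=1.0)
    n_lod_records: int = Field(default=25, ge=0)
    languages: tuple[str, ...] = ("en", "de")

    @field_validator("n_refinements_range")
    @classmethod
    def _range_ok(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if not (0 <= lo <= hi):
            raise ValueError(f"refinement range must satisfy 0 <= min <= max, got {v}")
        return v

    @model_validator(mode="after")
    def _vocab_ok(self) -> "GeneratorConfig":
        if not self.attribute_vocabulary:
            raise ValueError("attribute vocabulary must be non-empty")
        if not self.languages:
            raise ValueError("languages must be non-empty")
        return self


def random_expression(
    rng: random.Random,
    supertypes: tuple[ConceptRef, ...],
    attributes: tuple[ConceptRef, ...],
    values: tuple[ConceptRef, ...],
    n_refinements_range: tuple[int, int] = (0, 4),
    p_group: float = 0.25,
    p_multifocus: float = 0.1,
):
    """Draw one random (flat) short-canonical-form expression."""
    n_focus = 2 if (rng.random() < p_multifocus and len(supertypes) >= 2) else 1
    focus = tuple(rng.sample(list(supertypes), n_focus))
    lo, hi = n_refinements_range
    k = min(rng.randint(lo, hi), len(attributes))
    attrs = rng.sample(list(attributes), k)
    pairs = tuple(
        {"attribute": a, "value": rng.choice(list(values))} for a in attrs
    )
    from .core import AttributeRefinement, RefinementGroup, SCTExpression

    refinements = tuple(AttributeRefinement(**p) for p in pairs)
    if refinements and rng.random() < p_group:
        return SCTExpression(focus=focus, groups=(RefinementGroup(refinements=refinements),))
    return SCTExpression(focus=focus, ungrouped=refinements)


def generate(config: GeneratorConfig) -> FixtureBundle:
    """Generate a reproducible synthetic bundle plus expected-counts manifest.

    Identical configs (same seed) produce bit-identical bundles.  The
    manifest's coverage block is computed by :func:`brute_force_manifest`,
    an index-free nested-loop recount independent of the linker.
    """
    rng = random.Random(config.seed)

    supertypes = tuple(
        ConceptRef(sctid=str(sid), term=term)
        for sid, term in zip(rng.sample(range(100000, 400000), len(_SUPERTYPE_TERMS)),
                             _SUPERTYPE_TERMS)
    )
    values = tuple(
        ConceptRef(sctid=str(sid), term=f"{rng.choice(_ADJECTIVES)} {rng.choice(_NOUNS)} {i}")
        for i, sid in enumerate(rng.sample(range(400000, 700000), 15))
    )

    concept_ids = [str(s) for s in rng.sample(range(700000, 1000000), config.n_concepts)]
    canonical_rows = []
    for i, sctid in enumerate(concept_ids):
        term = f"{rng.choice(_ADJECTIVES)} {rng.choice(_NOUNS)} of {rng.choice(_SITES)} {i}"
        expr = random_expression(
            rng, supertypes, config.attribute_vocabulary, values, config.n_refinements_range
        )
        canonical_rows.append((sctid, f"{term} (disorder)", serialize_expression(expr)))

    n_icd = max(4, config.n_crosswalk // 4)
    icd_pool: list[str] = []
    while len(icd_pool) < n_icd:
        code = f"{rng.choice('ABCEFGHJKLMNQRSTVXYZ')}{rng.randrange(100):02d}"
        if rng.random() < 0.15:
            a = rng.randrange(10, 80)
            code = f"{code[0]}{a:02d}-{code[0]}{a + rng.randrange(1, 15):02d}"
        if code not in icd_pool:
            icd_pool.append(code)
    mesh_pool = [f"M9{rng.randrange(10000, 99999)}" for _ in range(max(4, config.n_crosswalk // 3))]
    cui_pool = [f"C9{rng.randrange(100000, 999999):06d}" for _ in range(max(4, config.n_crosswalk // 2))]

    crosswalk_rows: list[tuple[str, str, str, str]] = []
    for _ in range(config.n_crosswalk):
        cui = rng.choice(cui_pool)
        mesh = rng.choice(mesh_pool) if rng.random() < config.p_mesh_link else ""
        icd = rng.choice(icd_pool) if rng.random() < config.p_icd_link else ""
        sct = rng.choice(concept_ids) if rng.random() < config.p_sct_link else ""
        if not (mesh or icd or sct):
            mesh = rng.choice(mesh_pool)
        crosswalk_rows.append((cui, mesh, icd, sct))

    lod_rows: list[dict] = []
    for i in range(config.n_lod_records):
        if lod_rows and rng.random() < 0.1:
            lod_rows.append(dict(lod_rows[-1]))  # exact duplicate: exercises DISTINCT
            continue
        noun = rng.choice(_NOUNS)
        label = f"{noun.capitalize()} disease {i}"
        lod_rows.append(
            {
                "label": label,
                "abstract": f"{label} is a synthetic condition affecting the {rng.choice(_SITES)}.",
                "meshId": rng.choice(mesh_pool),
                "wikipediaLink": f"http://en.wikipedia.org/wiki/Synthetic_disease_{i}",
                "lang": rng.choice(list(config.languages)),
            }
        )

    used_icd = sorted({row[2] for row in crosswalk_rows if row[2]})
    definition_rows: list[tuple[str, ...]] = []
    for code in used_icd:
        if rng.random() < 0.5:
            for j in range(rng.randint(1, 2)):
                definition_rows.append(
                    (
                        code,
                        f"{code}. Synthetic category {code}",
                        f"A synthetic textual definition {j} of category {code}.",
                        rng.choice(_SCHEMES),
                        f"C9{rng.randrange(100000, 999999):06d}",
                        "",
                        "textual",
                    )
                )

    chapters = sorted({code[0] for code in used_icd})
    hierarchy_rows: list[tuple[str, str, str]] = [
        (f"{L}00-{L}99", f"Synthetic chapter {L}", "") for L in chapters
    ]
    hierarchy_rows += [(code, f"{code}. Synthetic category {code}", f"{code[0]}00-{code[0]}99")
                       for code in used_icd]

    bundle = FixtureBundle(
        canonical_rows=canonical_rows,
        crosswalk_rows=crosswalk_rows,
        lod_rows=lod_rows,
        definition_rows=definition_rows,
        hierarchy_rows=hierarchy_rows,
    )
    bundle.manifest = brute_force_manifest(bundle)
    return bundle


# ---------------------------------------------------------------------------
# Independent expected-counts oracle (nested loops, no indices)


def brute_force_manifest(bundle: FixtureBundle, lang: str = "en") -> dict:
    """Recount the bundle's expected coverage statistics from first principles.

    Re-derives every linking chain by scanning the raw crosswalk rows with
    nested loops (no dictionaries keyed on identifiers), applying the same
    collapse rule the pipeline defines: one entry per (icd_code, ontology_id,
    definition_text), the smallest (term_id, sct_id) surviving.
    """
    # language filter + DISTINCT on the four projected values
    filtered: list[dict] = []
    seen: set[tuple] = set()
    for row in bundle.lod_rows:
        if not lang_matches(str(row["lang"]), lang):
            continue
        key = (row["label"], row["abstract"], row["meshId"], row["wikipediaLink"])
        if key not in seen:
            seen.add(key)
            filtered.append(row)

    # entries keyed (icd_code, ontology_id, definition_text) -> (term_id, sct_id)
    entry_meta: dict[tuple, tuple[str, str]] = {}

    def _keep(key: tuple, term_id: str, sct_id: str) -> None:
        cur = entry_meta.get(key)
        if cur is None or (term_id, sct_id) < cur:
            entry_meta[key] = (term_id, sct_id)

    for rec in filtered:
        for cui, mesh, _icd, _sct in bundle.crosswalk_rows:
            if mesh and mesh == rec["meshId"]:
                for cui2, _m2, icd2, _s2 in bundle.crosswalk_rows:
                    if cui2 == cui and icd2:
                        _keep((icd2, "DBpedia", rec["abstract"]), cui, "")

    style = RenderStyle(mode="sentence")
    for sctid, fsn, expr_text in bundle.canonical_rows:
        sentence = verbalize(
            parse_expression(expr_text), strip_semantic_tag(fsn), style
        ).rendered_text
        for cui, _mesh, _icd, sct in bundle.crosswalk_rows:
            if sct and sct == sctid:
                for cui2, _m2, icd2, _s2 in bundle.crosswalk_rows:
                    if cui2 == cui and icd2:
                        _keep((icd2, "SNOMED CT", sentence), cui, sctid)

    for row in bundle.definition_rows:
        code, _label, text, scheme, term_id, sct_id, _type = row
        _keep((code, scheme, text), term_id, sct_id)

    mesh_ids = {r["meshId"] for r in filtered}
    cuis = {
        cui
        for cui, mesh, _icd, _sct in bundle.crosswalk_rows
        if mesh and mesh in mesh_ids
    }
    coverage = {
        "n_source_records": len(filtered),
        "n_distinct_mesh": len(mesh_ids),
        "n_distinct_cuis": len(cuis),
        "n_icd_categories_linked": len({k[0] for k in entry_meta}),
        "n_sctids_linked": len({s for _t, s in entry_meta.values() if s}),
        "n_definition_entries": len(entry_meta),
    }
    return {
        "coverage": coverage,
        "n_canonical_rows": len(bundle.canonical_rows),
        "n_crosswalk_rows": len(bundle.crosswalk_rows),
        "n_lod_rows": len(bundle.lod_rows),
        "n_definition_rows": len(bundle.definition_rows),
        "n_hierarchy_rows": len(bundle.hierarchy_rows),
    }
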