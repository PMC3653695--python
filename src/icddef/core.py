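"""Shared domain types for terminology integration.

The ICD-11 content model describes every ICD category through 13 main
parameters ("ICD Entity Title", "Textual Definitions", ...).  This module
holds the content-model schema loader and the value types shared by every
other module: SNOMED CT concept references and short-canonical-form
expressions, definition entries attached to ICD categories, UMLS-CUI-anchored
crosswalk records, and the ICD category hierarchy.

All types validate their invariants at construction (pydantic); an invalid
instance raises, it is never silently repaired.  Strings are NFC-normalized
and compared case-sensitively.
"""

from __future__ import annotations

import csv
import io
import re
import unicodedata
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "IcddefError",
    "SchemaError",
    "FormatError",
    "ConfigError",
    "ExpressionParseError",
    "ConceptRef",
    "AttributeRefinement",
    "RefinementGroup",
    "SCTExpression",
    "StructuredDefinition",
    "DefinitionEntry",
    "CrosswalkRecord",
    "ICDCategory",
    "ContentModelParameter",
    "DBpediaDiseaseRecord",
    "validate_cui",
    "lang_matches",
    "nfc",
    "load_content_model_schema",
    "build_hierarchy",
    "load_hierarchy_table",
]


class IcddefError(Exception):
    """Base class for package errors."""


class SchemaError(IcddefError, ValueError):
    """Content-model schema violates its structural constraints."""


class FormatError(IcddefError, ValueError):
    """A tabular input file does not match its expected layout."""


class ConfigError(IcddefError, ValueError):
    """Pipeline configuration is incomplete or names a missing input."""


class ExpressionParseError(IcddefError, ValueError):
    """A short-canonical-form expression string is malformed."""

    def __init__(self, message: str, offset: Optional[int] = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


# UMLS Concept Unique Identifiers as printed: "C" followed by digits.
_CUI_RE = re.compile(r"C\d+")
_SCTID_RE = re.compile(r"\d+")
# BCP-47-shaped language tag; only the primary subtag is interpreted.
_LANG_RE = re.compile(r"[A-Za-z]{1,8}(-[A-Za-z0-9]{1,8})*")


def nfc(text: str) -> str:
    """NFC-normalize *text* (canonical composition)."""
    return unicodedata.normalize("NFC", text)


def validate_cui(text: str) -> bool:
    """True iff *text* is a well-formed CUI ("C" followed by >=1 digits)."""
    return isinstance(text, str) and _CUI_RE.fullmatch(text) is not None


def lang_matches(tag: str, requested: str) -> bool:
    """SPARQL langMatches basic filtering: "en" accepts "en" and "en-GB"."""
    tag_l, req_l = tag.lower(), requested.lower()
    if req_l == "*":
        return bool(tag_l)
    return tag_l == req_l or tag_l.startswith(req_l + "-")


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True)


class ConceptRef(_Frozen):
    """A SNOMED CT concept: numeric identifier plus preferred term."""

    sctid: str
    term: str

    @field_validator("sctid")
    @classmethod
    def _sctid_numeric(cls, v: str) -> str:
        v = v.strip()
        if not v or _SCTID_RE.fullmatch(v) is None:
            raise ValueError(f"sctid must be non-empty digits, got {v!r}")
        return v

    @field_validator("term")
    @classmethod
    def _term_nonempty(cls, v: str) -> str:
        v = nfc(v).strip()
        if not v:
            raise ValueError("term must be non-empty")
        return v


class AttributeRefinement(_Frozen):
    """One defining attribute-value pair, e.g. Finding site = Myocardium structure."""

    attribute: ConceptRef
    value: ConceptRef


class RefinementGroup(_Frozen):
    """A braced set of refinements that jointly qualify the focus concept."""

    refinements: tuple[AttributeRefinement, ...]

    @field_validator("refinements")
    @classmethod
    def _check(cls, v: tuple[AttributeRefinement, ...]) -> tuple[AttributeRefinement, ...]:
        if not v:
            raise ValueError("refinement group must be non-empty")
        pairs = [(r.attribute.sctid, r.value.sctid) for r in v]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (attribute, value) pair within one group")
        return v


class SCTExpression(_Frozen):
    """A short canonical form: proximal supertype(s) plus defining refinements.

    The short normal form is the maximally decomposed, redundancy-free view of
    a precoordinated concept: one or more focus (proximal supertype) concepts,
    optionally refined by attribute-value pairs, grouped or ungrouped.
    """

    focus: tuple[ConceptRef, ...]
    groups: tuple[RefinementGroup, ...] = ()
    ungrouped: tuple[AttributeRefinement, ...] = ()

    @field_validator("focus")
    @classmethod
    def _focus_nonempty(cls, v: tuple[ConceptRef, ...]) -> tuple[ConceptRef, ...]:
        if not v:
            raise ValueError("expression must have at least one focus concept")
        return v

    def all_refinements(self) -> tuple[AttributeRefinement, ...]:
        """Grouped refinements flattened in order, then ungrouped ones."""
        flat: list[AttributeRefinement] = []
        for g in self.groups:
            flat.extend(g.refinements)
        flat.extend(self.ungrouped)
        return tuple(flat)


class StructuredDefinition(_Frozen):
    """A human-readable definition rendered from a formal expression."""

    subject_term: str
    supertype_terms: tuple[str, ...]
    clauses: tuple[tuple[str, str], ...]
    rendered_text: str
    rendered_outline: tuple[str, ...]


class DefinitionEntry(_Frozen):
    """One definition (textual or structured) attached to an ICD category."""

    icd_code: str
    icd_label: str = ""
    definition_text: str
    ontology_id: str
    term_id: str = ""
    sct_id: Optional[str] = None
    definition_type: Literal["textual", "structured"]

    @field_validator("icd_code", "definition_text", "ontology_id")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        v = nfc(v)
        if not v.strip():
            raise ValueError("field must be non-empty")
        return v

    @field_validator("term_id")
    @classmethod
    def _cui_shape(cls, v: str) -> str:
        if v and not validate_cui(v):
            raise ValueError(f"term_id must be a CUI (C + digits), got {v!r}")
        return v

    @field_validator("sct_id")
    @classmethod
    def _sctid_shape(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and _SCTID_RE.fullmatch(v) is None:
            raise ValueError(f"sct_id must be digits, got {v!r}")
        return v

    @model_validator(mode="after")
    def _structured_has_sctid(self) -> "DefinitionEntry":
        if self.definition_type == "structured" and not self.sct_id:
            raise ValueError("a structured definition must carry its sct_id")
        return self

    def dedup_key(self) -> tuple[str, str, str]:
        """Identity for deduplication: the same definition text from the same
        source attached to the same category is one entry, whichever CUI chain
        reached it (the surviving entry carries the smallest CUI)."""
        return (self.icd_code, self.ontology_id, self.definition_text)


class CrosswalkRecord(_Frozen):
    """A CUI-anchored identifier tuple bridging MeSH, ICD-10 and SNOMED CT."""

    cui: str
    mesh_id: Optional[str] = None
    icd10_code: Optional[str] = None
    sctid: Optional[str] = None

    @field_validator("cui")
    @classmethod
    def _cui_ok(cls, v: str) -> str:
        if not validate_cui(v):
            raise ValueError(f"malformed CUI {v!r}")
        return v

    @field_validator("sctid")
    @classmethod
    def _sctid_ok(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and _SCTID_RE.fullmatch(v) is None:
            raise ValueError(f"sctid must be digits, got {v!r}")
        return v

    @model_validator(mode="after")
    def _any_link(self) -> "CrosswalkRecord":
        if self.mesh_id is None and self.icd10_code is None and self.sctid is None:
            raise ValueError("crosswalk record must carry at least one linked identifier")
        return self


class ICDCategory(_Frozen):
    """An ICD category: code, rubric label and hierarchy links.

    Codes are opaque strings; block ranges like "N17-N19" are themselves
    categories and get no range arithmetic.
    """

    code: str
    label: str = ""
    parent_code: Optional[str] = None
    children_codes: tuple[str, ...] = ()

    @field_validator("code")
    @classmethod
    def _code_nonempty(cls, v: str) -> str:
        v = nfc(v).strip()
        if not v:
            raise ValueError("code must be non-empty")
        return v


class ContentModelParameter(_Frozen):
    """One of the main parameters of the ICD-11 content model."""

    index: int
    name: str

    @field_validator("index")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("parameter index must be >= 1")
        return v

    @field_validator("name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        v = nfc(v).strip()
        if not v:
            raise ValueError("parameter name must be non-empty")
        return v


class DBpediaDiseaseRecord(_Frozen):
    """A disease record harvested from a linked-open-data dump."""

    label: str
    abstract: str
    mesh_id: str
    wikipedia_link: str
    lang: str

    @field_validator("label", "abstract", "mesh_id", "wikipedia_link")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        v = nfc(v)
        if not v.strip():
            raise ValueError("field must be non-empty")
        return v

    @field_validator("lang")
    @classmethod
    def _lang_ok(cls, v: str) -> str:
        if _LANG_RE.fullmatch(v) is None:
            raise ValueError(f"malformed language tag {v!r}")
        return v


TabularSource = Union[str, Path, io.IOBase, list]


def _rows_from_source(source: TabularSource) -> list[dict]:
    """Read TSV rows (as dicts) from a path, open text file, or row list."""
    if isinstance(source, list):
        return [dict(r) for r in source]
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return list(csv.DictReader(fh, delimiter="\t"))
    return list(csv.DictReader(source, delimiter="\t"))


def load_content_model_schema(
    source: Optional[TabularSource] = None,
) -> list[ContentModelParameter]:
    """Load a content-model parameter schema from a TSV (index, name) table.

    With no *source*, the packaged default schema — the 13 main parameters of
    the ICD-11 content model — is loaded.  Indices must form the contiguous
    sequence 1..N with no duplicates; parameters are returned in index order.
    """
    if source is None:
        text = resources.files("icddef").joinpath("data/content_model.tsv").read_text("utf-8")
        source = io.StringIO(text)
    rows = _rows_from_source(source)
    params: list[ContentModelParameter] = []
    for row in rows:
        if "index" not in row or "name" not in row or row["index"] is None or row["name"] is None:
            raise SchemaError("schema table requires 'index' and 'name' columns")
        try:
            idx = int(str(row["index"]).strip())
        except ValueError as exc:
            raise SchemaError(f"non-integer parameter index {row['index']!r}") from exc
        params.append(ContentModelParameter(index=idx, name=str(row["name"])))
    params.sort(key=lambda p: p.index)
    indices = [p.index for p in params]
    if len(set(indices)) != len(indices):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        raise SchemaError(f"duplicate parameter index {dupes[0]}")
    if indices != list(range(1, len(indices) + 1)):
        raise SchemaError(f"parameter indices must be contiguous 1..{len(indices)}, got {indices}")
    return params


def build_hierarchy(rows: list[dict]) -> dict[str, ICDCategory]:
    """Build a consistent category map from (code, label, parent_code) rows.

    Children links are derived from parent links, so the two are mutually
    consistent by construction; cyclic ancestry raises FormatError.
    """
    parents: dict[str, Optional[str]] = {}
    labels: dict[str, str] = {}
    children: dict[str, list[str]] = {}
    for row in rows:
        code = nfc(str(row.get("code", ""))).strip()
        if not code:
            raise FormatError("hierarchy row missing code")
        if code in parents:
            raise FormatError(f"duplicate hierarchy code {code!r}")
        parent = str(row.get("parent_code") or "").strip() or None
        parents[code] = parent
        labels[code] = nfc(str(row.get("label") or "")).strip()
    for code, parent in parents.items():
        if parent is not None:
            children.setdefault(parent, []).append(code)
    for code in parents:
        seen = {code}
        cur = parents[code]
        while cur is not None:
            if cur in seen:
                raise FormatError(f"cyclic ancestry at category {code!r}")
            seen.add(cur)
            cur = parents.get(cur)
    return {
        code: ICDCategory(
            code=code,
            label=labels[code],
            parent_code=parents[code],
            children_codes=tuple(children.get(code, ())),
        )
        for code in parents
    }


def load_hierarchy_table(source: TabularSource) -> dict[str, ICDCategory]:
    """Load an ICD hierarchy TSV with columns code, label, parent_code."""
    rows = _rows_from_source(source)
    if rows and not {"code", "label"}.issubset(rows[0].keys()):
        raise FormatError("hierarchy table requires 'code' and 'label' columns")
    return build_hierarchy(rows)
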