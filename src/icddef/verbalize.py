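"""Render short canonical forms into structured human-readable definitions.

Grammatical rules
-----------------
Given a subject term S, focus concepts T1..Tm and refinements
(A1,V1)..(Ak,Vk) (groups flattened in order, then ungrouped pairs):

* supertype clause: ``is a T1`` (several foci: ``is a T1 and a T2 ...``);
* each refinement renders ``<conn> has Ai of Vi`` where the connective is
  ``that`` for every refinement except the last of two or more, which takes
  ``and`` (a single refinement keeps ``that``);
* sentence mode concatenates S and the clauses with single spaces and a
  terminal period; outline mode yields S as the first line then one clause
  per line, no periods;
* every term is first stripped of a trailing parenthesized semantic tag
  (fully-specified-name suffixes such as "(disorder)").

The rendered definition can then be profiled against the content-model
parameters it touches: the supertype clause maps to "Supertype" and each
attribute maps through a configurable attribute -> tag table.
"""

from __future__ import annotations

import re
from typing import Literal, Mapping, Optional

import yaml

from .core import SCTExpression, StructuredDefinition, _Frozen, nfc

__all__ = [
    "RenderStyle",
    "strip_semantic_tag",
    "verbalize",
    "profile_structured_definition",
    "DEFAULT_PROFILE_MAP",
    "load_profile_map",
]

#: Connective introducing every non-final refinement clause.
CONNECTIVE_THAT = "that"
#: Connective introducing the final refinement clause (when there are >= 2).
CONNECTIVE_AND = "and"


class RenderStyle(_Frozen):
    """Rendering mode for structured definitions."""

    mode: Literal["sentence", "outline"] = "sentence"


_TAG_RE = re.compile(r"^(.*\S)\s+\([^()]*\)\s*$", re.DOTALL)


def strip_semantic_tag(term: str) -> str:
    """Drop one trailing parenthesized tag: "Disease (disorder)" -> "Disease".

    Only a parenthetical that is the final token is removed; parentheses
    elsewhere in the term are untouched.
    """
    m = _TAG_RE.match(term)
    return m.group(1) if m else term


def verbalize(
    expr: SCTExpression, subject_term: str, style: Optional[RenderStyle] = None
) -> StructuredDefinition:
    """Render *expr* as a structured definition of *subject_term*.

    Deterministic and total on valid expressions.  The outline lines joined
    by single spaces plus a terminal period equal the sentence rendering.
    """
    if style is None:
        style = RenderStyle()
    subject = strip_semantic_tag(nfc(subject_term).strip())
    if not subject:
        raise ValueError("subject term must be non-empty")
    supertypes = tuple(strip_semantic_tag(c.term) for c in expr.focus)
    refinements = expr.all_refinements()
    clauses_terms = tuple(
        (strip_semantic_tag(r.attribute.term), strip_semantic_tag(r.value.term))
        for r in refinements
    )

    lines = [subject, "is a " + " and a ".join(supertypes)]
    n = len(clauses_terms)
    for i, (attr, value) in enumerate(clauses_terms):
        conn = CONNECTIVE_AND if (n >= 2 and i == n - 1) else CONNECTIVE_THAT
        lines.append(f"{conn} has {attr} of {value}")

    sentence = " ".join(lines) + "."
    rendered = sentence if style.mode == "sentence" else "\n".join(lines)
    return StructuredDefinition(
        subject_term=subject,
        supertype_terms=supertypes,
        clauses=clauses_terms,
        rendered_text=rendered,
        rendered_outline=tuple(lines),
    )


#: Default attribute-term -> content-model profile tag table.  The supertype
#: clause always contributes "Supertype"; attributes outside this table are
#: reported as "Other:<attribute term>".
DEFAULT_PROFILE_MAP: dict[str, str] = {
    "Associated morphology": "Morphology",
    "Finding site": "Anatomical site",
    "Clinical course": "Temporal",
    "Causative agent": "Causal",
}


def profile_structured_definition(
    definition: StructuredDefinition,
    attribute_map: Optional[Mapping[str, str]] = None,
) -> list[str]:
    """Profile tags touched by a verbalized definition, first-occurrence order.

    Returns the deduplicated ordered tag list: "Supertype" when a supertype
    clause exists, then one tag per attribute clause via *attribute_map*
    (default :data:`DEFAULT_PROFILE_MAP`).
    """
    amap = DEFAULT_PROFILE_MAP if attribute_map is None else attribute_map
    tags: list[str] = []
    if definition.supertype_terms:
        tags.append("Supertype")
    for attr, _value in definition.clauses:
        tag = amap.get(attr, f"Other:{attr}")
        if tag not in tags:
            tags.append(tag)
    return tags


def load_profile_map(path) -> dict[str, str]:
    """Load an attribute -> tag override table from a YAML/JSON mapping file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in data.items()
    ):
        raise ValueError("profile map must be a flat string -> string mapping")
    return {nfc(k): nfc(v) for k, v in data.items()}
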