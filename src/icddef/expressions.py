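"""Parse and serialize SNOMED CT short-canonical-form expressions.

The supported grammar is the flat compositional-grammar subset used by short
normal forms::

    expr            := concept ("+" concept)* (":" refinement-part)?
    refinement-part := (group | attr-pair) ("," (group | attr-pair))*
    group           := "{" attr-pair ("," attr-pair)* "}"
    attr-pair       := concept "=" concept
    concept         := sctid ("|" term "|")?

Whitespace between tokens is ignored; term text is taken verbatim between
pipes with outer whitespace trimmed.  Nested expressions (a value that is
itself refined) are rejected: short canonical forms are flat.
"""

from __future__ import annotations

import json
from typing import Mapping, Optional

from .core import (
    AttributeRefinement,
    ConceptRef,
    ExpressionParseError,
    FormatError,
    RefinementGroup,
    SCTExpression,
)
from .core import TabularSource, _rows_from_source

__all__ = [
    "parse_expression",
    "serialize_expression",
    "expression_to_json_dict",
    "load_canonical_table",
    "CANONICAL_COLUMNS",
]

CANONICAL_COLUMNS = ("CONCEPTID", "FULLYSPECIFIEDNAME", "CANONICALEXPRESSION")


class _Cursor:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def at_end(self) -> bool:
        self.skip_ws()
        return self.pos >= len(self.text)

    def expect(self, char: str, what: str) -> None:
        self.skip_ws()
        if self.peek() != char:
            raise ExpressionParseError(f"expected {what!r}", self.pos)
        self.pos += 1


def _parse_concept(cur: _Cursor, terms: Optional[Mapping[str, str]]) -> ConceptRef:
    cur.skip_ws()
    start = cur.pos
    while cur.peek().isdigit():
        cur.pos += 1
    sctid = cur.text[start : cur.pos]
    if not sctid:
        raise ExpressionParseError("expected a concept identifier (digits)", start)
    cur.skip_ws()
    if cur.peek() == "|":
        open_pos = cur.pos
        cur.pos += 1
        close = cur.text.find("|", cur.pos)
        if close < 0:
            raise ExpressionParseError("unbalanced '|' in term", open_pos)
        term = cur.text[cur.pos : close].strip()
        if not term:
            raise ExpressionParseError("empty term between pipes", open_pos)
        cur.pos = close + 1
    elif terms is not None and sctid in terms:
        term = terms[sctid]
    else:
        term = sctid
    return ConceptRef(sctid=sctid, term=term)


def _parse_pair(cur: _Cursor, terms: Optional[Mapping[str, str]]) -> AttributeRefinement:
    attribute = _parse_concept(cur, terms)
    cur.expect("=", "=")
    value = _parse_concept(cur, terms)
    cur.skip_ws()
    if cur.peek() == ":":
        raise ExpressionParseError("nested expressions are not supported", cur.pos)
    return AttributeRefinement(attribute=attribute, value=value)


def parse_expression(
    text: str, terms: Optional[Mapping[str, str]] = None
) -> SCTExpression:
    """Parse a short-canonical-form expression string.

    Parameters
    ----------
    text:
        The expression, e.g.
        ``"100001 |Disease| : 100006 |Finding site| = 100007 |Myocardium structure|"``.
    terms:
        Optional sctid -> preferred-term lookup for concepts written without an
        embedded ``|term|``; absent from the lookup, the sctid doubles as term.

    Raises
    ------
    ExpressionParseError
        On malformed input, with the character offset of the defect.
    """
    if not text or not text.strip():
        raise ExpressionParseError("empty expression", 0)
    cur = _Cursor(text)
    focus = [_parse_concept(cur, terms)]
    while True:
        cur.skip_ws()
        if cur.peek() == "+":
            cur.pos += 1
            focus.append(_parse_concept(cur, terms))
        else:
            break
    groups: list[RefinementGroup] = []
    ungrouped: list[AttributeRefinement] = []
    cur.skip_ws()
    if cur.peek() == ":":
        cur.pos += 1
        while True:
            cur.skip_ws()
            if cur.peek() == "{":
                open_pos = cur.pos
                cur.pos += 1
                members = [_parse_pair(cur, terms)]
                while True:
                    cur.skip_ws()
                    if cur.peek() == ",":
                        cur.pos += 1
                        members.append(_parse_pair(cur, terms))
                    elif cur.peek() == "}":
                        cur.pos += 1
                        break
                    else:
                        raise ExpressionParseError("unbalanced '{' in group", open_pos)
                groups.append(RefinementGroup(refinements=tuple(members)))
            else:
                ungrouped.append(_parse_pair(cur, terms))
            cur.skip_ws()
            if cur.peek() == ",":
                cur.pos += 1
                continue
            break
    if not cur.at_end():
        raise ExpressionParseError(f"unexpected character {cur.peek()!r}", cur.pos)
    return SCTExpression(focus=tuple(focus), groups=tuple(groups), ungrouped=tuple(ungrouped))


def _concept_str(c: ConceptRef) -> str:
    return f"{c.sctid} |{c.term}|"


def _pair_str(r: AttributeRefinement) -> str:
    return f"{_concept_str(r.attribute)} = {_concept_str(r.value)}"


def serialize_expression(expr: SCTExpression) -> str:
    """Serialize canonically: single spaces around ':', '=', ',', '+'.

    Groups are emitted (braced) before ungrouped refinements; terms are always
    emitted.  ``parse_expression(serialize_expression(e))`` is structurally
    identical to ``e``, and equal structures yield byte-identical strings.
    """
    out = " + ".join(_concept_str(c) for c in expr.focus)
    parts = [
        "{ " + " , ".join(_pair_str(r) for r in g.refinements) + " }" for g in expr.groups
    ]
    parts.extend(_pair_str(r) for r in expr.ungrouped)
    if parts:
        out += " : " + " , ".join(parts)
    return out


def expression_to_json_dict(expr: SCTExpression) -> dict:
    """Plain-dict rendering of the parsed structure (for JSON output)."""

    def concept(c: ConceptRef) -> dict:
        return {"sctid": c.sctid, "term": c.term}

    def pair(r: AttributeRefinement) -> dict:
        return {"attribute": concept(r.attribute), "value": concept(r.value)}

    return {
        "focus": [concept(c) for c in expr.focus],
        "groups": [[pair(r) for r in g.refinements] for g in expr.groups],
        "ungrouped": [pair(r) for r in expr.ungrouped],
    }


def load_canonical_table(
    source: TabularSource, terms: Optional[Mapping[str, str]] = None
) -> tuple[dict[str, tuple[str, SCTExpression]], int]:
    """Load a canonical table: sctid -> (fully specified name, expression).

    The table is a TSV with header columns CONCEPTID, FULLYSPECIFIEDNAME and
    CANONICALEXPRESSION.  Rows whose expression fails to parse are skipped;
    the skip count is returned alongside the mapping.
    """
    rows = _rows_from_source(source)
    if rows:
        missing = [c for c in CANONICAL_COLUMNS if c not in rows[0]]
        if missing:
            raise FormatError(f"canonical table missing column(s) {missing}")
    mapping: dict[str, tuple[str, SCTExpression]] = {}
    skipped = 0
    for row in rows:
        sctid = str(row.get(CANONICAL_COLUMNS[0]) or "").strip()
        fsn = str(row.get(CANONICAL_COLUMNS[1]) or "").strip()
        expr_text = str(row.get(CANONICAL_COLUMNS[2]) or "")
        if not sctid or not sctid.isdigit():
            skipped += 1
            continue
        try:
            mapping[sctid] = (fsn, parse_expression(expr_text, terms))
        except (ExpressionParseError, ValueError):
            skipped += 1
    return mapping, skipped


def dump_expression_json(expr: SCTExpression) -> str:
    return json.dumps(expression_to_json_dict(expr), ensure_ascii=False, indent=2)
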