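import random

import pytest

from icddef.fixtures import (
    DEFAULT_ATTRIBUTES,
    build_in_paper_fixture,
    random_expression,
)
from icddef.core import ConceptRef

# The worked-example expression behind "Acute myocardial infarction"
AMI_EXPR = (
    "100001 |Disease| : "
    "100002 |Clinical course| = 100003 |Sudden onset AND/OR short duration| , "
    "100004 |Associated morphology| = 100005 |Acute infarct| , "
    "100006 |Finding site| = 100007 |Myocardium structure|"
)

AMI_OUTLINE = (
    "Acute myocardial infarction",
    "is a Disease",
    "that has Clinical course of Sudden onset AND/OR short duration",
    "that has Associated morphology of Acute infarct",
    "and has Finding site of Myocardium structure",
)


@pytest.fixture(scope="session")
def in_paper_bundle():
    return build_in_paper_fixture()


@pytest.fixture()
def bundle_paths(tmp_path, in_paper_bundle):
    return in_paper_bundle.write(tmp_path / "inputs")


def run_linking(bundle, lang="en"):
    """Run the in-memory linking path on a fixture bundle.

    Returns (filtered records, deduplicated entries, crosswalk index) — the
    inputs coverage_stats expects — without touching the filesystem.
    """
    from icddef.expressions import load_canonical_table
    from icddef.fixtures import (
        CANONICAL_HEADER,
        CROSSWALK_HEADER,
        DEFINITION_HEADER,
    )
    from icddef.linker import (
        dedupe_entries,
        filter_disease_records,
        index_crosswalk,
        link_lod_definitions,
        link_structured_definitions,
        load_crosswalk_table,
        load_definition_table,
        lod_rows_to_graph,
    )

    idx = index_crosswalk(
        load_crosswalk_table(
            [dict(zip(CROSSWALK_HEADER, r)) for r in bundle.crosswalk_rows]
        )
    )
    records = filter_disease_records(lod_rows_to_graph(bundle.lod_rows), lang)
    canon, _ = load_canonical_table(
        [dict(zip(CANONICAL_HEADER, r)) for r in bundle.canonical_rows]
    )
    pre = load_definition_table(
        [dict(zip(DEFINITION_HEADER, r)) for r in bundle.definition_rows]
    )
    entries = dedupe_entries(
        link_lod_definitions(records, idx)
        + link_structured_definitions(canon, idx)
        + pre
    )
    return records, entries, idx


_SUPERTYPES = tuple(
    ConceptRef(sctid=str(100000 + i), term=t)
    for i, t in enumerate(
        ["Disease", "Clinical finding", "Disorder of system", "Syndrome (disorder)"]
    )
)
_VALUES = tuple(
    ConceptRef(sctid=str(200000 + i), term=t)
    for i, t in enumerate(
        [
            "Acute infarct",
            "Stenosis",
            "Myocardium structure",
            "Sudden onset AND/OR short duration",
            "Chronic inflammation (morphologic abnormality)",
            "Renal structure",
        ]
    )
)


def make_random_expression(rng: random.Random, n_refinements_range=(0, 4)):
    """Draw a random flat expression over a small mixed vocabulary."""
    return random_expression(
        rng, _SUPERTYPES, DEFAULT_ATTRIBUTES, _VALUES, n_refinements_range
    )
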