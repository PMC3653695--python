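"""End-to-end pipeline: inputs -> parse -> verbalize -> link -> RDF -> report.

The pipeline is a pure function of (inputs, config, seed): re-runs with the
same configuration write identical outputs, with the wall-clock timestamp
isolated in a single report field.  Outputs are ``defs.tsv`` (the integrated
definition entries), ``graph.ttl`` (the named-graph Turtle export),
``stats.json`` (coverage statistics) and ``report.json`` (config echo,
per-stage record counts, per-source and per-category entry counts).
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict

from .core import ConfigError, DefinitionEntry, IcddefError, load_hierarchy_table
from .expressions import load_canonical_table
from .fixtures import FixtureBundle, GeneratorConfig, build_in_paper_fixture, generate
from .linker import (
    coverage_stats,
    dedupe_entries,
    filter_disease_records,
    index_crosswalk,
    link_lod_definitions,
    link_structured_definitions,
    load_crosswalk_table,
    load_definition_table,
    load_lod_graph,
    write_definitions_tsv,
)
from .rdf import build_graph, serialize_turtle

__all__ = ["InputPaths", "PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(IcddefError):
    """A stage failed; carries the stage name and the underlying error."""

    def __init__(self, stage: str, error: Exception):
        self.stage = stage
        self.error = error
        super().__init__(f"stage {stage!r} failed: {error}")


class InputPaths(BaseModel):
    model_config = ConfigDict(frozen=True)

    crosswalk: Optional[str] = None
    lod: Optional[str] = None
    canonical: Optional[str] = None
    definitions: Optional[str] = None
    hierarchy: Optional[str] = None


class PipelineConfig(BaseModel):
    """One pipeline run: either explicit input files or a fixture source.

    Exactly one of ``inputs``, ``generator`` or ``in_paper`` drives the run;
    generated/in-paper inputs are materialized under ``<out_dir>/inputs`` so
    the run is replayable from files.
    """

    model_config = ConfigDict(frozen=True)

    inputs: Optional[InputPaths] = None
    generator: Optional[GeneratorConfig] = None
    in_paper: bool = False
    lang: str = "en"
    source_tag: str = "DBpedia"
    out_dir: str = "."

    def echo(self) -> dict:
        """Config echo for the report; output paths excluded by design."""
        data = self.model_dump(exclude={"out_dir"})
        if data.get("generator") and data["generator"].get("attribute_vocabulary"):
            data["generator"]["attribute_vocabulary"] = [
                c["term"] for c in data["generator"]["attribute_vocabulary"]
            ]
        return data


def _as_config(config: Union[PipelineConfig, dict, str, Path]) -> PipelineConfig:
    if isinstance(config, PipelineConfig):
        return config
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    try:
        return PipelineConfig.model_validate(config)
    except Exception as exc:
        raise ConfigError(f"invalid pipeline config: {exc}") from exc


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ConfigError, PipelineStageError):
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: Union[PipelineConfig, dict, str, Path]) -> dict:
    """Execute all stages and write defs.tsv, graph.ttl, stats.json, report.json.

    Returns the run report (also written as JSON).  Configuration problems —
    a missing input file, no input source at all — raise :class:`ConfigError`
    before any output is written; stage failures raise
    :class:`PipelineStageError` naming the stage.
    """
    cfg = _as_config(config)
    out_dir = Path(cfg.out_dir)

    sources = [cfg.inputs is not None, cfg.generator is not None, cfg.in_paper]
    if sum(sources) != 1:
        raise ConfigError("exactly one of inputs, generator, in_paper must be set")

    bundle: Optional[FixtureBundle] = None
    if cfg.generator is not None:
        bundle = generate(cfg.generator)
    elif cfg.in_paper:
        bundle = build_in_paper_fixture()

    if bundle is not None:
        paths = bundle.write(out_dir / "inputs")
    else:
        assert cfg.inputs is not None
        named = cfg.inputs.model_dump()
        for field in ("crosswalk", "lod", "canonical"):
            if not named.get(field):
                raise ConfigError(f"inputs.{field}: required input not configured")
        paths = {}
        for field, value in named.items():
            if value is None:
                continue
            p = Path(value)
            if not p.is_file():
                raise ConfigError(f"inputs.{field}: no such file {value!r}")
            paths[field] = p

    # ---- load ----
    canon, canon_skipped = _stage("load_canonical")(load_canonical_table)(paths["canonical"])
    crosswalk = _stage("load_crosswalk")(load_crosswalk_table)(paths["crosswalk"])
    lod_graph = _stage("load_lod")(load_lod_graph)(paths["lod"])
    pre_keyed = (
        _stage("load_definitions")(load_definition_table)(paths["definitions"])
        if "definitions" in paths
        else []
    )
    hierarchy = (
        _stage("load_hierarchy")(load_hierarchy_table)(paths["hierarchy"])
        if "hierarchy" in paths
        else {}
    )
    labels = {code: cat.label for code, cat in hierarchy.items() if cat.label}

    # ---- filter + link ----
    records = _stage("filter_lod")(filter_disease_records)(lod_graph, cfg.lang)
    index = _stage("index_crosswalk")(index_crosswalk)(crosswalk)
    lod_entries = _stage("link_lod")(link_lod_definitions)(
        records, index, cfg.source_tag, labels
    )
    structured_entries = _stage("link_structured")(link_structured_definitions)(
        canon, index, labels
    )
    pre_keyed = [
        e if e.icd_label or e.icd_code not in labels
        else e.model_copy(update={"icd_label": labels[e.icd_code]})
        for e in pre_keyed
    ]

    entries = dedupe_entries([*lod_entries, *structured_entries, *pre_keyed])

    stats = _stage("coverage_stats")(coverage_stats)(records, entries, index)

    # ---- export ----
    entries_by_code: dict[str, list[DefinitionEntry]] = {}
    for e in entries:
        entries_by_code.setdefault(e.icd_code, []).append(e)
    graph = _stage("export_rdf")(build_graph)(hierarchy.values(), entries_by_code)
    turtle = serialize_turtle(graph)

    by_source: dict[str, int] = {}
    for e in entries:
        by_source[e.ontology_id] = by_source.get(e.ontology_id, 0) + 1

    report = {
        "config": cfg.echo(),
        "seed": cfg.generator.seed if cfg.generator is not None else None,
        "counts": {
            "canonical_rows": len(canon),
            "canonical_skipped": canon_skipped,
            "crosswalk_records": len(crosswalk),
            "lod_triples": len(lod_graph),
            "filtered_lod_records": len(records),
            "pre_keyed_definitions": len(pre_keyed),
            "hierarchy_categories": len(hierarchy),
            "definition_entries": len(entries),
            "graph_triples": len(graph),
        },
        "entries_by_source": dict(sorted(by_source.items())),
        "entries_by_category": {
            code: len(es) for code, es in sorted(entries_by_code.items())
        },
        "coverage": stats.model_dump(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }

    out_dir.mkdir(parents=True, exist_ok=True)
    write_definitions_tsv(entries, out_dir / "defs.tsv")
    (out_dir / "graph.ttl").write_text(turtle, "utf-8")
    (out_dir / "stats.json").write_text(
        json.dumps(stats.model_dump(), indent=2, sort_keys=True) + "\n", "utf-8"
    )
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", "utf-8"
    )
    return report
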