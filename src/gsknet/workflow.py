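"""Declarative, reproducible integration workflows.

A workflow is an ordered list of steps — parse, merge, map, transform,
export — described in a YAML (or equivalent XML) document.  Steps refer
to named graphs: parsers create them, ``merge`` unions them, mapping and
collapsing operators transform them in place, exporters write them out.
Running a workflow yields the final graph plus an integration log with
per-step concept/relation deltas and captured warnings, so a build can
be audited and reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import yaml
from lxml import etree

from . import integrate, oxl, readers, textmine
from .errors import WorkflowError
from .graph import KnowledgeGraph
from .metamodel import MetaModel


# ---------------------------------------------------------------------------
# plugin registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Plugin:
    name: str
    kind: str  #: parser | transform | export | merge
    func: Optional[Callable] = None
    required: tuple[str, ...] = ()
    #: parameters holding file paths, resolved against the workflow dir
    paths: tuple[str, ...] = ()


def _parse_tabular(source, spec: dict) -> KnowledgeGraph:
    return readers.parse_tabular(source, readers.TableSpec.from_dict(spec))


def _textmine(g: KnowledgeGraph, gene_class: str = "Gene",
              term_class: str = "TO", gene_min_len: int = 3,
              term_min_len: int = 4, gene_case_sensitive: bool = True) -> int:
    gene_dict = textmine.build_dictionary(
        g, gene_class, min_len=gene_min_len,
        case_sensitive=gene_case_sensitive)
    term_dict = textmine.build_dictionary(
        g, term_class, min_len=term_min_len, case_sensitive=False)
    return textmine.cooccurrence_map(g, gene_dict, term_dict)


def _external2go(g: KnowledgeGraph, mapping_source):
    return dataclasses.asdict(integrate.external2go_map(g, mapping_source))


def _collapse(g: KnowledgeGraph):
    return dataclasses.asdict(integrate.collapse_equal(g))


PLUGINS: dict[str, Plugin] = {
    p.name: p for p in [
        Plugin("parse_fasta_gff3", "parser", readers.parse_fasta_gff3,
               required=("gff3_source", "fasta_source", "taxid"),
               paths=("gff3_source", "fasta_source")),
        Plugin("parse_obo", "parser", readers.parse_obo,
               required=("source",), paths=("source",)),
        Plugin("parse_gaf", "parser", readers.parse_gaf,
               required=("source",), paths=("source",)),
        Plugin("parse_tabular", "parser", _parse_tabular,
               required=("source", "spec"), paths=("source",)),
        Plugin("parse_publications", "parser", readers.parse_publications,
               required=("source",), paths=("source",)),
        Plugin("parse_uniprot_min", "parser", readers.parse_uniprot_min,
               required=("source",), paths=("source",)),
        Plugin("merge", "merge"),
        Plugin("accession_map", "transform", integrate.accession_map),
        Plugin("name_map", "transform", integrate.name_map),
        Plugin("sequence_map", "transform", integrate.sequence_map),
        Plugin("colocation_map", "transform", integrate.colocation_map),
        Plugin("proximity_map", "transform", integrate.proximity_map),
        Plugin("external2go_map", "transform", _external2go,
               required=("mapping_source",), paths=("mapping_source",)),
        Plugin("collapse_equal", "transform", _collapse),
        Plugin("textmine_cooccurrence", "transform", _textmine),
        Plugin("write_oxl", "export", oxl.write_oxl,
               required=("destination",), paths=("destination",)),
        Plugin("write_json", "export", oxl.write_json,
               required=("destination",), paths=("destination",)),
    ]
}


# ---------------------------------------------------------------------------
# workflow specification
# ---------------------------------------------------------------------------

@dataclass
class Step:
    plugin: str
    params: dict = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)  #: merge inputs
    graph: Optional[str] = None    #: graph label for transform/export
    output: Optional[str] = None   #: label created (parser/merge)

    def label_used(self) -> list[str]:
        if self.plugin == "merge":
            return list(self.inputs)
        return [self.graph] if self.graph else []


@dataclass
class WorkflowSpec:
    steps: list[Step]
    seed: int = 0
    base_dir: Path = field(default_factory=Path)

    def validate(self) -> None:
        """Type-check every step before execution: plugins must resolve,
        required parameters be present, and graph labels be defined
        before use."""
        defined: set[str] = set()
        problems: list[str] = []
        for i, step in enumerate(self.steps, 1):
            plugin = PLUGINS.get(step.plugin)
            if plugin is None:
                problems.append(f"step {i}: unknown plugin {step.plugin!r}")
                continue
            for key in plugin.required:
                if key not in step.params:
                    problems.append(
                        f"step {i} ({step.plugin}): missing required "
                        f"parameter {key!r}")
            if plugin.kind == "parser":
                if not step.output:
                    problems.append(
                        f"step {i} ({step.plugin}): parser needs an output label")
            elif plugin.kind == "merge":
                if not step.output:
                    problems.append(f"step {i} (merge): missing output label")
                if not step.inputs:
                    problems.append(f"step {i} (merge): no input labels")
            else:
                if not step.graph:
                    problems.append(
                        f"step {i} ({step.plugin}): missing graph label")
            for label in step.label_used():
                if label not in defined:
                    problems.append(
                        f"step {i} ({step.plugin}): graph label {label!r} "
                        f"not defined by an earlier step")
            if step.output:
                defined.add(step.output)
        if problems:
            raise WorkflowError("; ".join(problems))

    def to_yaml(self) -> str:
        doc = {
            "seed": self.seed,
            "steps": [
                {
                    "plugin": s.plugin,
                    **({"params": s.params} if s.params else {}),
                    **({"inputs": s.inputs} if s.inputs else {}),
                    **({"graph": s.graph} if s.graph else {}),
                    **({"output": s.output} if s.output else {}),
                }
                for s in self.steps
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)


def _steps_from_doc(doc: dict) -> list[Step]:
    steps = []
    for raw in doc.get("steps", []):
        steps.append(Step(
            plugin=raw.get("plugin", ""),
            params=dict(raw.get("params", {}) or {}),
            inputs=list(raw.get("inputs", []) or []),
            graph=raw.get("graph"),
            output=raw.get("output"),
        ))
    return steps


def load_workflow(source) -> WorkflowSpec:
    """Load and validate a workflow document (YAML, or XML for fidelity
    with pipeline descriptions exchanged as XML)."""
    base_dir = Path()
    if hasattr(source, "read"):
        text = source.read()
    else:
        base_dir = Path(source).parent
        with open(source, "rt", encoding="utf-8") as fh:
            text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("<"):
        doc = _doc_from_xml(text)
    else:
        doc = yaml.safe_load(text) or {}
    spec = WorkflowSpec(
        steps=_steps_from_doc(doc),
        seed=int(doc.get("seed", 0)),
        base_dir=base_dir,
    )
    spec.validate()
    return spec


def _doc_from_xml(text: str) -> dict:
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise WorkflowError(f"malformed workflow XML: {exc}") from exc
    steps = []
    for el in root.findall("step"):
        params = {}
        for p in el.findall("param"):
            params[p.get("name")] = yaml.safe_load(p.text or "")
        steps.append({
            "plugin": el.get("plugin"),
            "params": params,
            "inputs": [i.get("ref") for i in el.findall("input")],
            "graph": el.get("graph"),
            "output": el.get("output"),
        })
    return {"seed": int(root.get("seed", "0")), "steps": steps}


# ---------------------------------------------------------------------------
# execution with integration logging
# ---------------------------------------------------------------------------

@dataclass
class StepRecord:
    step: str
    params: dict
    duration: float
    concepts_before: int
    concepts_after: int
    relations_before: int
    relations_after: int
    warnings: list[str] = field(default_factory=list)
    result: object = None


@dataclass
class IntegrationLog:
    records: list[StepRecord] = field(default_factory=list)

    def to_text(self) -> str:
        lines = []
        for i, r in enumerate(self.records, 1):
            lines.append(
                f"[{i:02d}] {r.step}: concepts {r.concepts_before}"
                f" -> {r.concepts_after}, relations {r.relations_before}"
                f" -> {r.relations_after} ({r.duration:.2f}s)"
            )
            if r.result is not None:
                lines.append(f"     result: {r.result}")
            for w in r.warnings:
                lines.append(f"     warning: {w}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps([dataclasses.asdict(r) for r in self.records],
                          indent=2, default=str)


class _WarningCapture(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def run_workflow(
    spec: WorkflowSpec, base_dir: Optional[Path] = None
) -> tuple[KnowledgeGraph, IntegrationLog]:
    """Execute a validated workflow.

    Steps run in order; a step failure aborts with a
    :class:`WorkflowError` naming the step, the partial log attached as
    ``exc.log``.  Returns the graph last touched and the full log.
    """
    spec.validate()
    base = Path(base_dir) if base_dir is not None else spec.base_dir
    graphs: dict[str, KnowledgeGraph] = {}
    log = IntegrationLog()
    final: Optional[KnowledgeGraph] = None
    logger = logging.getLogger("gsknet")
    for i, step in enumerate(spec.steps, 1):
        plugin = PLUGINS[step.plugin]
        params = dict(step.params)
        for key in plugin.paths:
            if key in params and isinstance(params[key], str):
                params[key] = str(base / params[key])
        target = graphs.get(step.graph) if step.graph else None
        before_c = len(target) if target else 0
        before_r = target.num_relations if target else 0
        capture = _WarningCapture()
        logger.addHandler(capture)
        t0 = time.perf_counter()
        try:
            if plugin.kind == "parser":
                result_graph = plugin.func(**params)
                graphs[step.output] = result_graph
                result = None
                after = result_graph
            elif plugin.kind == "merge":
                merged = KnowledgeGraph(MetaModel.default())
                for label in step.inputs:
                    merged.add_graph(graphs[label])
                graphs[step.output] = merged
                result = None
                after = merged
            elif plugin.kind == "export":
                plugin.func(target, **params)
                result = params.get("destination")
                after = target
            else:  # transform
                result = plugin.func(target, **params)
                after = target
        except Exception as exc:
            logger.removeHandler(capture)
            err = WorkflowError(
                f"step {i} ({step.plugin}) failed: {exc}")
            err.log = log  # partial log for inspection
            raise err from exc
        finally:
            if capture in logger.handlers:
                logger.removeHandler(capture)
        log.records.append(StepRecord(
            step=step.plugin, params=step.params,
            duration=time.perf_counter() - t0,
            concepts_before=before_c, concepts_after=len(after),
            relations_before=before_r, relations_after=after.num_relations,
            warnings=capture.messages, result=result,
        ))
        final = after
    if final is None:
        raise WorkflowError("workflow has no steps")
    return final, log
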