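"""Structural validation of instance graphs against the MCRO schema.

The validator makes the schema's implicit expectations machine-checkable:

* **V1** every individual typed by a section class is reachable from some
  ``ModelCardReport`` individual through asserted *has part* links;
* **V2** object-property assertions between individuals respect declared
  domain/range after materialization;
* **V3** date annotations parse as ISO 8601;
* **V4** every report individual has at least one section part (error),
  and a warning flags each of the four main sections it lacks;
* **V5** no disjointness violations (delegates to the reasoner).

Problems are findings, never exceptions; an empty report means the graph
is schema-valid.  Missing main sections are warnings rather than errors
because sample cards in circulation cover, but are not required to fill,
every section.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

from . import vocab
from .ontgraph import Literal, OntologyGraph
from .reasoning import check_consistency, materialize
from .schema import MAIN_SECTIONS, mcro_iri

__all__ = ["Finding", "ValidationReport", "validate_instances"]


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    rule_id: str   # "V1".."V5"
    subject: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity.upper()} {self.rule_id} {self.subject}: {self.message}"


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    def render(self) -> str:
        if not self.findings:
            return "OK: graph is schema-valid\n"
        return "\n".join(str(f) for f in self.findings) + "\n"

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "findings": [
                {
                    "severity": f.severity,
                    "rule": f.rule_id,
                    "subject": f.subject,
                    "message": f.message,
                }
                for f in self.findings
            ],
        }


def _is_iso8601(value: str) -> bool:
    try:
        _dt.date.fromisoformat(value[:10])
        if len(value) > 10:
            _dt.datetime.fromisoformat(value)
        return True
    except ValueError:
        return False


def validate_instances(
    graph: OntologyGraph, schema: OntologyGraph
) -> ValidationReport:
    """Apply rules V1-V5 to ``graph`` (which may embed the schema)."""
    report = ValidationReport()
    add = report.findings.append
    materialized = materialize(graph)

    individuals = {t.iri for t in graph.individuals()}

    asserted_types: dict[str, set[str]] = {}
    for ax in graph.axioms_of_kind("type-assertion"):
        if ax.subject in individuals:
            asserted_types.setdefault(ax.subject, set()).add(str(ax.object))
    mat_types: dict[str, set[str]] = {}
    for ax in materialized.axioms_of_kind("type-assertion"):
        if ax.subject in individuals:
            mat_types.setdefault(ax.subject, set()).add(str(ax.object))

    report_class = mcro_iri("ModelCardReport")
    reports = sorted(
        i for i, ts in mat_types.items() if report_class in ts
    )

    section_classes = {
        t.iri
        for t in schema.terms_of_category("class")
        if t.iri.startswith(vocab.MCRO_NS) and t.iri != report_class
    }

    # asserted has-part edges between individuals
    children: dict[str, set[str]] = {}
    for ax in graph.axioms_of_kind("object-property-assertion"):
        if (
            ax.predicate == vocab.HAS_PART
            and ax.subject in individuals
            and str(ax.object) in individuals
            and not ax.inferred
        ):
            children.setdefault(ax.subject, set()).add(str(ax.object))

    reachable: set[str] = set()
    stack = list(reports)
    while stack:
        node = stack.pop()
        for child in children.get(node, ()):
            if child not in reachable:
                reachable.add(child)
                stack.append(child)

    # V1: orphan section individuals
    for individual in sorted(individuals):
        if individual in reports:
            continue
        if mat_types.get(individual, set()) & section_classes:
            if individual not in reachable:
                add(Finding(
                    "error", "V1", individual,
                    "section individual is not linked to any model card "
                    "report via has-part",
                ))

    # V2: domain/range of object-property assertions
    domains: dict[str, set[str]] = {}
    ranges: dict[str, set[str]] = {}
    for ax in schema.axioms_of_kind("domain"):
        domains.setdefault(ax.subject, set()).add(str(ax.object))
    for ax in schema.axioms_of_kind("range"):
        ranges.setdefault(ax.subject, set()).add(str(ax.object))
    for ax in sorted(
        graph.axioms_of_kind("object-property-assertion"),
        key=lambda a: (a.subject, a.predicate or "", str(a.object)),
    ):
        if ax.subject not in individuals or str(ax.object) not in individuals:
            continue
        for cls in domains.get(ax.predicate, ()):
            if cls not in mat_types.get(ax.subject, set()):
                add(Finding(
                    "error", "V2", ax.subject,
                    f"subject of {ax.predicate} lacks domain type {cls}",
                ))
        for cls in ranges.get(ax.predicate, ()):
            if cls not in mat_types.get(str(ax.object), set()):
                add(Finding(
                    "error", "V2", str(ax.object),
                    f"object of {ax.predicate} lacks range type {cls}",
                ))

    # V3: ISO 8601 dates
    for ax in sorted(
        graph.axioms_of_kind("annotation-assertion", "data-property-assertion"),
        key=lambda a: (a.subject, a.predicate or "", str(a.object)),
    ):
        if ax.predicate == vocab.DCTERMS_DATE and isinstance(ax.object, Literal):
            if not _is_iso8601(ax.object.value):
                add(Finding(
                    "error", "V3", ax.subject,
                    f"date annotation {ax.object.value!r} is not ISO 8601",
                ))

    # V4: report composition
    main_iris = {name: mcro_iri(name) for name in MAIN_SECTIONS}
    for rep in reports:
        parts = children.get(rep, set())
        if not parts:
            add(Finding(
                "error", "V4", rep,
                "model card report has no section parts",
            ))
            continue
        present = set()
        for child in parts:
            present |= mat_types.get(child, set())
        for name, iri in main_iris.items():
            if iri not in present:
                add(Finding(
                    "warning", "V4", rep,
                    f"main section {name} is absent",
                ))

    # V5: disjointness
    for inc in check_consistency(graph):
        add(Finding(
            "error", "V5", inc.individual,
            f"typed by disjoint classes {inc.class_a} and {inc.class_b}",
        ))

    return report
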