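"""Single-pattern triple matching over (optionally materialized) graphs.

This is the smallest query facility that demonstrates inference-aware
search over encoded model cards: match one (subject, predicate, object)
pattern, with ``None`` / ``"?"`` as wildcard, against the assertion-level
statements of a graph.  With ``infer=True`` the pattern runs against the
reasoner's materialization, so e.g. asking for the parts of a card
individual also returns parts beyond the first-degree connection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .ontgraph import ASSERTION_KINDS, Literal, OntologyGraph
from .reasoning import materialize
from .vocab import RDF_NS

__all__ = ["match", "Binding", "PatternTermError"]

RDF_TYPE = RDF_NS + "type"

Wildcard = None
PatternTerm = Union[str, Literal, None]


class PatternTermError(KeyError):
    """A non-wildcard pattern term does not resolve in the graph."""


@dataclass(frozen=True)
class Binding:
    """One matching statement; each matching axiom yields exactly one row."""

    subject: str
    predicate: str
    object: Union[str, Literal]
    inferred: bool


def _resolve(graph: OntologyGraph, term: PatternTerm, role: str) -> PatternTerm:
    if term is None or term == "?":
        return None
    if isinstance(term, Literal):
        return term
    # CURIE expansion under the graph's prefixes
    if "://" not in term and ":" in term:
        prefix, local = term.split(":", 1)
        if prefix in graph.prefixes:
            term = graph.prefixes[prefix] + local
    if role in {"subject", "predicate"} or "://" in term:
        if term not in graph.terms and term != RDF_TYPE:
            raise PatternTermError(
                f"{role} term {term!r} does not resolve in the graph"
            )
    return term


def match(
    graph: OntologyGraph,
    pattern: tuple[PatternTerm, PatternTerm, PatternTerm],
    infer: bool = False,
) -> list[Binding]:
    """All assertion-level statements matching ``pattern``.

    The predicate position matches ``rdf:type`` for type assertions; object
    position strings match IRIs, or literal values when the statement
    carries a literal.
    """
    s_pat, p_pat, o_pat = (
        _resolve(graph, pattern[0], "subject"),
        _resolve(graph, pattern[1], "predicate"),
        _resolve(graph, pattern[2], "object"),
    )
    source = materialize(graph) if infer else graph

    rows: list[Binding] = []
    for ax in source.axioms:
        if ax.kind not in ASSERTION_KINDS:
            continue
        predicate = RDF_TYPE if ax.kind == "type-assertion" else ax.predicate
        if s_pat is not None and ax.subject != s_pat:
            continue
        if p_pat is not None and predicate != p_pat:
            continue
        if o_pat is not None:
            if isinstance(ax.object, Literal):
                want = o_pat.value if isinstance(o_pat, Literal) else o_pat
                if ax.object.value != want:
                    continue
            elif isinstance(o_pat, Literal) or ax.object != o_pat:
                continue
        rows.append(
            Binding(ax.subject, predicate, ax.object, ax.inferred)
        )
    rows.sort(key=lambda b: (b.subject, b.predicate, str(b.object), b.inferred))
    return rows
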