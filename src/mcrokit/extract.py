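"""Seed-based ontology subset extraction.

Given a list of seed terms, the extractor keeps the seeds, the transitive
superclass closure of every seed, every axiom whose subject and object are
both retained, and the property terms those axioms use.  This is the
minimal upward-closure variant of module extraction — enough to carve a
small, closed import (e.g. a filtered Software Ontology) out of a large
source ontology, in the spirit of seed-file driven extraction workflows.
Entailment-preserving locality modules are deliberately out of scope.
"""

from __future__ import annotations

from .ontgraph import AxiomRec, OntologyGraph

__all__ = ["extract_subset", "read_seed_file", "UnknownSeedError"]


class UnknownSeedError(KeyError):
    """One or more seed IRIs are absent from the source ontology."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(
            "seed terms not present in ontology: " + ", ".join(self.missing)
        )


def read_seed_file(text: str) -> list[str]:
    """Parse a seed list: one IRI or CURIE per line, ``#`` comments allowed."""
    seeds: list[str] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            seeds.append(line)
    return seeds


def _expand(ontology: OntologyGraph, seed: str) -> str:
    """CURIE -> IRI under the ontology's prefixes; IRIs pass through."""
    if "://" in seed:
        return seed
    prefix, _, local = seed.partition(":")
    if local and prefix in ontology.prefixes:
        return ontology.prefixes[prefix] + local
    return seed


def extract_subset(ontology: OntologyGraph, seeds: list[str]) -> OntologyGraph:
    """Closed sub-ontology of ``ontology`` induced by ``seeds``.

    Seeds may be absolute IRIs or CURIEs resolvable under the ontology's
    prefix table.  Unknown seeds raise :class:`UnknownSeedError` listing
    every missing IRI.
    """
    resolved = [_expand(ontology, s) for s in seeds]
    missing = [iri for iri in resolved if iri not in ontology.terms]
    if missing:
        raise UnknownSeedError(missing)

    supers: dict[str, set[str]] = {}
    for ax in ontology.axioms_of_kind("subclass-of"):
        supers.setdefault(ax.subject, set()).add(str(ax.object))

    retained: set[str] = set()
    stack = list(resolved)
    while stack:
        iri = stack.pop()
        if iri in retained:
            continue
        retained.add(iri)
        stack.extend(supers.get(iri, ()))

    sub = OntologyGraph(prefixes=ontology.prefixes)
    kept: list[AxiomRec] = []
    for ax in ontology.axioms:
        if ax.subject not in retained:
            continue
        if isinstance(ax.object, str) and ax.object not in retained:
            continue
        kept.append(ax)
    for iri in sorted(retained):
        sub.add_term(ontology.terms[iri])
    for ax in kept:
        if ax.predicate is not None and ax.predicate not in sub.terms:
            sub.add_term(ontology.terms[ax.predicate])
    for ax in kept:
        sub.add_axiom(ax)
    sub.check_closed()
    return sub
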