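"""In-memory ontology container: terms, axioms and prefixes.

The toolkit represents both schema-level ontologies and instance graphs with
the same structure: a table of named terms (:class:`TermRef`), a set of
axioms (:class:`AxiomRec`) over those terms, and a prefix map for compact
IRI rendering.  The container is *closed*: every IRI an axiom mentions must
be present in the term table.  Axioms are held with set semantics, so a
statement is counted once no matter how often it is asserted.

Symmetric axiom kinds (equivalent-class, disjoint-with) are stored once,
with subject and object ordered lexicographically by IRI, so that graph
equality and statement counting are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Union

__all__ = [
    "Category",
    "TermRef",
    "Literal",
    "AxiomRec",
    "OntologyGraph",
    "OntologyStats",
    "StructuralError",
    "CATEGORIES",
    "LOGICAL_KINDS",
    "SYMMETRIC_KINDS",
    "ASSERTION_KINDS",
]

Category = str

CATEGORIES = frozenset(
    {
        "class",
        "object-property",
        "data-property",
        "annotation-property",
        "individual",
    }
)

#: axiom kinds that count as logical axioms (declarations and annotations
#: are terminological bookkeeping, matching the usual editor metric)
LOGICAL_KINDS = frozenset(
    {
        "subclass-of",
        "equivalent-class",
        "disjoint-with",
        "transitive-property",
        "inverse-of",
        "domain",
        "range",
        "type-assertion",
        "object-property-assertion",
        "data-property-assertion",
    }
)

SYMMETRIC_KINDS = frozenset({"equivalent-class", "disjoint-with"})

#: assertion-level kinds: the facts about individuals (and punned classes)
ASSERTION_KINDS = frozenset(
    {
        "type-assertion",
        "object-property-assertion",
        "data-property-assertion",
        "annotation-assertion",
    }
)

ALL_KINDS = LOGICAL_KINDS | {"annotation-assertion", "declaration"}


class StructuralError(ValueError):
    """A graph violates a structural invariant (e.g. dangling IRI)."""


@dataclass(frozen=True)
class TermRef:
    """A named ontology term.

    ``curie`` is a cached compact rendering; it is display metadata and is
    excluded from equality so that graphs compare on substance.
    """

    iri: str
    category: Category
    label: Optional[str] = None
    curie: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown term category: {self.category!r}")
        if not self.iri:
            raise ValueError("term IRI must be non-empty")


@dataclass(frozen=True)
class Literal:
    """An RDF literal: text plus optional datatype IRI or language tag."""

    value: str
    datatype: Optional[str] = None
    lang: Optional[str] = None

    def __post_init__(self) -> None:
        if self.datatype is not None and self.lang is not None:
            raise ValueError("a literal cannot carry both datatype and language")


Obj = Union[str, Literal, None]


@dataclass(frozen=True)
class AxiomRec:
    """One statement.

    ``subject`` and (IRI-valued) ``object`` are term IRIs; ``predicate`` is
    the property IRI for assertion kinds and ``None`` for kinds whose
    predicate is fixed by the kind itself (subclass-of, equivalent-class,
    ...).  ``inferred`` marks reasoner-derived statements and is excluded
    from equality, so an inferred duplicate of an asserted axiom is the
    same axiom.
    """

    kind: str
    subject: str
    predicate: Optional[str] = None
    object: Obj = None
    inferred: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown axiom kind: {self.kind!r}")
        if self.kind in LOGICAL_KINDS and isinstance(self.subject, Literal):
            raise ValueError("logical axioms never carry literal subjects")

    def iris(self) -> Iterator[str]:
        """All term IRIs this axiom mentions."""
        yield self.subject
        if self.predicate is not None:
            yield self.predicate
        if isinstance(self.object, str):
            yield self.object


#: expected category of subject/object per kind; None means unconstrained.
#: Property assertions admit classes as well as individuals: class-level
#: relationship links (the OBO "some values from" pattern) are stored as
#: punned property assertions between class terms.
_KIND_SUBJECT = {
    "subclass-of": {"class"},
    "equivalent-class": {"class"},
    "disjoint-with": {"class"},
    "transitive-property": {"object-property"},
    "inverse-of": {"object-property"},
    "domain": {"object-property", "data-property"},
    "range": {"object-property", "data-property"},
    "type-assertion": {"individual", "class"},
    "object-property-assertion": {"individual", "class"},
    "data-property-assertion": {"individual", "class"},
    "annotation-assertion": None,
    "declaration": None,
}

_KIND_OBJECT = {
    "subclass-of": {"class"},
    "equivalent-class": {"class"},
    "disjoint-with": {"class"},
    "transitive-property": None,  # no object
    "inverse-of": {"object-property"},
    "domain": {"class"},
    "range": None,  # class or datatype IRI
    "type-assertion": {"class"},
    "object-property-assertion": {"individual", "class"},
    "data-property-assertion": None,  # literal
    "annotation-assertion": None,
    "declaration": None,
}


@dataclass
class OntologyStats:
    """The four headline ontology metrics."""

    n_classes: int
    n_object_properties: int
    n_data_properties: int
    n_logical_axioms: int

    def astuple(self) -> tuple[int, int, int, int]:
        return (
            self.n_classes,
            self.n_object_properties,
            self.n_data_properties,
            self.n_logical_axioms,
        )


class OntologyGraph:
    """A closed set of terms plus a set of axioms over them."""

    def __init__(self, prefixes: Optional[dict[str, str]] = None) -> None:
        self.terms: dict[str, TermRef] = {}
        self.axioms: set[AxiomRec] = set()
        self.prefixes: dict[str, str] = dict(prefixes or {})
        # Constructs outside the supported dialect, preserved opaquely on
        # read.  Not part of graph equality and never re-serialized.
        self.unsupported: list[tuple[str, str]] = []

    # -- term management ---------------------------------------------------

    def add_term(self, term: TermRef) -> TermRef:
        """Insert a term; categories are immutable once set."""
        existing = self.terms.get(term.iri)
        if existing is not None:
            if existing.category != term.category:
                raise StructuralError(
                    f"term {term.iri} already present with category "
                    f"{existing.category!r}; cannot re-declare as {term.category!r}"
                )
            if existing.label is None and term.label is not None:
                self.terms[term.iri] = replace(existing, label=term.label,
                                               curie=existing.curie)
            return self.terms[term.iri]
        if term.curie is None:
            term = replace(term, curie=self.curie(term.iri))
        self.terms[term.iri] = term
        return term

    def term(self, iri: str) -> TermRef:
        try:
            return self.terms[iri]
        except KeyError:
            raise KeyError(f"no term {iri} in graph") from None

    def curie(self, iri: str) -> str:
        """Compact form of ``iri`` under the declared prefixes, else the IRI."""
        best = None
        for prefix, ns in self.prefixes.items():
            if iri.startswith(ns) and len(ns) > (len(self.prefixes.get(best, ""))
                                                 if best else 0):
                local = iri[len(ns):]
                if local and "/" not in local and "#" not in local:
                    best = prefix
        if best is not None:
            return f"{best}:{iri[len(self.prefixes[best]):]}"
        return iri

    # -- axiom management --------------------------------------------------

    @staticmethod
    def normalize(axiom: AxiomRec) -> AxiomRec:
        """Directionally normalize symmetric kinds by lexicographic IRI order."""
        if (
            axiom.kind in SYMMETRIC_KINDS
            and isinstance(axiom.object, str)
            and axiom.object < axiom.subject
        ):
            return replace(axiom, subject=axiom.object, object=axiom.subject)
        return axiom

    def add_axiom(self, axiom: AxiomRec) -> AxiomRec:
        """Insert an axiom, checking closure and category constraints."""
        axiom = self.normalize(axiom)
        for iri in axiom.iris():
            if iri not in self.terms:
                raise StructuralError(f"axiom references undeclared term {iri}")
        want = _KIND_SUBJECT.get(axiom.kind)
        if want is not None:
            cat = self.terms[axiom.subject].category
            if cat not in want:
                raise StructuralError(
                    f"{axiom.kind} axiom requires subject category in "
                    f"{sorted(want)}, got {cat!r} for {axiom.subject}"
                )
        want = _KIND_OBJECT.get(axiom.kind)
        if want is not None and isinstance(axiom.object, str):
            cat = self.terms[axiom.object].category
            if cat not in want:
                raise StructuralError(
                    f"{axiom.kind} axiom requires object category in "
                    f"{sorted(want)}, got {cat!r} for {axiom.object}"
                )
        if isinstance(axiom.object, Literal) and axiom.kind not in {
            "data-property-assertion",
            "annotation-assertion",
        }:
            raise StructuralError(
                f"{axiom.kind} axiom cannot carry a literal object"
            )
        self.axioms.add(axiom)
        return axiom

    def has_axiom(
        self,
        kind: str,
        subject: str,
        predicate: Optional[str] = None,
        object: Obj = None,
    ) -> bool:
        """Membership test; symmetric kinds match in either orientation."""
        probe = self.normalize(
            AxiomRec(kind=kind, subject=subject, predicate=predicate, object=object)
        )
        return probe in self.axioms

    def axioms_of_kind(self, *kinds: str) -> Iterator[AxiomRec]:
        for ax in self.axioms:
            if ax.kind in kinds:
                yield ax

    # -- invariants --------------------------------------------------------

    def check_closed(self) -> None:
        """Raise :class:`StructuralError` naming the first dangling IRI."""
        for ax in self.axioms:
            for iri in ax.iris():
                if iri not in self.terms:
                    raise StructuralError(
                        f"graph is not closed: axiom {ax.kind} references "
                        f"undeclared term {iri}"
                    )

    # -- bulk operations ---------------------------------------------------

    def copy(self) -> "OntologyGraph":
        g = OntologyGraph(self.prefixes)
        g.terms = dict(self.terms)
        g.axioms = set(self.axioms)
        g.unsupported = list(self.unsupported)
        return g

    def update(self, other: "OntologyGraph") -> None:
        """In-place union with another graph."""
        for prefix, ns in other.prefixes.items():
            self.prefixes.setdefault(prefix, ns)
        for term in other.terms.values():
            self.add_term(term)
        for ax in other.axioms:
            self.add_axiom(ax)

    def terms_of_category(self, category: Category) -> Iterator[TermRef]:
        for term in self.terms.values():
            if term.category == category:
                yield term

    def individuals(self) -> Iterator[TermRef]:
        return self.terms_of_category("individual")

    # -- comparison --------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return (
            self.terms == other.terms
            and self.axioms == other.axioms
            and self.prefixes == other.prefixes
        )

    def __repr__(self) -> str:
        return (
            f"<OntologyGraph terms={len(self.terms)} axioms={len(self.axioms)}>"
        )


def stats_for(
    graph: OntologyGraph, namespace: Optional[str] = None
) -> OntologyStats:
    """Count the four headline metrics, optionally restricted to one namespace.

    With ``namespace`` given, a term counts if its IRI starts with the
    namespace; a logical axiom counts if its subject is in the namespace or,
    for symmetric kinds, if either side is (an ontology asserts its own
    alignment axioms regardless of orientation after normalization).
    """
    graph.check_closed()

    def in_ns(iri: str) -> bool:
        return namespace is None or iri.startswith(namespace)

    n_classes = sum(1 for t in graph.terms_of_category("class") if in_ns(t.iri))
    n_obj = sum(
        1 for t in graph.terms_of_category("object-property") if in_ns(t.iri)
    )
    n_data = sum(
        1 for t in graph.terms_of_category("data-property") if in_ns(t.iri)
    )
    n_logical = 0
    for ax in graph.axioms:
        if ax.kind not in LOGICAL_KINDS:
            continue
        if in_ns(ax.subject):
            n_logical += 1
        elif ax.kind in SYMMETRIC_KINDS and isinstance(ax.object, str) and in_ns(
            ax.object
        ):
            n_logical += 1
    return OntologyStats(n_classes, n_obj, n_data, n_logical)
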