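"""Forward-chaining materialization and disjointness checking.

A small, complete rule engine for the axiom fragment instance-encoded
model cards actually use:

* R1  transitivity      — ``p`` transitive, ⟨a p b⟩, ⟨b p c⟩ ⇒ ⟨a p c⟩
* R2  inverse           — ``p`` inverse-of ``q``, ⟨a p b⟩ ⇒ ⟨b q a⟩ (both ways)
* R3  subclass chain    — A⊑B, B⊑C ⇒ A⊑C
* R4  type inheritance  — ⟨x type A⟩, A⊑B ⇒ ⟨x type B⟩
* R5  equivalence       — A≡B ⇒ A⊑B and B⊑A (feeding R3/R4)

The rules are monotone over a finite base, so the least fixpoint exists
and the semi-naive loop (only facts derived in the previous round can fire
new rules) terminates.  Derived axioms carry ``inferred=True``; asserted
axioms are never removed or re-flagged.

Consistency checking materializes first, then reports one
:class:`Inconsistency` per individual and unordered disjoint class pair
whose (possibly inherited) types collide — the classic *software* vs
*algorithm* clash where one individual is asserted to be both.

Property-chain, functional and cardinality axioms are outside this
fragment; the Turtle reader surfaces them as labelled unsupported records
rather than silently dropping them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ontgraph import AxiomRec, OntologyGraph

__all__ = ["materialize", "check_consistency", "Inconsistency"]


@dataclass(frozen=True)
class Inconsistency:
    """An individual typed by two classes declared (or inherited) disjoint.

    ``provenance`` records, for each clashing type, whether it was asserted
    or inferred during materialization.
    """

    individual: str
    class_a: str
    class_b: str
    provenance: tuple[str, str] = ("asserted", "asserted")

    def __str__(self) -> str:  # pragma: no cover - display helper
        return (
            f"{self.individual} is typed by disjoint classes "
            f"{self.class_a} ({self.provenance[0]}) and "
            f"{self.class_b} ({self.provenance[1]})"
        )


def materialize(graph: OntologyGraph) -> OntologyGraph:
    """Least fixpoint of R1-R5 over ``graph``; the input is contained."""
    graph.check_closed()
    g = graph.copy()

    transitive = {ax.subject for ax in g.axioms_of_kind("transitive-property")}
    inverses: dict[str, set[str]] = {}
    for ax in g.axioms_of_kind("inverse-of"):
        inverses.setdefault(ax.subject, set()).add(str(ax.object))
        inverses.setdefault(str(ax.object), set()).add(ax.subject)

    # R5: equivalence seeds subclass facts in both directions
    seed: set[AxiomRec] = set()
    for ax in g.axioms_of_kind("equivalent-class"):
        seed.add(AxiomRec("subclass-of", ax.subject, object=str(ax.object),
                          inferred=True))
        seed.add(AxiomRec("subclass-of", str(ax.object), object=ax.subject,
                          inferred=True))

    # indexes over the growing fact set
    sub_of: dict[str, set[str]] = {}       # class -> direct/derived supers
    sub_inv: dict[str, set[str]] = {}      # class -> known subs
    types: dict[str, set[str]] = {}        # entity -> classes
    by_type: dict[str, set[str]] = {}      # class -> entities
    succ: dict[tuple[str, str], set[str]] = {}  # (prop, a) -> {b}
    pred: dict[tuple[str, str], set[str]] = {}  # (prop, b) -> {a}

    def index(ax: AxiomRec) -> None:
        if ax.kind == "subclass-of":
            sub_of.setdefault(ax.subject, set()).add(str(ax.object))
            sub_inv.setdefault(str(ax.object), set()).add(ax.subject)
        elif ax.kind == "type-assertion":
            types.setdefault(ax.subject, set()).add(str(ax.object))
            by_type.setdefault(str(ax.object), set()).add(ax.subject)
        elif ax.kind == "object-property-assertion":
            p, a, b = ax.predicate, ax.subject, str(ax.object)
            succ.setdefault((p, a), set()).add(b)
            pred.setdefault((p, b), set()).add(a)

    for ax in g.axioms:
        index(ax)

    facts = set(g.axioms)
    delta = set()
    for ax in seed:
        if ax not in facts:
            facts.add(ax)
            index(ax)
            delta.add(ax)

    def derive(ax: AxiomRec, out: set[AxiomRec]) -> None:
        """Consequences of one newly-established fact."""
        if ax.kind == "object-property-assertion":
            p, a, b = ax.predicate, ax.subject, str(ax.object)
            if p in transitive:
                for c in succ.get((p, b), ()):   # R1 forward
                    out.add(AxiomRec("object-property-assertion", a,
                                     predicate=p, object=c, inferred=True))
                for z in pred.get((p, a), ()):   # R1 backward
                    out.add(AxiomRec("object-property-assertion", z,
                                     predicate=p, object=b, inferred=True))
            for q in inverses.get(p, ()):        # R2
                out.add(AxiomRec("object-property-assertion", b,
                                 predicate=q, object=a, inferred=True))
        elif ax.kind == "subclass-of":
            a, b = ax.subject, str(ax.object)
            for c in sub_of.get(b, ()):          # R3 forward
                if c != a:
                    out.add(AxiomRec("subclass-of", a, object=c, inferred=True))
            for z in sub_inv.get(a, ()):         # R3 backward
                if z != b:
                    out.add(AxiomRec("subclass-of", z, object=b, inferred=True))
            for x in by_type.get(a, ()):         # R4 (new subclass edge)
                out.add(AxiomRec("type-assertion", x, object=b, inferred=True))
        elif ax.kind == "type-assertion":
            x, a = ax.subject, str(ax.object)
            for b in sub_of.get(a, ()):          # R4 (new type fact)
                out.add(AxiomRec("type-assertion", x, object=b, inferred=True))

    # round 0: existing facts may already interact (asserted chains)
    fresh: set[AxiomRec] = set()
    for ax in facts:
        derive(ax, fresh)
    delta |= {ax for ax in fresh if ax not in facts}

    while delta:
        for ax in delta:
            facts.add(ax)
            index(ax)
        fresh = set()
        for ax in delta:
            derive(ax, fresh)
        delta = {ax for ax in fresh if ax not in facts}

    g.axioms = facts
    g.check_closed()
    return g


def check_consistency(graph: OntologyGraph) -> list[Inconsistency]:
    """Disjointness violations in the materialized graph.

    Returns one record per (individual, unordered disjoint class pair);
    an empty list means the graph is consistent for this fragment.
    """
    m = materialize(graph)
    asserted_types = {
        (ax.subject, str(ax.object))
        for ax in graph.axioms_of_kind("type-assertion")
    }
    types: dict[str, set[str]] = {}
    for ax in m.axioms_of_kind("type-assertion"):
        if m.terms[ax.subject].category == "individual":
            types.setdefault(ax.subject, set()).add(str(ax.object))

    found: list[Inconsistency] = []
    seen: set[tuple[str, str, str]] = set()
    for ax in m.axioms_of_kind("disjoint-with"):
        a, b = sorted((ax.subject, str(ax.object)))
        for individual, tset in sorted(types.items()):
            if a in tset and b in tset and (individual, a, b) not in seen:
                seen.add((individual, a, b))
                prov = tuple(
                    "asserted" if (individual, c) in asserted_types
                    else "inferred"
                    for c in (a, b)
                )
                found.append(Inconsistency(individual, a, b, prov))
    return found
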