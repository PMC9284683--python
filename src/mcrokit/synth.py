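"""Synthetic fixture generators for graphs and ontologies.

Alongside :func:`mcrokit.card.generate_card` (synthetic model cards), this
module generates the random ontology structures the property suite runs
on: partonomy instance graphs for the reasoner, typed graphs with planted
disjointness violations for the consistency checker, taxonomies for the
extractor, and mixed graphs for serialization round-trips.  Everything is
seed-deterministic.

These fixtures emulate the *structure* of encoded model card artifacts —
named terms, shallow taxonomies, tree-ish partonomies, literal
annotations — not the content of any real ontology; conclusions from
tests on them are about the toolkit's algebra, not about coverage of
real-world vocabulary.
"""

from __future__ import annotations

import random

from . import vocab
from .ontgraph import AxiomRec, Literal, OntologyGraph, TermRef

__all__ = [
    "random_partonomy",
    "random_typed_graph",
    "random_taxonomy",
    "random_ontology",
    "EX",
]

EX = "https://example.org/x#"


def _base_graph() -> OntologyGraph:
    g = OntologyGraph(prefixes={"ex": EX, "obo": vocab.OBO,
                                "rdfs": vocab.RDFS_NS, "owl": vocab.OWL_NS,
                                "skos": vocab.SKOS_NS,
                                "dcterms": vocab.DCTERMS_NS,
                                "xsd": vocab.XSD_NS})
    g.add_term(vocab.stub_term(vocab.HAS_PART))
    g.add_term(vocab.stub_term(vocab.PART_OF))
    g.add_axiom(AxiomRec("transitive-property", vocab.HAS_PART))
    g.add_axiom(AxiomRec("inverse-of", vocab.HAS_PART, object=vocab.PART_OF))
    return g


def random_partonomy(seed: int, n_individuals: int = 8,
                     edge_prob: float = 0.35) -> OntologyGraph:
    """Random DAG of individuals wired with *has part* edges.

    Edges only go from lower to higher index, so the asserted partonomy is
    acyclic; the reasoner's transitive closure therefore equals plain
    reachability, which tests check against an independent oracle.
    """
    rng = random.Random(seed)
    g = _base_graph()
    names = [f"{EX}i{k}" for k in range(n_individuals)]
    for iri in names:
        g.add_term(TermRef(iri=iri, category="individual"))
    for a in range(n_individuals):
        for b in range(a + 1, n_individuals):
            if rng.random() < edge_prob:
                g.add_axiom(
                    AxiomRec("object-property-assertion", names[a],
                             predicate=vocab.HAS_PART, object=names[b])
                )
    return g


def random_taxonomy(seed: int, n_classes: int = 6) -> OntologyGraph:
    """Random forest-shaped subclass taxonomy over ``n_classes`` classes."""
    rng = random.Random(seed)
    g = _base_graph()
    names = [f"{EX}C{k}" for k in range(n_classes)]
    for iri in names:
        g.add_term(TermRef(iri=iri, category="class"))
    for k in range(1, n_classes):
        parent = rng.randrange(k)  # earlier index -> acyclic
        g.add_axiom(AxiomRec("subclass-of", names[k], object=names[parent]))
    return g


def random_typed_graph(
    seed: int,
    n_individuals: int = 6,
    n_classes: int = 5,
    n_violations: int = 0,
) -> tuple[OntologyGraph, set[tuple[str, str, str]]]:
    """Taxonomy + typed individuals, optionally with planted disjoint clashes.

    Returns the graph and the set of planted ``(individual, class_a,
    class_b)`` violations (classes ordered lexicographically), where the
    individual is typed by subclasses of both sides of a declared disjoint
    pair.
    """
    rng = random.Random(seed)
    g = random_taxonomy(seed * 31 + 7, n_classes)
    classes = [f"{EX}C{k}" for k in range(n_classes)]
    individuals = [f"{EX}i{k}" for k in range(n_individuals)]
    for iri in individuals:
        g.add_term(TermRef(iri=iri, category="individual"))
        g.add_axiom(
            AxiomRec("type-assertion", iri, object=rng.choice(classes))
        )

    # two disjoint root-ish classes, fresh so planting is controllable
    a = f"{EX}DisA"
    b = f"{EX}DisB"
    for iri in (a, b):
        g.add_term(TermRef(iri=iri, category="class"))
    g.add_axiom(AxiomRec("disjoint-with", a, object=b))
    suba = f"{EX}DisAsub"
    subb = f"{EX}DisBsub"
    for iri, parent in ((suba, a), (subb, b)):
        g.add_term(TermRef(iri=iri, category="class"))
        g.add_axiom(AxiomRec("subclass-of", iri, object=parent))

    planted: set[tuple[str, str, str]] = set()
    victims = rng.sample(individuals, min(n_violations, len(individuals)))
    for iri in victims:
        # type through subclasses so detection must pass through inference
        g.add_axiom(AxiomRec("type-assertion", iri, object=suba))
        g.add_axiom(AxiomRec("type-assertion", iri, object=subb))
        planted.add((iri, *sorted((a, b))))
    return g, planted


def random_ontology(seed: int) -> OntologyGraph:
    """Mixed schema + instance graph exercising every serializable kind."""
    rng = random.Random(seed)
    g, _ = random_typed_graph(seed, n_individuals=rng.randrange(1, 6),
                              n_classes=rng.randrange(2, 6))
    dp = f"{EX}score"
    ap = f"{EX}comment"
    g.add_term(TermRef(iri=dp, category="data-property", label="score"))
    g.add_term(TermRef(iri=ap, category="annotation-property", label="comment"))
    classes = sorted(t.iri for t in g.terms_of_category("class"))
    individuals = sorted(t.iri for t in g.terms_of_category("individual"))
    g.add_axiom(AxiomRec("domain", dp, object=rng.choice(classes)))
    if rng.random() < 0.5 and len(classes) >= 2:
        x, y = rng.sample(classes, 2)
        g.add_axiom(AxiomRec("equivalent-class", x, object=y))
    for iri in individuals:
        if rng.random() < 0.6:
            g.add_axiom(
                AxiomRec("data-property-assertion", iri, predicate=dp,
                         object=Literal(str(rng.randrange(100))))
            )
        if rng.random() < 0.6:
            g.add_axiom(
                AxiomRec("annotation-assertion", iri, predicate=ap,
                         object=Literal(f"note {rng.randrange(10)}",
                                        lang="en"))
            )
        if rng.random() < 0.4 and len(individuals) >= 2:
            other = rng.choice([x for x in individuals if x != iri])
            g.add_axiom(
                AxiomRec("object-property-assertion", iri,
                         predicate=vocab.HAS_PART, object=other)
            )
    return g
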