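"""Materialization and consistency against independent oracles.

The partonomy closure is checked against graph reachability computed by
networkx, and disjointness detection against exhaustive enumeration over
individuals and disjoint pairs; both oracles are independent of the
fixpoint engine.
"""

import networkx as nx
import pytest

from mcrokit import build_core_schema, check_consistency, materialize
from mcrokit import vocab
from mcrokit.ontgraph import AxiomRec, OntologyGraph, TermRef
from mcrokit.synth import EX, random_partonomy, random_typed_graph


def haspart_edges(graph, inferred=None):
    return {
        (ax.subject, str(ax.object))
        for ax in graph.axioms_of_kind("object-property-assertion")
        if ax.predicate == vocab.HAS_PART
        and (inferred is None or ax.inferred == inferred)
    }


def partof_edges(graph):
    return {
        (ax.subject, str(ax.object))
        for ax in graph.axioms_of_kind("object-property-assertion")
        if ax.predicate == vocab.PART_OF
    }


def test_two_level_card_closure_adds_partof_beyond_first_degree():
    """A card with a considerations section holding a trade-off part infers
    the grandparent has-part link and all three part-of links."""
    g = OntologyGraph(prefixes={"ex": EX})
    for stub in (vocab.HAS_PART, vocab.PART_OF):
        g.add_term(vocab.stub_term(stub))
    g.add_axiom(AxiomRec("transitive-property", vocab.HAS_PART))
    g.add_axiom(AxiomRec("inverse-of", vocab.HAS_PART, object=vocab.PART_OF))
    card, cons, trade = EX + "card", EX + "considerations", EX + "tradeoff"
    for iri in (card, cons, trade):
        g.add_term(TermRef(iri=iri, category="individual"))
    g.add_axiom(AxiomRec("object-property-assertion", card,
                         predicate=vocab.HAS_PART, object=cons))
    g.add_axiom(AxiomRec("object-property-assertion", cons,
                         predicate=vocab.HAS_PART, object=trade))

    m = materialize(g)
    assert haspart_edges(m) == {(card, cons), (cons, trade), (card, trade)}
    assert partof_edges(m) == {(cons, card), (trade, cons), (trade, card)}
    assert haspart_edges(m, inferred=True) == {(card, trade)}


def test_materialize_empty_graph_is_empty():
    assert materialize(OntologyGraph()).axioms == set()


@pytest.mark.parametrize("seed", range(20))
def test_closure_equals_reachability_oracle(seed):
    g = random_partonomy(seed, n_individuals=8)
    asserted = haspart_edges(g)
    m = materialize(g)

    dg = nx.DiGraph()
    dg.add_nodes_from(f"{EX}i{k}" for k in range(8))
    dg.add_edges_from(asserted)
    oracle = set(nx.transitive_closure(dg).edges())

    assert haspart_edges(m) == oracle
    assert partof_edges(m) == {(b, a) for a, b in oracle}


@pytest.mark.parametrize("seed", range(8))
def test_idempotence_and_monotonicity(seed):
    g = random_partonomy(seed * 13 + 1, n_individuals=9)
    m = materialize(g)
    assert g.axioms <= m.axioms
    again = materialize(m)
    assert again == m


def test_type_inheritance_through_equivalence_and_subclass():
    g = OntologyGraph(prefixes={"ex": EX})
    for name in ("A", "B", "C"):
        g.add_term(TermRef(iri=EX + name, category="class"))
    g.add_term(TermRef(iri=EX + "x", category="individual"))
    g.add_axiom(AxiomRec("subclass-of", EX + "A", object=EX + "B"))
    g.add_axiom(AxiomRec("equivalent-class", EX + "B", object=EX + "C"))
    g.add_axiom(AxiomRec("type-assertion", EX + "x", object=EX + "A"))
    m = materialize(g)
    types = {str(ax.object) for ax in m.axioms_of_kind("type-assertion")}
    assert types == {EX + "A", EX + "B", EX + "C"}
    # equivalence expands to mutual subclassing before type propagation
    assert m.has_axiom("subclass-of", EX + "B", object=EX + "C")
    assert m.has_axiom("subclass-of", EX + "C", object=EX + "B")


def test_disjoint_software_algorithm_individual_flagged_once():
    """An individual asserted as both software and algorithm under the
    disjointness axiom yields exactly one inconsistency."""
    g = build_core_schema()
    acme = EX + "differential-evolution-acme-variant"
    g.add_term(TermRef(iri=acme, category="individual",
                       label="differential evolution (acme-variant)"))
    g.add_axiom(AxiomRec("type-assertion", acme, object=vocab.SWO_SOFTWARE))
    g.add_axiom(AxiomRec("type-assertion", acme, object=vocab.IAO_ALGORITHM))
    found = check_consistency(g)
    assert len(found) == 1
    inc = found[0]
    assert inc.individual == acme
    assert {inc.class_a, inc.class_b} == {vocab.SWO_SOFTWARE, vocab.IAO_ALGORITHM}
    assert inc.provenance == ("asserted", "asserted")


def test_inherited_types_marked_inferred_in_provenance():
    g = OntologyGraph(prefixes={"ex": EX})
    for name in ("A", "B", "Asub"):
        g.add_term(TermRef(iri=EX + name, category="class"))
    g.add_term(TermRef(iri=EX + "x", category="individual"))
    g.add_axiom(AxiomRec("disjoint-with", EX + "A", object=EX + "B"))
    g.add_axiom(AxiomRec("subclass-of", EX + "Asub", object=EX + "A"))
    g.add_axiom(AxiomRec("type-assertion", EX + "x", object=EX + "Asub"))
    g.add_axiom(AxiomRec("type-assertion", EX + "x", object=EX + "B"))
    (inc,) = check_consistency(g)
    assert inc.provenance == ("inferred", "asserted")


def _consistency_oracle(graph):
    """Exhaustive check: every individual x declared-or-inherited disjoint
    pair, with hand-rolled superclass expansion."""
    supers = {}
    for ax in graph.axioms_of_kind("subclass-of"):
        supers.setdefault(ax.subject, set()).add(str(ax.object))

    def up(cls):
        out, stack = {cls}, [cls]
        while stack:
            for parent in supers.get(stack.pop(), ()):
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    types = {}
    for ax in graph.axioms_of_kind("type-assertion"):
        if graph.terms[ax.subject].category == "individual":
            expanded = types.setdefault(ax.subject, set())
            expanded |= up(str(ax.object))
    hits = set()
    for ax in graph.axioms_of_kind("disjoint-with"):
        a, b = sorted((ax.subject, str(ax.object)))
        for ind, tset in types.items():
            if a in tset and b in tset:
                hits.add((ind, a, b))
    return hits


@pytest.mark.parametrize("seed,n_violations", [(1, 0), (2, 1), (3, 2), (4, 3)])
def test_detection_matches_exhaustive_oracle(seed, n_violations):
    g, planted = random_typed_graph(seed, n_individuals=6,
                                    n_violations=n_violations)
    detected = {
        (inc.individual, inc.class_a, inc.class_b)
        for inc in check_consistency(g)
    }
    assert detected == _consistency_oracle(g)
    assert detected == planted
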