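"""Serialization: deterministic Turtle, dialect mapping, OWL/XML."""

import xml.etree.ElementTree as ET

import pytest

from mcrokit import read_turtle, stats, write_owl_xml, write_turtle
from mcrokit import vocab
from mcrokit.ontgraph import AxiomRec, OntologyGraph, TermRef
from mcrokit.rdfio import TurtleParseError, UnsupportedAxiomWarning
from mcrokit.synth import EX, random_ontology


def test_empty_graph_writes_only_prefix_block():
    g = OntologyGraph(prefixes={"ex": EX})
    text = write_turtle(g)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    assert lines == [f"@prefix ex: <{EX}> ."]
    assert read_turtle(text) == g


def test_output_is_byte_identical_across_calls(core):
    assert write_turtle(core) == write_turtle(core)
    assert "_:" not in write_turtle(core)  # no blank nodes ever


def test_core_schema_roundtrips(core):
    assert read_turtle(write_turtle(core)) == core


@pytest.mark.parametrize("seed", range(12))
def test_generated_graphs_roundtrip(seed):
    g = random_ontology(seed)
    assert read_turtle(write_turtle(g)) == g


@pytest.mark.parametrize("seed", [0, 5])
def test_stats_invariant_under_roundtrip(seed):
    g = random_ontology(seed)
    assert stats(read_turtle(write_turtle(g))).astuple() == stats(g).astuple()


def test_transitive_declaration_maps_to_axiom_kind():
    text = (
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .\n"
        "@prefix ex: <https://example.org/x#> .\n"
        "ex:p a owl:ObjectProperty, owl:TransitiveObjectProperty .\n"
    )
    g = read_turtle(text)
    assert g.has_axiom("transitive-property", EX + "p")
    assert g.terms[EX + "p"].category == "object-property"


def test_syntax_error_reports_line():
    with pytest.raises(TurtleParseError, match="line"):
        read_turtle("@prefix ex: <https://example.org/> .\nex:a ex:b .\n")


def test_blank_node_class_expression_is_unsupported_not_silent():
    text = (
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .\n"
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .\n"
        "@prefix ex: <https://example.org/x#> .\n"
        "ex:A a owl:Class ; rdfs:subClassOf [ a owl:Restriction ;"
        " owl:onProperty ex:p ; owl:someValuesFrom ex:B ] .\n"
        "ex:B a owl:Class .\n"
    )
    with pytest.warns(UnsupportedAxiomWarning):
        g = read_turtle(text)
    assert g.unsupported
    assert not any(g.axioms_of_kind("subclass-of"))
    # unsupported records never count as logical axioms
    assert stats(g).n_logical_axioms == 0


def test_reified_owl_axiom_is_decoded_to_its_kind():
    text = (
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .\n"
        "@prefix ex: <https://example.org/x#> .\n"
        "ex:A a owl:Class . ex:B a owl:Class .\n"
        "[] a owl:Axiom ; owl:annotatedSource ex:A ;\n"
        "   owl:annotatedProperty owl:equivalentClass ;\n"
        "   owl:annotatedTarget ex:B .\n"
    )
    g = read_turtle(text)
    assert g.has_axiom("equivalent-class", EX + "A", object=EX + "B")
    assert stats(g).n_logical_axioms == 1


def test_nary_disjointness_decomposes_into_pairs():
    text = (
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .\n"
        "@prefix ex: <https://example.org/x#> .\n"
        "ex:A a owl:Class . ex:B a owl:Class . ex:C a owl:Class .\n"
        "[] a owl:AllDisjointClasses ; owl:members (ex:A ex:B ex:C) .\n"
    )
    g = read_turtle(text)
    pairs = {
        (ax.subject, str(ax.object))
        for ax in g.axioms_of_kind("disjoint-with")
    }
    assert pairs == {(EX + "A", EX + "B"), (EX + "A", EX + "C"),
                     (EX + "B", EX + "C")}


def test_literals_keep_language_and_datatype():
    text = (
        "@prefix ex: <https://example.org/x#> .\n"
        "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .\n"
        "ex:i ex:p \"hello\"@en ; ex:q \"3\"^^xsd:integer ;"
        " ex:r \"with \\\"quotes\\\"\\nand newline\" .\n"
    )
    g = read_turtle(text)
    assert read_turtle(write_turtle(g)) == g
    values = {
        (ax.object.value, ax.object.lang, ax.object.datatype)
        for ax in g.axioms
        if ax.kind == "annotation-assertion"
    }
    assert ("hello", "en", None) in values
    assert ("3", None, vocab.XSD_NS + "integer") in values
    assert ('with "quotes"\nand newline', None, None) in values


def test_owl_xml_is_wellformed_and_complete(core):
    text = write_owl_xml(core)
    root = ET.fromstring(text)  # XML parser as the well-formedness oracle
    ns = "{http://www.w3.org/ns/owl2-xml}"
    assert root.tag == f"{ns}Ontology" or root.tag == "Ontology"
    tags = [el.tag.replace(ns, "") for el in root]
    assert tags.count("Declaration") == len(core.terms)
    n_sub = sum(1 for _ in core.axioms_of_kind("subclass-of"))
    assert tags.count("SubClassOf") == n_sub
    assert tags.count("EquivalentClasses") == 2
    assert tags.count("TransitiveObjectProperty") == 1
    assert write_owl_xml(core) == text  # deterministic


def test_one_type_assertion_one_class_assertion_element():
    g = OntologyGraph(prefixes={"ex": EX})
    g.add_term(TermRef(iri=EX + "C", category="class"))
    g.add_term(TermRef(iri=EX + "i", category="individual"))
    g.add_axiom(AxiomRec("type-assertion", EX + "i", object=EX + "C"))
    root = ET.fromstring(write_owl_xml(g))
    assertions = [el for el in root if el.tag.endswith("ClassAssertion")]
    assert len(assertions) == 1


def test_empty_graph_owl_xml_is_minimal_valid_document():
    root = ET.fromstring(write_owl_xml(OntologyGraph(prefixes={"ex": EX})))
    assert all(el.tag.endswith("Prefix") for el in root)
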