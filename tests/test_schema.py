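"""The core conceptual model: alignments, characteristics, metrics."""

import re

import pytest
import rdflib

from mcrokit import build_core_schema, check_consistency, stats, write_turtle
from mcrokit import vocab
from mcrokit.schema import MAIN_SECTIONS, mcro_iri, part_map, section_classes

TABLE_ALIGNMENTS = [
    # (section local name, link kind, predicate, target IRI)
    ("DatasetInformation", "is-about", vocab.IS_ABOUT, vocab.IAO_DATA_SET),
    ("ModelArchitecture", "is-about", vocab.IS_ABOUT, vocab.IAO_ALGORITHM),
    ("FormatInformation", "is-about", vocab.IS_ABOUT, vocab.IAO_DATA_FORMAT),
    ("VersionInformation", "is-about", vocab.IS_ABOUT, vocab.IAO_VERSION_NUMBER),
    ("LicenseInformation", "is-about", vocab.IS_ABOUT, vocab.SWO_LICENSE),
    ("ReferenceInformation", "equivalent", None, vocab.IAO_REFERENCE_SECTION),
    ("Graphic", "equivalent", None, vocab.IAO_GRAPH),
    ("CitationInformation", "has-part", vocab.HAS_PART, vocab.IAO_CITATION),
]


@pytest.mark.parametrize("name,kind,pred,target",
                         TABLE_ALIGNMENTS,
                         ids=[row[0] for row in TABLE_ALIGNMENTS])
def test_obo_alignment_axioms(core, name, kind, pred, target):
    """All eight section-to-OBO alignments are asserted with the OBO PURLs."""
    assert target in core.terms
    if kind == "equivalent":
        assert core.has_axiom("equivalent-class", mcro_iri(name), object=target)
    else:
        assert core.has_axiom("object-property-assertion", mcro_iri(name),
                              predicate=pred, object=target)


def test_report_and_sections_align_to_iao(core):
    assert core.has_axiom("subclass-of", mcro_iri("ModelCardReport"),
                          object=vocab.IAO_REPORT)
    for name in MAIN_SECTIONS:
        assert core.has_axiom("subclass-of", mcro_iri(name),
                              object=vocab.IAO_DOCUMENT_PART)
        assert core.has_axiom("object-property-assertion",
                              mcro_iri("ModelCardReport"),
                              predicate=vocab.HAS_PART, object=mcro_iri(name))


def test_graphic_collection_is_skos_collection(core):
    assert core.has_axiom("subclass-of", mcro_iri("GraphicCollection"),
                          object=vocab.SKOS_COLLECTION)


def test_has_part_is_transitive_with_declared_inverse(core):
    assert core.has_axiom("transitive-property", vocab.HAS_PART)
    assert core.has_axiom("inverse-of", vocab.HAS_PART, object=vocab.PART_OF)


def test_tradeoff_alternative_label_is_caveats(core):
    hits = [
        ax for ax in core.axioms_of_kind("annotation-assertion")
        if ax.subject == mcro_iri("TradeOff")
        and ax.predicate == vocab.SKOS_ALT_LABEL
    ]
    assert [ax.object.value for ax in hits] == ["Caveats"]


def test_software_and_algorithm_are_disjoint(core):
    assert core.has_axiom("disjoint-with", vocab.SWO_SOFTWARE,
                          object=vocab.IAO_ALGORITHM)


def test_build_is_deterministic():
    assert build_core_schema() == build_core_schema()


def test_graphic_collection_edge_is_configurable():
    about = build_core_schema(graphic_collection_edge="is-about")
    assert about.has_axiom("object-property-assertion",
                           mcro_iri("QuantitativeAnalysis"),
                           predicate=vocab.IS_ABOUT,
                           object=mcro_iri("GraphicCollection"))
    with pytest.raises(ValueError):
        build_core_schema(graphic_collection_edge="part-of")


def test_core_schema_is_self_consistent(core):
    assert check_consistency(core) == []


def test_core_native_feature_counts(core):
    """The MCRO-namespace core: 38 classes, no object properties, 11 data
    properties, 79 logical axioms."""
    s = stats(core, namespace=vocab.MCRO_NS)
    assert s.astuple() == (38, 0, 11, 79)


def test_stats_against_serialized_statement_enumeration(core):
    """Counts agree with a brute-force enumeration of the serialized
    statements by kind, done over rdflib triples independently of the
    container's own bookkeeping."""
    rg = rdflib.Graph()
    rg.parse(data=write_turtle(core), format="turtle")
    OWL = "http://www.w3.org/2002/07/owl#"
    RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
    RDFS = "http://www.w3.org/2000/01/rdf-schema#"

    def count(pred, obj=None):
        return sum(
            1 for _ in rg.triples(
                (None, rdflib.URIRef(pred),
                 rdflib.URIRef(obj) if obj else None))
        )

    n_classes = count(RDF + "type", OWL + "Class")
    n_obj = count(RDF + "type", OWL + "ObjectProperty")
    n_data = count(RDF + "type", OWL + "DatatypeProperty")
    meta = {OWL + "Class", OWL + "ObjectProperty", OWL + "DatatypeProperty",
            OWL + "AnnotationProperty", OWL + "NamedIndividual"}
    n_logical = (
        count(RDFS + "subClassOf")
        + count(OWL + "equivalentClass")
        + count(OWL + "disjointWith")
        + count(OWL + "inverseOf")
        + count(RDF + "type", OWL + "TransitiveObjectProperty")
        + sum(
            1 for s, p, o in rg
            if str(p) == RDF + "type" and str(o) not in meta
            and str(o) != OWL + "TransitiveObjectProperty"
        )
        # property assertions: named-object triples off the RDF(S)/OWL vocab
        + sum(
            1 for s, p, o in rg
            if isinstance(o, rdflib.URIRef)
            and not str(p).startswith((RDF, RDFS, OWL))
        )
    )
    assert stats(core).astuple() == (n_classes, n_obj, n_data, n_logical)


def test_section_vocabulary_and_nesting_map(core):
    kinds = section_classes(core)
    assert "ModelCardReport" not in kinds
    assert {"TradeOff", "User", "Graphic"} <= set(kinds)
    parts = part_map(core)
    assert set(MAIN_SECTIONS) <= parts["ModelCardReport"]
    assert "TradeOff" in parts["Considerations"]
    assert "User" in parts["ModelDetails"]
    # subclasses of an allowed kind are allowed
    assert "PrimaryUse" in parts["Considerations"]
    assert "TradeOff" not in parts["QuantitativeAnalysis"]
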