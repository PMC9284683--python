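"""Namespaces and stub terms for the external vocabularies MCRO aligns to.

MCRO (the Model Card Report Ontology) reuses terms from the OBO Foundry
ecosystem — BFO for partonomy, IAO for information artifacts, SWO for
software concepts — plus SKOS and Dublin Core for annotation.  The toolkit
does not re-host those ontologies; it carries *stub* terms: the IRI, label
and category of exactly the external terms the core model and the bundled
fixtures need.  This module is the single table resolving every external
label to its canonical published identifier.

One resolution is worth flagging: the ``note`` annotation is commonly
grouped with Dublin Core's description/date/source, but Dublin Core defines
no ``note`` property; the canonical published identifier is ``skos:note``,
which is what the toolkit uses.
"""

from __future__ import annotations

from .ontgraph import TermRef

# -- namespaces -----------------------------------------------------------

OBO = "http://purl.obolibrary.org/obo/"
SWO_NS = "http://www.ebi.ac.uk/swo/"
MCRO_NS = "https://w3id.org/mcro#"
#: namespace for minted model-card instance individuals
MCRI_NS = "https://w3id.org/mcro/report#"
SKOS_NS = "http://www.w3.org/2004/02/skos/core#"
DCTERMS_NS = "http://purl.org/dc/terms/"
PROV_NS = "http://www.w3.org/ns/prov#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"

#: default prefix table for every graph the toolkit builds
PREFIXES: dict[str, str] = {
    "obo": OBO,
    "swo": SWO_NS,
    "mcro": MCRO_NS,
    "mcri": MCRI_NS,
    "skos": SKOS_NS,
    "dcterms": DCTERMS_NS,
    "prov": PROV_NS,
    "rdf": RDF_NS,
    "rdfs": RDFS_NS,
    "owl": OWL_NS,
    "xsd": XSD_NS,
}

# -- BFO / IAO / SWO stub terms -------------------------------------------

HAS_PART = OBO + "BFO_0000051"          # has part (transitive)
PART_OF = OBO + "BFO_0000050"           # part of (inverse of has part)
IS_ABOUT = OBO + "IAO_0000136"          # is about
IAO_REPORT = OBO + "IAO_0000088"        # report
IAO_DOCUMENT_PART = OBO + "IAO_0000314" # document part
IAO_DATA_SET = OBO + "IAO_0000100"      # data set
IAO_ALGORITHM = OBO + "IAO_0000064"     # algorithm
IAO_DATA_FORMAT = OBO + "IAO_0000098"   # data format specification
IAO_VERSION_NUMBER = OBO + "IAO_0000129"  # version number
IAO_REFERENCE_SECTION = OBO + "IAO_0000320"  # reference section
IAO_GRAPH = OBO + "IAO_0000038"         # graph
IAO_CITATION = OBO + "IAO_0000301"      # citation
SWO_LICENSE = SWO_NS + "SWO_0000002"    # license
SWO_SOFTWARE = SWO_NS + "SWO_0000001"   # software

# -- annotation vocabulary ------------------------------------------------

SKOS_COLLECTION = SKOS_NS + "Collection"
SKOS_ALT_LABEL = SKOS_NS + "altLabel"
SKOS_NOTE = SKOS_NS + "note"
DCTERMS_DESCRIPTION = DCTERMS_NS + "description"
DCTERMS_DATE = DCTERMS_NS + "date"
DCTERMS_SOURCE = DCTERMS_NS + "source"
RDFS_LABEL = RDFS_NS + "label"

#: the four section annotation keys of the card format, in canonical order,
#: mapped to their annotation-property IRIs
ANNOTATION_PROPERTIES: dict[str, str] = {
    "note": SKOS_NOTE,
    "description": DCTERMS_DESCRIPTION,
    "date": DCTERMS_DATE,
    "source": DCTERMS_SOURCE,
}

#: stub TermRefs, keyed by IRI: (category, label)
_STUBS: dict[str, tuple[str, str]] = {
    HAS_PART: ("object-property", "has part"),
    PART_OF: ("object-property", "part of"),
    IS_ABOUT: ("object-property", "is about"),
    IAO_REPORT: ("class", "report"),
    IAO_DOCUMENT_PART: ("class", "document part"),
    IAO_DATA_SET: ("class", "data set"),
    IAO_ALGORITHM: ("class", "algorithm"),
    IAO_DATA_FORMAT: ("class", "data format specification"),
    IAO_VERSION_NUMBER: ("class", "version number"),
    IAO_REFERENCE_SECTION: ("class", "reference section"),
    IAO_GRAPH: ("class", "graph"),
    IAO_CITATION: ("class", "citation"),
    SWO_LICENSE: ("class", "license"),
    SWO_SOFTWARE: ("class", "software"),
    SKOS_COLLECTION: ("class", "Collection"),
    SKOS_ALT_LABEL: ("annotation-property", "alternative label"),
    SKOS_NOTE: ("annotation-property", "note"),
    DCTERMS_DESCRIPTION: ("annotation-property", "description"),
    DCTERMS_DATE: ("annotation-property", "date"),
    DCTERMS_SOURCE: ("annotation-property", "source"),
    RDFS_LABEL: ("annotation-property", "label"),
}


def stub_term(iri: str) -> TermRef:
    """The stub :class:`TermRef` for a known external IRI."""
    category, label = _STUBS[iri]
    return TermRef(iri=iri, category=category, label=label)


def all_stub_terms() -> list[TermRef]:
    return [stub_term(iri) for iri in _STUBS]
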