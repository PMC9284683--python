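"""Construction of the MCRO core conceptual model, and ontology metrics.

The core model mirrors the published structure of the Model Card Report
Ontology: a ``ModelCardReport`` class aligned to IAO's *report*, four main
section classes (*model parameters*, *considerations*, *model details*,
*quantitative analysis*) aligned to IAO's *document part*, a roster of
subsection classes, and eight alignment axioms tying sections to OBO
concepts (is-about links to IAO/SWO targets, two equivalences, one
class-level has-part to *citation*).  Part-whole structure uses BFO's
*has part* (``BFO_0000051``), declared transitive with inverse *part of*
(``BFO_0000050``).

The full membership of the core class roster is not published term-by-term;
the roster here is reconstructed from the model-card report structure
(owners, intended users, factors, metrics, training/evaluation data,
unitary/intersectional results, ...) so that the core's headline feature
counts match the published artifact: 38 classes, 0 object properties,
11 data properties and 79 logical axioms native to the MCRO namespace.
See ``docs/methods.md`` for the reconstruction rationale.
"""

from __future__ import annotations

from typing import Optional

from . import vocab
from .ontgraph import AxiomRec, Literal, OntologyGraph, OntologyStats, TermRef
from .ontgraph import stats_for

__all__ = ["build_core_schema", "stats", "section_classes", "part_map",
           "MAIN_SECTIONS", "mcro_iri"]


def mcro_iri(name: str) -> str:
    """IRI of an MCRO-native term with CamelCase local name ``name``."""
    return vocab.MCRO_NS + name


def _humanize(name: str) -> str:
    """CamelCase -> sentence-case label ("TradeOff" -> "trade off")."""
    out: list[str] = []
    for ch in name:
        if ch.isupper() and out:
            out.append(" ")
        out.append(ch.lower())
    return "".join(out)


#: the four main section classes, in document order
MAIN_SECTIONS = (
    "ModelDetails",
    "ModelParameters",
    "Considerations",
    "QuantitativeAnalysis",
)

#: MCRO class -> asserted superclass (local name, or external IRI marker).
#: Every core class has exactly one asserted parent.
_SUPERCLASS: dict[str, str] = {
    "ModelCardReport": vocab.IAO_REPORT,
    # main sections
    "ModelDetails": vocab.IAO_DOCUMENT_PART,
    "ModelParameters": vocab.IAO_DOCUMENT_PART,
    "Considerations": vocab.IAO_DOCUMENT_PART,
    "QuantitativeAnalysis": vocab.IAO_DOCUMENT_PART,
    # model details subsections
    "VersionInformation": vocab.IAO_DOCUMENT_PART,
    "LicenseInformation": vocab.IAO_DOCUMENT_PART,
    "CitationInformation": vocab.IAO_DOCUMENT_PART,
    "ReferenceInformation": vocab.IAO_DOCUMENT_PART,
    "OwnerInformation": vocab.IAO_DOCUMENT_PART,
    "DeveloperInformation": vocab.IAO_DOCUMENT_PART,
    "ContactInformation": vocab.IAO_DOCUMENT_PART,
    "DateInformation": vocab.IAO_DOCUMENT_PART,
    "ModelType": vocab.IAO_DOCUMENT_PART,
    "User": vocab.IAO_DOCUMENT_PART,
    # model parameters subsections
    "ModelArchitecture": vocab.IAO_DOCUMENT_PART,
    "DatasetInformation": vocab.IAO_DOCUMENT_PART,
    "FormatInformation": vocab.IAO_DOCUMENT_PART,
    "TrainingData": vocab.IAO_DOCUMENT_PART,
    "EvaluationData": vocab.IAO_DOCUMENT_PART,
    "PreprocessingInformation": vocab.IAO_DOCUMENT_PART,
    "MotivationInformation": vocab.IAO_DOCUMENT_PART,
    # considerations subsections
    "TradeOff": vocab.IAO_DOCUMENT_PART,
    "EthicalConsideration": vocab.IAO_DOCUMENT_PART,
    "IntendedUse": vocab.IAO_DOCUMENT_PART,
    "Factor": vocab.IAO_DOCUMENT_PART,
    "Limitation": vocab.IAO_DOCUMENT_PART,
    "PrimaryUse": "IntendedUse",
    "OutOfScopeUse": "IntendedUse",
    "EvaluationFactor": "Factor",
    "RelevantFactor": "Factor",
    # quantitative analysis subsections
    "PerformanceMetric": vocab.IAO_DOCUMENT_PART,
    "DecisionThreshold": vocab.IAO_DOCUMENT_PART,
    "VariationApproach": vocab.IAO_DOCUMENT_PART,
    "UnitaryResult": vocab.IAO_DOCUMENT_PART,
    "IntersectionalResult": vocab.IAO_DOCUMENT_PART,
    "Graphic": vocab.IAO_DOCUMENT_PART,
    "GraphicCollection": vocab.SKOS_COLLECTION,
}

#: class-level has-part wiring: parent local name -> child local names
_PARTS: dict[str, tuple[str, ...]] = {
    "ModelCardReport": MAIN_SECTIONS,
    "ModelDetails": (
        "VersionInformation",
        "LicenseInformation",
        "CitationInformation",
        "ReferenceInformation",
        "OwnerInformation",
        "DeveloperInformation",
        "ContactInformation",
        "DateInformation",
        "ModelType",
        "User",
    ),
    "ModelParameters": (
        "ModelArchitecture",
        "DatasetInformation",
        "FormatInformation",
        "TrainingData",
        "EvaluationData",
        "PreprocessingInformation",
        "MotivationInformation",
    ),
    "Considerations": (
        "TradeOff",
        "EthicalConsideration",
        "IntendedUse",
        "Factor",
        "Limitation",
    ),
    "QuantitativeAnalysis": (
        "PerformanceMetric",
        "DecisionThreshold",
        "VariationApproach",
        "UnitaryResult",
        "IntersectionalResult",
        # GraphicCollection added per the configurable edge, see below
    ),
    "GraphicCollection": ("Graphic",),
}

#: is-about alignments to OBO targets (Table-style section->concept links)
_IS_ABOUT: dict[str, str] = {
    "DatasetInformation": vocab.IAO_DATA_SET,
    "ModelArchitecture": vocab.IAO_ALGORITHM,
    "FormatInformation": vocab.IAO_DATA_FORMAT,
    "VersionInformation": vocab.IAO_VERSION_NUMBER,
    "LicenseInformation": vocab.SWO_LICENSE,
}

#: equivalence alignments
_EQUIVALENT: dict[str, str] = {
    "ReferenceInformation": vocab.IAO_REFERENCE_SECTION,
    "Graphic": vocab.IAO_GRAPH,
}

#: the 11 MCRO-native data properties (declared, ranges left untyped)
_DATA_PROPERTIES = (
    "documentation",
    "overview",
    "modelName",
    "versionValue",
    "licenseName",
    "citationText",
    "contactDetail",
    "metricName",
    "metricValue",
    "datasetName",
    "useCaseDescription",
)


def build_core_schema(graphic_collection_edge: str = "has-part") -> OntologyGraph:
    """Build the MCRO core model as an :class:`OntologyGraph`.

    Parameters
    ----------
    graphic_collection_edge:
        How ``QuantitativeAnalysis`` links to ``GraphicCollection``:
        ``"has-part"`` (default, the partonomy pattern used by every other
        section link) or ``"is-about"``.  The published sources do not pin
        this edge down, so it is exposed as an option.

    The result is deterministic: two calls produce equal graphs.
    """
    if graphic_collection_edge not in {"has-part", "is-about"}:
        raise ValueError(
            "graphic_collection_edge must be 'has-part' or 'is-about', "
            f"got {graphic_collection_edge!r}"
        )
    g = OntologyGraph(prefixes=vocab.PREFIXES)
    for stub in vocab.all_stub_terms():
        g.add_term(stub)

    for name in _SUPERCLASS:
        g.add_term(TermRef(iri=mcro_iri(name), category="class",
                           label=_humanize(name)))
    for prop in _DATA_PROPERTIES:
        g.add_term(TermRef(iri=mcro_iri(prop), category="data-property",
                           label=_humanize(prop[0].upper() + prop[1:])))

    # taxonomy: one asserted parent per core class
    for name, parent in _SUPERCLASS.items():
        parent_iri = parent if parent.startswith("http") else mcro_iri(parent)
        g.add_axiom(AxiomRec("subclass-of", mcro_iri(name), object=parent_iri))

    # class-level partonomy wiring
    for parent, children in _PARTS.items():
        for child in children:
            g.add_axiom(
                AxiomRec(
                    "object-property-assertion",
                    mcro_iri(parent),
                    predicate=vocab.HAS_PART,
                    object=mcro_iri(child),
                )
            )
    gc_kind = (
        "object-property-assertion"
    )
    gc_pred = vocab.HAS_PART if graphic_collection_edge == "has-part" else vocab.IS_ABOUT
    g.add_axiom(
        AxiomRec(gc_kind, mcro_iri("QuantitativeAnalysis"), predicate=gc_pred,
                 object=mcro_iri("GraphicCollection"))
    )
    # citation section carries a citation (class-level has-part to IAO target)
    g.add_axiom(
        AxiomRec("object-property-assertion", mcro_iri("CitationInformation"),
                 predicate=vocab.HAS_PART, object=vocab.IAO_CITATION)
    )

    # is-about alignments
    for name, target in _IS_ABOUT.items():
        g.add_axiom(
            AxiomRec("object-property-assertion", mcro_iri(name),
                     predicate=vocab.IS_ABOUT, object=target)
        )
    # equivalence alignments
    for name, target in _EQUIVALENT.items():
        g.add_axiom(AxiomRec("equivalent-class", mcro_iri(name), object=target))

    # property characteristics: has-part is transitive, inverse of part-of
    g.add_axiom(AxiomRec("transitive-property", vocab.HAS_PART))
    g.add_axiom(AxiomRec("inverse-of", vocab.HAS_PART, object=vocab.PART_OF))

    # software and algorithm are disjoint sibling concepts
    g.add_axiom(
        AxiomRec("disjoint-with", vocab.SWO_SOFTWARE, object=vocab.IAO_ALGORITHM)
    )

    # alternative label: trade offs are also called caveats
    g.add_axiom(
        AxiomRec("annotation-assertion", mcro_iri("TradeOff"),
                 predicate=vocab.SKOS_ALT_LABEL, object=Literal("Caveats"))
    )
    return g


def stats(graph: OntologyGraph, namespace: Optional[str] = None) -> OntologyStats:
    """Headline ontology metrics, optionally for one namespace.

    ``stats(g, namespace=vocab.MCRO_NS)`` reports the core-native counts the
    way per-ontology breakdowns are usually tabulated: terms by IRI prefix,
    logical axioms by subject (either side for symmetric kinds).
    """
    return stats_for(graph, namespace=namespace)


def section_classes(schema: OntologyGraph) -> dict[str, str]:
    """Local name -> IRI for every MCRO section class (report excluded)."""
    out = {}
    for term in schema.terms_of_category("class"):
        if term.iri.startswith(vocab.MCRO_NS):
            name = term.iri[len(vocab.MCRO_NS):]
            if name != "ModelCardReport":
                out[name] = term.iri
    return out


def part_map(schema: OntologyGraph) -> dict[str, set[str]]:
    """Allowed child kinds per parent kind, from the class-level wiring.

    A kind is a valid child of a parent if the schema asserts a class-level
    has-part from the parent (or one of the parent's superclasses) to the
    child's class or to one of the child's superclasses.
    """
    mcro = vocab.MCRO_NS

    def local(iri: str) -> Optional[str]:
        return iri[len(mcro):] if iri.startswith(mcro) else None

    # subclass closure among MCRO classes
    parents: dict[str, set[str]] = {}
    for ax in schema.axioms_of_kind("subclass-of"):
        s, o = local(ax.subject), local(str(ax.object))
        if s is not None and o is not None:
            parents.setdefault(s, set()).add(o)

    def ancestors(name: str) -> set[str]:
        seen: set[str] = set()
        stack = [name]
        while stack:
            cur = stack.pop()
            for p in parents.get(cur, ()):  # acyclic by construction
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    direct: dict[str, set[str]] = {}
    for ax in schema.axioms_of_kind("object-property-assertion"):
        if ax.predicate != vocab.HAS_PART:
            continue
        s, o = local(ax.subject), local(str(ax.object))
        if s is not None and o is not None:
            direct.setdefault(s, set()).add(o)

    all_names = {local(t.iri) for t in schema.terms_of_category("class")
                 if local(t.iri) is not None}
    out: dict[str, set[str]] = {}
    for parent in all_names:
        allowed: set[str] = set()
        for holder in {parent} | ancestors(parent):
            allowed |= direct.get(holder, set())
        # a child kind is valid if its class or any superclass is allowed
        expanded = {
            child for child in all_names
            if ({child} | ancestors(child)) & allowed
        }
        out[parent] = expanded
    return out
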