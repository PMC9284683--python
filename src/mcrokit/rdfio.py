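"""Serialization: deterministic Turtle read/write, OWL/XML write.

The writer emits a stable, blank-node-free Turtle dialect — prefixes
sorted, subjects sorted, one predicate group per line — so two writes of
the same graph are byte-identical and graph equality after a round-trip is
plain set equality (no isomorphism search).

The reader delegates Turtle parsing to rdflib and then maps RDF triples
onto :class:`~mcrokit.ontgraph.AxiomRec` kinds.  Real-world OWL files use
blank-node scaffolding for some axioms; reified ``owl:Axiom`` annotations
and ``owl:AllDisjointClasses`` lists are decoded to their logical kinds,
while constructs outside the supported fragment (class expressions,
property characteristics the reasoner does not implement) are preserved as
labelled unsupported records and reported with a warning — never silently
dropped.

OWL/XML output is write-only, mirroring artifacts that ship both a ``.ttl``
and a ``.owl`` rendering.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from typing import Optional, Union

import rdflib
from rdflib.collection import Collection as RDFCollection

from . import vocab
from .ontgraph import AxiomRec, Literal, OntologyGraph, TermRef

__all__ = [
    "write_turtle",
    "read_turtle",
    "write_owl_xml",
    "read_graph",
    "write_graph",
    "TurtleParseError",
    "UnsupportedAxiomWarning",
]

_OWL = vocab.OWL_NS
_RDF = vocab.RDF_NS
_RDFS = vocab.RDFS_NS

_DECL_TYPES = {
    "class": _OWL + "Class",
    "object-property": _OWL + "ObjectProperty",
    "data-property": _OWL + "DatatypeProperty",
    "annotation-property": _OWL + "AnnotationProperty",
    "individual": _OWL + "NamedIndividual",
}
_DECL_BY_IRI = {v: k for k, v in _DECL_TYPES.items()}

_KIND_PREDICATES = {
    "subclass-of": _RDFS + "subClassOf",
    "equivalent-class": _OWL + "equivalentClass",
    "disjoint-with": _OWL + "disjointWith",
    "inverse-of": _OWL + "inverseOf",
    "domain": _RDFS + "domain",
    "range": _RDFS + "range",
}
_PREDICATE_KINDS = {v: k for k, v in _KIND_PREDICATES.items()}

#: property characteristics outside the reasoner's fragment
_UNSUPPORTED_CHARACTERISTICS = {
    _OWL + "SymmetricObjectProperty",
    _OWL + "AsymmetricObjectProperty",
    _OWL + "ReflexiveObjectProperty",
    _OWL + "IrreflexiveObjectProperty",
    _OWL + "FunctionalProperty",
    _OWL + "FunctionalObjectProperty",
    _OWL + "InverseFunctionalProperty",
    _OWL + "FunctionalDataProperty",
}


class TurtleParseError(ValueError):
    """Turtle syntax error, with the offending line when available."""


class UnsupportedAxiomWarning(UserWarning):
    """Emitted when a read encounters constructs outside the dialect."""


# -------------------------------------------------------------------------
# Turtle writing
# -------------------------------------------------------------------------

def _qname(graph: OntologyGraph, iri: str) -> str:
    compact = graph.curie(iri)
    if compact != iri and _safe_local(compact.split(":", 1)[1]):
        return compact
    return f"<{iri}>"


def _safe_local(local: str) -> bool:
    return bool(local) and all(c.isalnum() or c in "_-." for c in local) and \
        not local.startswith((".", "-")) and not local.endswith(".")


def _render_literal(graph: OntologyGraph, lit: Literal) -> str:
    value = (
        lit.value.replace("\\", "\\\\").replace('"', '\\"')
        .replace("\n", "\\n").replace("\r", "\\r").replace("\t", "\\t")
    )
    out = f'"{value}"'
    if lit.lang:
        out += f"@{lit.lang}"
    elif lit.datatype:
        out += f"^^{_qname(graph, lit.datatype)}"
    return out


def write_turtle(graph: OntologyGraph) -> str:
    """Deterministic Turtle rendering of a closed graph."""
    graph.check_closed()
    lines = [
        f"@prefix {p}: <{ns}> ."
        for p, ns in sorted(graph.prefixes.items())
    ]
    lines.append("")

    # (subject, predicate-iri-or-"a", rendered-object)
    triples: list[tuple[str, str, str]] = []
    for term in graph.terms.values():
        triples.append((term.iri, "a", _qname(graph, _DECL_TYPES[term.category])))
        if term.label is not None:
            triples.append(
                (term.iri, vocab.RDFS_LABEL,
                 _render_literal(graph, Literal(term.label)))
            )
    for ax in graph.axioms:
        if ax.kind == "transitive-property":
            triples.append(
                (ax.subject, "a", _qname(graph, _OWL + "TransitiveObjectProperty"))
            )
        elif ax.kind == "type-assertion":
            triples.append((ax.subject, "a", _qname(graph, str(ax.object))))
        elif ax.kind in _KIND_PREDICATES:
            triples.append(
                (ax.subject, _KIND_PREDICATES[ax.kind], _qname(graph, str(ax.object)))
            )
        elif ax.kind in {"object-property-assertion", "data-property-assertion",
                         "annotation-assertion"}:
            obj = (
                _render_literal(graph, ax.object)
                if isinstance(ax.object, Literal)
                else _qname(graph, str(ax.object))
            )
            triples.append((ax.subject, ax.predicate, obj))

    def pred_key(p: str) -> tuple[int, str]:
        return (0, "") if p == "a" else (1, p)

    by_subject: dict[str, dict[str, set[str]]] = {}
    for s, p, o in triples:
        by_subject.setdefault(s, {}).setdefault(p, set()).add(o)

    for s in sorted(by_subject):
        groups = by_subject[s]
        parts = []
        for p in sorted(groups, key=pred_key):
            pr = "a" if p == "a" else _qname(graph, p)
            objs = ", ".join(sorted(groups[p]))
            parts.append(f"{pr} {objs}")
        subject = _qname(graph, s)
        joined = " ;\n    ".join(parts)
        lines.append(f"{subject} {joined} .")
    lines.append("")
    return "\n".join(lines)


# -------------------------------------------------------------------------
# Turtle reading
# -------------------------------------------------------------------------

def _note_unsupported(graph: OntologyGraph, what: str, detail: str) -> None:
    graph.unsupported.append((what, detail))
    warnings.warn(
        f"unsupported axiom ({what}): {detail}", UnsupportedAxiomWarning,
        stacklevel=3,
    )


def read_turtle(text: str) -> OntologyGraph:
    """Parse Turtle text into a closed :class:`OntologyGraph`."""
    rg = rdflib.Graph(bind_namespaces="none")
    try:
        rg.parse(data=text, format="turtle")
    except Exception as exc:  # rdflib raises plugin-specific errors
        line = getattr(exc, "lines", None)
        suffix = f" (line {line})" if line else ""
        raise TurtleParseError(f"Turtle syntax error{suffix}: {exc}") from exc

    graph = OntologyGraph(
        prefixes={str(p): str(ns) for p, ns in rg.namespaces()}
    )

    RDF_TYPE = rdflib.URIRef(_RDF + "type")
    categories: dict[str, str] = {}
    transitive: set[str] = set()
    ontology_headers: set[rdflib.term.Node] = set(
        rg.subjects(RDF_TYPE, rdflib.URIRef(_OWL + "Ontology"))
    )

    def named(node: rdflib.term.Node) -> Optional[str]:
        return str(node) if isinstance(node, rdflib.URIRef) else None

    # pass 1: declarations and characteristics
    for s, o in rg.subject_objects(RDF_TYPE):
        s_iri, o_iri = named(s), named(o)
        if s_iri is None or o_iri is None:
            continue
        if o_iri in _DECL_BY_IRI:
            cat = _DECL_BY_IRI[o_iri]
            prev = categories.get(s_iri)
            # a term may be punned individual+class; prefer the stronger
            # schema category for the term table
            if prev is None or prev == "individual":
                categories[s_iri] = cat
        elif o_iri == _OWL + "TransitiveObjectProperty":
            categories.setdefault(s_iri, "object-property")
            transitive.add(s_iri)
        elif o_iri in _UNSUPPORTED_CHARACTERISTICS:
            categories.setdefault(s_iri, "object-property")
            _note_unsupported(graph, "property-characteristic",
                              f"{s_iri} a {o_iri}")

    pending: list[AxiomRec] = []
    plain_labels: dict[str, set[str]] = {}
    extra_labels: list[tuple[str, Literal]] = []

    def require(iri: str, category: str, *, force: bool = False) -> None:
        if force:
            categories[iri] = category
        else:
            categories.setdefault(iri, category)

    def to_literal(node: rdflib.Literal) -> Literal:
        if node.language:
            return Literal(str(node), lang=str(node.language))
        if node.datatype and str(node.datatype) != vocab.XSD_NS + "string":
            return Literal(str(node), datatype=str(node.datatype))
        return Literal(str(node))

    def decode_statement(s_iri: str, p_iri: str,
                         o: rdflib.term.Node) -> None:
        o_iri = named(o)
        if p_iri == vocab.RDFS_LABEL and isinstance(o, rdflib.Literal):
            lit = to_literal(o)
            if lit.datatype is None and lit.lang is None:
                plain_labels.setdefault(s_iri, set()).add(lit.value)
            else:
                extra_labels.append((s_iri, lit))
            return
        if p_iri in _PREDICATE_KINDS:
            kind = _PREDICATE_KINDS[p_iri]
            if o_iri is None:
                _note_unsupported(graph, kind,
                                  f"{s_iri} {p_iri} <blank class expression>")
                return
            if kind in {"subclass-of", "equivalent-class", "disjoint-with"}:
                require(s_iri, "class", force=True)
                require(o_iri, "class", force=True)
            elif kind == "inverse-of":
                require(s_iri, "object-property")
                require(o_iri, "object-property")
            elif kind == "domain":
                require(o_iri, "class")
            pending.append(AxiomRec(kind, s_iri, object=o_iri))
            return
        if p_iri == _RDF + "type":
            # remaining named types are class assertions
            if o_iri is None:
                _note_unsupported(graph, "type-assertion",
                                  f"{s_iri} a <blank class expression>")
                return
            require(o_iri, "class", force=True)
            require(s_iri, "individual")
            pending.append(AxiomRec("type-assertion", s_iri, object=o_iri))
            return
        if isinstance(o, rdflib.Literal):
            cat = categories.get(p_iri)
            kind = ("data-property-assertion" if cat == "data-property"
                    else "annotation-assertion")
            require(p_iri, "annotation-property")
            require(s_iri, "individual")
            pending.append(
                AxiomRec(kind, s_iri, predicate=p_iri, object=to_literal(o))
            )
            return
        if o_iri is not None:
            cat = categories.get(p_iri)
            kind = ("annotation-assertion" if cat == "annotation-property"
                    else "object-property-assertion")
            require(p_iri, "object-property")
            require(s_iri, "individual")
            require(o_iri, "individual")
            pending.append(
                AxiomRec(kind, s_iri, predicate=p_iri, object=o_iri)
            )
            return
        _note_unsupported(graph, "blank-object", f"{s_iri} {p_iri} _:")

    # pass 2: blank-node scaffolding (reified axioms, n-ary disjointness)
    handled_bnodes: set[rdflib.term.Node] = set()
    for bnode in set(rg.subjects(RDF_TYPE, rdflib.URIRef(_OWL + "Axiom"))):
        src = rg.value(bnode, rdflib.URIRef(_OWL + "annotatedSource"))
        prop = rg.value(bnode, rdflib.URIRef(_OWL + "annotatedProperty"))
        tgt = rg.value(bnode, rdflib.URIRef(_OWL + "annotatedTarget"))
        handled_bnodes.add(bnode)
        if named(src) and named(prop):
            decode_statement(named(src), named(prop), tgt)
        else:
            _note_unsupported(graph, "owl-axiom",
                              "reified axiom with blank participants")
    for bnode in set(
        rg.subjects(RDF_TYPE, rdflib.URIRef(_OWL + "AllDisjointClasses"))
    ):
        handled_bnodes.add(bnode)
        members_head = rg.value(bnode, rdflib.URIRef(_OWL + "members"))
        members = []
        if members_head is not None:
            # mark the list cells handled so pass 3 does not re-report them
            cell = members_head
            REST = rdflib.URIRef(_RDF + "rest")
            while isinstance(cell, rdflib.BNode):
                handled_bnodes.add(cell)
                cell = rg.value(cell, REST)
            members = [named(m) for m in RDFCollection(rg, members_head)]
        if members and all(members):
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    require(a, "class", force=True)
                    require(b, "class", force=True)
                    pending.append(AxiomRec("disjoint-with", a, object=b))
        else:
            _note_unsupported(graph, "all-disjoint-classes",
                              "n-ary disjointness over class expressions")

    # pass 3: plain named statements
    noted_blank: set[rdflib.term.Node] = set()
    for s, p, o in sorted(rg, key=lambda t: (str(t[0]), str(t[1]), str(t[2]))):
        if s in ontology_headers or s in handled_bnodes:
            continue
        s_iri, p_iri = named(s), named(p)
        if s_iri is None:
            if s not in noted_blank:
                noted_blank.add(s)
                _note_unsupported(
                    graph, "blank-subject", f"blank node with {p_iri}"
                )
            continue
        if p_iri == _RDF + "type":
            o_iri = named(o)
            if o_iri in _DECL_BY_IRI or o_iri == _OWL + "TransitiveObjectProperty" \
                    or o_iri in _UNSUPPORTED_CHARACTERISTICS \
                    or o_iri == _OWL + "Ontology":
                continue
            if o_iri is None:
                _note_unsupported(graph, "type-assertion",
                                  f"{s_iri} a <blank class expression>")
                continue
        decode_statement(s_iri, p_iri, o)

    # materialize the term table, then the axioms
    for ax in pending:
        for iri in ax.iris():
            categories.setdefault(iri, "individual")
    for iri in transitive:
        categories.setdefault(iri, "object-property")
    labels = {}
    for iri, values in plain_labels.items():
        ordered = sorted(values)
        labels[iri] = ordered[0]
        for extra in ordered[1:]:
            extra_labels.append((iri, Literal(extra)))
        categories.setdefault(iri, "individual")
    for iri, cat in sorted(categories.items()):
        graph.add_term(TermRef(iri=iri, category=cat, label=labels.get(iri)))
    for iri in transitive:
        graph.add_axiom(AxiomRec("transitive-property", iri))
    for ax in pending:
        graph.add_axiom(ax)
    for s_iri, lit in extra_labels:
        graph.add_axiom(
            AxiomRec("annotation-assertion", s_iri,
                     predicate=vocab.RDFS_LABEL, object=lit)
        )
    graph.check_closed()
    return graph


# -------------------------------------------------------------------------
# OWL/XML writing
# -------------------------------------------------------------------------

_OWLXML_NS = "http://www.w3.org/ns/owl2-xml"


def _iri_el(parent: ET.Element, tag: str, iri: str) -> ET.Element:
    el = ET.SubElement(parent, tag)
    el.set("IRI", iri)
    return el


def _literal_el(parent: ET.Element, lit: Literal) -> ET.Element:
    el = ET.SubElement(parent, "Literal")
    if lit.lang:
        el.set("xml:lang", lit.lang)
    elif lit.datatype:
        el.set("datatypeIRI", lit.datatype)
    el.text = lit.value
    return el


_CATEGORY_XML = {
    "class": "Class",
    "object-property": "ObjectProperty",
    "data-property": "DataProperty",
    "annotation-property": "AnnotationProperty",
    "individual": "NamedIndividual",
}


def write_owl_xml(graph: OntologyGraph) -> str:
    """Well-formed OWL/XML rendering of a closed graph (write-only)."""
    graph.check_closed()
    root = ET.Element("Ontology")
    root.set("xmlns", _OWLXML_NS)
    for prefix, ns in sorted(graph.prefixes.items()):
        el = ET.SubElement(root, "Prefix")
        el.set("name", prefix)
        el.set("IRI", ns)

    for iri in sorted(graph.terms):
        term = graph.terms[iri]
        decl = ET.SubElement(root, "Declaration")
        _iri_el(decl, _CATEGORY_XML[term.category], iri)

    def annotation(prop: str, subject: str, value: Union[str, Literal]) -> None:
        el = ET.SubElement(root, "AnnotationAssertion")
        _iri_el(el, "AnnotationProperty", prop)
        sub = ET.SubElement(el, "IRI")
        sub.text = subject
        if isinstance(value, Literal):
            _literal_el(el, value)
        else:
            tgt = ET.SubElement(el, "IRI")
            tgt.text = value

    for iri in sorted(graph.terms):
        term = graph.terms[iri]
        if term.label is not None:
            annotation(vocab.RDFS_LABEL, iri, Literal(term.label))

    def axiom_sort_key(ax: AxiomRec) -> tuple:
        return (ax.kind, ax.subject, ax.predicate or "", str(ax.object))

    for ax in sorted(graph.axioms, key=axiom_sort_key):
        if ax.kind == "subclass-of":
            el = ET.SubElement(root, "SubClassOf")
            _iri_el(el, "Class", ax.subject)
            _iri_el(el, "Class", str(ax.object))
        elif ax.kind == "equivalent-class":
            el = ET.SubElement(root, "EquivalentClasses")
            _iri_el(el, "Class", ax.subject)
            _iri_el(el, "Class", str(ax.object))
        elif ax.kind == "disjoint-with":
            el = ET.SubElement(root, "DisjointClasses")
            _iri_el(el, "Class", ax.subject)
            _iri_el(el, "Class", str(ax.object))
        elif ax.kind == "transitive-property":
            el = ET.SubElement(root, "TransitiveObjectProperty")
            _iri_el(el, "ObjectProperty", ax.subject)
        elif ax.kind == "inverse-of":
            el = ET.SubElement(root, "InverseObjectProperties")
            _iri_el(el, "ObjectProperty", ax.subject)
            _iri_el(el, "ObjectProperty", str(ax.object))
        elif ax.kind in {"domain", "range"}:
            cat = graph.terms[ax.subject].category
            prefix = "ObjectProperty" if cat == "object-property" else "DataProperty"
            el = ET.SubElement(root, prefix + ax.kind.capitalize())
            _iri_el(el, prefix, ax.subject)
            if ax.kind == "range" and cat == "data-property":
                _iri_el(el, "Datatype", str(ax.object))
            else:
                _iri_el(el, "Class", str(ax.object))
        elif ax.kind == "type-assertion":
            el = ET.SubElement(root, "ClassAssertion")
            _iri_el(el, "Class", str(ax.object))
            _iri_el(el, "NamedIndividual", ax.subject)
        elif ax.kind == "object-property-assertion":
            el = ET.SubElement(root, "ObjectPropertyAssertion")
            _iri_el(el, "ObjectProperty", ax.predicate)
            _iri_el(el, "NamedIndividual", ax.subject)
            _iri_el(el, "NamedIndividual", str(ax.object))
        elif ax.kind == "data-property-assertion":
            el = ET.SubElement(root, "DataPropertyAssertion")
            _iri_el(el, "DataProperty", ax.predicate)
            _iri_el(el, "NamedIndividual", ax.subject)
            _literal_el(el, ax.object)
        elif ax.kind == "annotation-assertion":
            annotation(ax.predicate, ax.subject, ax.object)

    ET.indent(root)
    return '<?xml version="1.0"?>\n' + ET.tostring(root, encoding="unicode") + "\n"


# -------------------------------------------------------------------------
# file helpers
# -------------------------------------------------------------------------

def read_graph(path: str) -> OntologyGraph:
    """Read a graph from a ``.ttl`` file."""
    if not str(path).endswith(".ttl"):
        raise ValueError(f"only Turtle (.ttl) input is supported: {path}")
    with open(path, encoding="utf-8") as fh:
        return read_turtle(fh.read())


def write_graph(graph: OntologyGraph, path: str) -> None:
    """Write a graph to ``.ttl`` (Turtle) or ``.owl`` (OWL/XML) by extension."""
    path = str(path)
    if path.endswith(".ttl"):
        text = write_turtle(graph)
    elif path.endswith(".owl"):
        text = write_owl_xml(graph)
    else:
        raise ValueError(f"unsupported output extension: {path}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
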