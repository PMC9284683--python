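"""Encode a model card as an MCRO-aligned instance graph.

Each card becomes one individual typed ``ModelCardReport``; each section
becomes an individual typed by its section class; parent-child structure
becomes *has part* (``BFO_0000051``) assertions, so the asserted partonomy
is a tree rooted at the card individual.  Body text and the note /
description / date / source annotations are attached to the section
individuals as annotation assertions.

Individual identifiers are minted deterministically: the card's slug for
the report individual, and the slug plus a short stable hash of the
section path for each section, so re-publication of the same card yields
byte-identical graphs.
"""

from __future__ import annotations

import hashlib
import re

from . import vocab
from .card import ModelCard, Section
from .ontgraph import AxiomRec, Literal, OntologyGraph, TermRef
from .schema import mcro_iri

__all__ = ["to_instance_graph", "individual_iri", "SchemaVocabularyError"]


class SchemaVocabularyError(KeyError):
    """A card uses a section kind absent from the supplied schema."""


def _slug(text: str) -> str:
    slug = re.sub(r"[^a-z0-9]+", "-", text.lower()).strip("-")
    return slug or "card"


def individual_iri(card_id: str, path: tuple[int, ...] = ()) -> str:
    """Deterministic IRI for the individual at a section path.

    The empty path is the report individual itself; otherwise the local
    name is ``<slug>-s<digest>`` where the digest hashes the index path
    from the card root.
    """
    slug = _slug(card_id)
    if not path:
        return vocab.MCRI_NS + slug
    digest = hashlib.sha256(
        ("/".join(str(i) for i in path)).encode()
    ).hexdigest()[:8]
    return vocab.MCRI_NS + f"{slug}-s{digest}"


def _annotate(g: OntologyGraph, subject: str, prop: str, value: str) -> None:
    g.add_axiom(
        AxiomRec("annotation-assertion", subject, predicate=prop,
                 object=Literal(value))
    )


def to_instance_graph(card: ModelCard, schema: OntologyGraph) -> OntologyGraph:
    """Return ``schema`` plus the card's instance triples.

    Raises :class:`SchemaVocabularyError` if a section kind's class is not
    in the schema (cards built by :func:`mcrokit.card.read_card` are always
    covered by the core schema).
    """
    for section in card.walk():
        if mcro_iri(section.kind) not in schema.terms:
            raise SchemaVocabularyError(
                f"section kind {section.kind!r} has no class in the schema"
            )
    g = schema.copy()
    report_iri = individual_iri(card.card_id)
    g.add_term(TermRef(iri=report_iri, category="individual", label=card.title))
    g.add_axiom(
        AxiomRec("type-assertion", report_iri, object=mcro_iri("ModelCardReport"))
    )

    def publish(section: Section, parent_iri: str, path: tuple[int, ...]) -> None:
        iri = individual_iri(card.card_id, path)
        label = section.heading or section.kind
        g.add_term(TermRef(iri=iri, category="individual", label=label))
        g.add_axiom(AxiomRec("type-assertion", iri, object=mcro_iri(section.kind)))
        g.add_axiom(
            AxiomRec("object-property-assertion", parent_iri,
                     predicate=vocab.HAS_PART, object=iri)
        )
        if section.body:
            _annotate(g, iri, vocab.DCTERMS_DESCRIPTION, section.body)
        for key, prop in vocab.ANNOTATION_PROPERTIES.items():
            if key in section.annotations:
                _annotate(g, iri, prop, section.annotations[key])
        for j, child in enumerate(section.children):
            publish(child, iri, path + (j,))

    for i, section in enumerate(card.sections):
        publish(section, report_iri, (i,))
    return g
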