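"""The model-card document model and its on-disk authoring format.

A :class:`ModelCard` is a titled document made of typed sections; each
section kind is one of the MCRO section classes, and sections nest only
where the schema's class-level part-whole wiring allows (a ``TradeOff``
under ``Considerations``, a ``User`` under ``ModelDetails``, ...).

The authoring format is YAML, one card per UTF-8 file, with an explicit
``kind`` tag per section (documented in ``docs/card-format.md`` and
versioned through the ``format`` field).  Cards in the wild were hand
entered through ontology editors; this format is the toolkit's scriptable
replacement for that manual step.
"""

from __future__ import annotations

import datetime as _dt
import functools
import io
import random
from dataclasses import dataclass, field
from typing import Any, Iterator

import yaml

from . import schema as _schema

__all__ = [
    "ModelCard",
    "Section",
    "CardError",
    "CardParseError",
    "CardVocabularyError",
    "read_card",
    "write_card",
    "generate_card",
    "FORMAT_TAG",
]

FORMAT_TAG = "mcro-card/1"

ANNOTATION_KEYS = ("note", "description", "date", "source")


class CardError(ValueError):
    """Base class for card-format errors."""


class CardParseError(CardError):
    """The document is not a well-formed card (syntax or structure)."""


class CardVocabularyError(CardError):
    """A section kind is not part of the schema vocabulary."""


@dataclass
class Section:
    """One typed section of a model card."""

    kind: str
    heading: str = ""
    body: str = ""
    annotations: dict[str, str] = field(default_factory=dict)
    children: list["Section"] = field(default_factory=list)

    def walk(self) -> Iterator["Section"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class ModelCard:
    """A titled card with an ordered list of typed sections."""

    card_id: str
    title: str
    sections: list[Section] = field(default_factory=list)

    def walk(self) -> Iterator[Section]:
        for section in self.sections:
            yield from section.walk()


@functools.lru_cache(maxsize=1)
def _card_vocabulary() -> tuple[dict[str, str], dict[str, set[str]]]:
    """(section kind -> IRI, parent kind -> allowed child kinds)."""
    core = _schema.build_core_schema()
    return _schema.section_classes(core), _schema.part_map(core)


def _check_date(value: str, path: str) -> None:
    try:
        _dt.date.fromisoformat(value[:10])
        if len(value) > 10:
            _dt.datetime.fromisoformat(value)
    except ValueError:
        raise CardParseError(
            f"{path}: date annotation {value!r} is not ISO 8601"
        ) from None


def _parse_section(node: Any, path: str, kinds: dict[str, str],
                   allowed: set[str], parts: dict[str, set[str]]) -> Section:
    if not isinstance(node, dict):
        raise CardParseError(f"{path}: section must be a mapping")
    unknown = set(node) - {"kind", "heading", "body", "annotations", "children"}
    if unknown:
        raise CardParseError(f"{path}: unknown keys {sorted(unknown)}")
    kind = node.get("kind")
    if not isinstance(kind, str) or not kind:
        raise CardParseError(f"{path}: missing section kind")
    if kind not in kinds:
        raise CardVocabularyError(
            f"{path}: unknown section kind {kind!r}; allowed kinds: "
            + ", ".join(sorted(kinds))
        )
    if kind not in allowed:
        raise CardVocabularyError(
            f"{path}: kind {kind!r} is not a schema-valid part here; "
            "allowed: " + ", ".join(sorted(allowed))
        )
    heading = node.get("heading", "")
    body = node.get("body", "")
    if not isinstance(heading, str) or not isinstance(body, str):
        raise CardParseError(f"{path}: heading and body must be text")
    raw_ann = node.get("annotations", {}) or {}
    if not isinstance(raw_ann, dict):
        raise CardParseError(f"{path}: annotations must be a mapping")
    annotations: dict[str, str] = {}
    for key, value in raw_ann.items():
        if key not in ANNOTATION_KEYS:
            raise CardParseError(
                f"{path}: unknown annotation {key!r}; allowed: "
                + ", ".join(ANNOTATION_KEYS)
            )
        if isinstance(value, (_dt.date, _dt.datetime)):
            value = value.isoformat()
        if not isinstance(value, str):
            raise CardParseError(f"{path}: annotation {key!r} must be text")
        if key == "date":
            _check_date(value, f"{path}.annotations.date")
        annotations[key] = value
    children_nodes = node.get("children", []) or []
    if not isinstance(children_nodes, list):
        raise CardParseError(f"{path}: children must be a list")
    child_allowed = parts.get(kind, set())
    children = [
        _parse_section(child, f"{path}.children[{i}]", kinds, child_allowed,
                       parts)
        for i, child in enumerate(children_nodes)
    ]
    return Section(kind=kind, heading=heading, body=body,
                   annotations=annotations, children=children)


def read_card(document: str) -> ModelCard:
    """Parse a card-format document into a validated :class:`ModelCard`.

    Raises :class:`CardParseError` for malformed documents (with the YAML
    line or the offending path) and :class:`CardVocabularyError` for
    section kinds outside the schema vocabulary.
    """
    try:
        data = yaml.safe_load(io.StringIO(document))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise CardParseError(f"malformed card document{where}: {exc}") from exc
    if not isinstance(data, dict):
        raise CardParseError("card document must be a mapping")
    if data.get("format") != FORMAT_TAG:
        raise CardParseError(
            f"format: expected {FORMAT_TAG!r}, got {data.get('format')!r}"
        )
    card_id = data.get("card_id")
    if not isinstance(card_id, str) or not card_id.strip():
        raise CardParseError("card_id: must be a non-empty slug")
    title = data.get("title")
    if not isinstance(title, str) or not title:
        raise CardParseError("title: must be non-empty text")
    unknown = set(data) - {"format", "card_id", "title", "sections"}
    if unknown:
        raise CardParseError(f"unknown top-level keys {sorted(unknown)}")
    kinds, parts = _card_vocabulary()
    top_allowed = parts.get("ModelCardReport", set()) | set(_schema.MAIN_SECTIONS)
    nodes = data.get("sections", []) or []
    if not isinstance(nodes, list):
        raise CardParseError("sections: must be a list")
    sections = [
        _parse_section(node, f"sections[{i}]", kinds, top_allowed, parts)
        for i, node in enumerate(nodes)
    ]
    return ModelCard(card_id=card_id.strip(), title=title, sections=sections)


def _section_to_node(section: Section) -> dict[str, Any]:
    node: dict[str, Any] = {"kind": section.kind}
    if section.heading:
        node["heading"] = section.heading
    if section.body:
        node["body"] = section.body
    if section.annotations:
        node["annotations"] = {
            key: section.annotations[key]
            for key in ANNOTATION_KEYS
            if key in section.annotations
        }
    if section.children:
        node["children"] = [_section_to_node(c) for c in section.children]
    return node


def write_card(card: ModelCard) -> str:
    """Serialize a card back to the authoring format.

    ``read_card(write_card(c)) == c`` for every valid card; section order
    and nesting are preserved.
    """
    doc = {
        "format": FORMAT_TAG,
        "card_id": card.card_id,
        "title": card.title,
    }
    if card.sections:
        doc["sections"] = [_section_to_node(s) for s in card.sections]
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True,
                          default_flow_style=False)


# -- synthetic cards -------------------------------------------------------

_WORDS = (
    "model", "data", "cohort", "feature", "risk", "evaluation", "training",
    "network", "clinical", "patient", "metric", "threshold", "bias",
    "population", "outcome", "prediction", "record", "survey",
)


def _prose(rng: random.Random, n_words: int) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(n_words))


def generate_card(seed: int, n_sections: int, depth: int = 2) -> ModelCard:
    """Generate a deterministic synthetic card.

    ``n_sections`` sections are created in total; kinds are drawn uniformly
    from the schema-valid kinds at each position and nesting never exceeds
    ``depth`` levels.  Every section carries description and date
    annotations, so generated cards exercise the full annotation path.
    """
    if n_sections < 0:
        raise ValueError("n_sections must be >= 0")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = random.Random(seed)
    _, parts = _card_vocabulary()
    top_allowed = sorted(parts.get("ModelCardReport", set()))

    card = ModelCard(card_id=f"synthetic-{seed}",
                     title=f"Synthetic model card {seed}")
    # open slots: (children-list, allowed kinds, remaining depth)
    slots: list[tuple[list[Section], list[str], int]] = [
        (card.sections, top_allowed, depth)
    ]
    for i in range(n_sections):
        slot_idx = rng.randrange(len(slots))
        siblings, allowed, room = slots[slot_idx]
        kind = allowed[rng.randrange(len(allowed))]
        section = Section(
            kind=kind,
            heading=f"{kind} {i}",
            body=_prose(rng, 8),
            annotations={
                "description": _prose(rng, 5),
                "date": (_dt.date(2022, 1, 1)
                         + _dt.timedelta(days=rng.randrange(365))).isoformat(),
            },
        )
        siblings.append(section)
        child_kinds = sorted(parts.get(kind, set()))
        if room > 1 and child_kinds:
            slots.append((section.children, child_kinds, room - 1))
    return card
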