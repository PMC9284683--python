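# Card authoring format, version `mcro-card/1`

One model card per UTF-8 YAML file.

## Top level

| key       | required | meaning                                    |
|-----------|----------|--------------------------------------------|
| `format`  | yes      | literal `mcro-card/1`                      |
| `card_id` | yes      | non-empty slug, stable across re-publishes |
| `title`   | yes      | card title                                 |
| `sections`| no       | ordered list of section nodes              |

## Section node

| key           | required | meaning                                                   |
|---------------|----------|-----------------------------------------------------------|
| `kind`        | yes      | a section class name from the core schema (`ModelDetails`, `Considerations`, `TradeOff`, `User`, ...) |
| `heading`     | no       | display heading (becomes the individual's label)          |
| `body`        | no       | prose content (published as a `dcterms:description`)      |
| `annotations` | no       | map with keys among `note`, `description`, `date`, `source` |
| `children`    | no       | nested section nodes                                      |

Constraints enforced by `mcrokit.card.read_card`:

* top-level sections must be the four main sections
  (`ModelDetails`, `ModelParameters`, `Considerations`, `QuantitativeAnalysis`);
* a child's `kind` must be a schema-valid part of its parent's `kind`
  (per the core schema's class-level *has part* wiring, subclasses
  included);
* `date` annotations must be ISO 8601 (`YYYY-MM-DD`, optionally with a
  time part);
* unknown keys, kinds, or annotation names are rejected with the path of
  the offending node.

The format version is bumped on any incompatible change; readers reject
documents whose `format` tag they do not support.
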