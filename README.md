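# mcrokit

Model card reports are short structured documents — akin to nutrition
labels — that describe a machine-learning model's details, parameters,
considerations (trade-offs, ethics, intended users) and quantitative
performance for stakeholders.  As static prose they cannot be indexed,
queried, aggregated or checked by machines.

`mcrokit` puts model cards on an OWL2 footing for people building FAIR
tooling around biomedical ML models: it carries the Model Card Report
Ontology (MCRO) core schema — a `ModelCardReport` class aligned to the
Information Artifact Ontology's *report*, section classes aligned to
*document part*, and the BFO partonomy `has part` (`BFO_0000051`,
transitive, with inverse `part of`) tying a report to its sections — and
the machinery around it:

* **author**: parse a YAML card document and encode it as an instance
  graph (one individual per section, typed by its section class, wired
  with *has part*, annotated with note/description/date/source);
* **reason**: forward-chaining materialization of the
  transitivity/inverse/subclass/type/equivalence fragment, so a card's
  partonomy closes beyond first-degree links (a `TradeOff` inside
  `Considerations` is inferred to be *part of* the card itself);
* **check & validate**: disjointness checking (the classic case: one
  individual typed both *software* and *algorithm* under their
  disjointness axiom) plus structural rules for orphan sections,
  domain/range, dates and report composition;
* **extract**: seed-based subset extraction (seeds + superclass closure,
  closed output) for carving small imports out of large vocabularies;
* **stats & query**: the four headline ontology metrics (classes, object
  properties, data properties, logical axioms), optionally per
  namespace, and single-pattern, inference-aware triple matching;
* **serialize**: deterministic, blank-node-free Turtle (read/write) and
  OWL/XML (write).

See `docs/methods.md` for the model, counting conventions and design
choices, and `docs/card-format.md` for the authoring format.

## Worked example

Two sample cards ship with the package; `pci.yaml` describes a recurrent
neural network predicting adverse endpoints after coronary stent
implantation.

```sh
$ python -c "from mcrokit.fixtures import sample_card_text; \
             open('pci.yaml','w').write(sample_card_text('pci'))"
$ mcrokit --quiet author pci.yaml -o pci.ttl
$ mcrokit --quiet stats pci.ttl
50 3 11 107
$ mcrokit --quiet stats pci.ttl --namespace mcro
38 0 11 79
$ mcrokit --quiet reason pci.ttl --check && echo consistent
consistent
$ mcrokit --quiet validate pci.ttl
OK: graph is schema-valid
```

The first `stats` line counts the whole graph — 38 core classes plus 12
external stubs, the BFO/IAO object properties, and the logical axioms
contributed by the card's 13 individuals: 50 classes, 3 object
properties, 11 data properties, 107 logical axioms.  Restricted to the MCRO namespace the
schema core shows its native footprint — 38 classes, 0 object properties
(partonomy and aboutness come from BFO/IAO), 11 data properties, 79
logical axioms.  `reason --check` exits 0 because the encoded card
violates no disjointness axiom, and `validate` confirms every section
individual hangs off the report via *has part* with well-formed
annotations.

Inference-aware querying reaches parts beyond the first degree (the
`[inferred]` rows are produced by the reasoner, not asserted):

```sh
$ mcrokit --quiet query pci.ttl mcri:pci-adverse-endpoints obo:BFO_0000051 "?" --infer
https://w3id.org/mcro/report#pci-adverse-endpoints http://purl.obolibrary.org/obo/BFO_0000051 https://w3id.org/mcro/report#pci-adverse-endpoints-s1032746e [inferred]
...
```

The same pipeline is available as a library:

```python
from mcrokit import (build_core_schema, read_card, to_instance_graph,
                     materialize, check_consistency)

card = read_card(open("pci.yaml").read())          # 12 sections
graph = to_instance_graph(card, build_core_schema())
closed = materialize(graph)
print(len(graph.axioms), len(closed.axioms))        # 124 273
print(check_consistency(graph))                     # []
```

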