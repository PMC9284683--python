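# Methods

## What the toolkit models

A model card report is a short structured document describing a machine
learning model — its details, parameters, considerations (ethics,
trade-offs, intended users) and quantitative performance.  As prose these
documents are not machine-processable.  `mcrokit` re-expresses them as
OWL2-style instance graphs over a small conceptual schema, the Model Card
Report Ontology (MCRO) core, aligned to OBO Foundry vocabularies:

* `mcro:ModelCardReport` is a subclass of IAO *report* (`IAO_0000088`);
* each section class is a subclass of IAO *document part* (`IAO_0000314`);
* part-whole structure uses BFO *has part* (`BFO_0000051`), declared
  transitive with inverse *part of* (`BFO_0000050`);
* eight section classes align to OBO concepts: *is about* links for
  dataset (`IAO_0000100`), architecture (`IAO_0000064`), format
  (`IAO_0000098`), version (`IAO_0000129`) and license (`SWO_0000002`);
  equivalences for reference section (`IAO_0000320`) and graph
  (`IAO_0000038`); a class-level *has part* from citation information to
  citation (`IAO_0000301`);
* `mcro:GraphicCollection` is a subclass of `skos:Collection`;
  `mcro:TradeOff` carries the alternative label "Caveats";
* *software* (`SWO_0000001`) and *algorithm* (`IAO_0000064`) are declared
  disjoint — the canonical worked example for inconsistency detection.

External vocabularies are carried as **stub terms** (IRI, label,
category), not re-hosted: the toolkit is a schema-and-instances engine,
not a mirror of IAO/SWO/PROV-O/SKOS.  Where a label has no printed IRI,
`mcrokit.vocab` is the single table resolving it to a canonical published
identifier; notably the `note` annotation resolves to `skos:note` because
Dublin Core defines no such property (description/date/source are
`dcterms:`).

## Reconstruction of the core roster

The published core artifact reports 38 classes, 0 native object
properties, 11 data properties and 79 logical axioms, but its class-by-
class membership is not published.  Seventeen classes are fixed by the
alignments and figures above; the remaining twenty-one are reconstructed
from the standard model card report structure (owners, developers,
contact, dates, model type, intended/out-of-scope uses, evaluation and
relevant factors, metrics, decision thresholds, variation approaches,
training/evaluation data, preprocessing, motivation, unitary and
intersectional results, limitations).  Each class has exactly one
asserted parent; class-level partonomy wiring assigns each subsection to
one main section.  Under this design the MCRO-namespace counts reproduce
the published core feature counts exactly; the roster itself is this
package's reconstruction, not a published enumeration.  `User` is wired
as a part of `ModelDetails` (matching the published sample nesting)
rather than of `Considerations`.

Class-level section-to-section and section-to-OBO links are stored as
punned property assertions between class terms — the named-term rendering
of the OBO "some values from" pattern — which keeps the container free of
blank-node class expressions.

One edge is genuinely undetermined: whether `QuantitativeAnalysis` links
`GraphicCollection` by *has part* or *is about*.  It is exposed as
`build_core_schema(graphic_collection_edge=...)`, defaulting to
`has-part` for symmetry with every other section link.

## Counting conventions

`stats` reports classes, object properties, data properties and logical
axioms.  Logical axioms are subclass-of, equivalent-class, disjoint-with,
transitive-property, inverse-of, domain, range and all assertion axioms;
declarations and annotation assertions are excluded, matching the common
ontology-editor metric.  With a namespace filter, a term counts by IRI
prefix and an axiom counts by its subject's namespace — except symmetric
kinds (equivalence, disjointness), which count if either side is in the
namespace, since an ontology asserts its own alignment axioms regardless
of how the pair is ordered after lexicographic normalization.

Labels live on terms (one plain `rdfs:label`), not as annotation axioms;
extra or language-tagged labels found on read become annotation axioms.

## Reasoning

`materialize` computes the least fixpoint of five rules: property
transitivity, property inverses (both directions), subclass-chain
closure, type inheritance, and equivalence expanded to mutual
subclassing.  The rule set is monotone over a finite base, so the
fixpoint exists and the semi-naive loop (only newly derived facts fire
further derivations) terminates; derived axioms are flagged `inferred`
and asserted axioms are never removed.  This covers exactly the fragment
instance-encoded cards exercise; property chains, functional and
cardinality axioms are out of scope and are surfaced on read as labelled
unsupported records with a warning rather than silently ignored.
Complete OWL2-DL tableau reasoning (unsatisfiability of complex class
expressions, classification) is a non-goal.

`check_consistency` materializes, then reports one record per
(individual, unordered disjoint pair) whose types collide, with
per-type provenance (asserted vs inferred).  N-ary disjointness read from
files is decomposed into pairs.

## Serialization

Turtle output is deterministic — prefixes, subjects, predicates and
objects all sorted, no blank nodes ever emitted — so byte equality and
graph equality coincide for toolkit-produced files and round-trip
equality needs no isomorphism search.  Reading delegates parsing to
rdflib and then maps triples to axiom kinds using declarations (data vs
annotation property decides the assertion kind; undeclared predicates
default to object/annotation property by object shape).  Reified
`owl:Axiom` annotations are decoded to the axiom they annotate.  OWL/XML
output is write-only; `.owl` files are produced, never read.  Dates and
other annotation values are written as plain literals; typed literals
found on read are preserved with their datatype.

## Validation rules

V1 section individuals must be reachable from a report individual via
asserted *has part*; V2 object-property assertions must satisfy declared
domain/range after materialization; V3 `dcterms:date` values must be ISO
8601; V4 a report with no parts is an error, while each absent main
section is a warning (circulating samples cover, but are not required to
fill, every section — making absence an error would reject them); V5
delegates disjointness to the reasoner.  Findings are data, never
exceptions.

## Synthetic data

`generate_card(seed, n_sections, depth)` draws section kinds uniformly
from the schema-valid kinds at each position, nests within the schema's
part-whole wiring up to `depth`, and stamps every section with
description and date annotations; defaults in the test-suite sweeps use
up to 50 sections and depth 3, comfortably beyond the handful of sections
real cards carry.  `mcrokit.synth` generates random partonomy DAGs
(8-10 individuals, edge probability 0.35), forest taxonomies, typed
graphs with planted disjointness violations, and mixed graphs exercising
every serializable axiom kind.  These fixtures emulate the *structure* of
encoded cards — named terms, shallow taxonomies, tree-ish partonomies,
literal annotations — not the vocabulary breadth or annotation richness
of real OBO ontologies; green tests certify the toolkit's algebra
(closure laws, round-trips, detection soundness), not coverage of any
real-world vocabulary.

## Identifier minting

Instance IRIs are deterministic: the report individual is the card slug
under the instance namespace; each section is the slug plus an 8-hex
digest of its index path from the root.  Re-publishing a card therefore
yields a byte-identical graph, and identifiers survive edits to sibling
sections' content (though not reordering).

## Problem sizes and numerical choices

The property sweeps run 200 random graphs per law with at most 10
individuals and 8 classes each, and 50-graph sweeps inside the
acceptance script; these sizes make closure behavior exhaustively
checkable against brute-force reachability and enumeration oracles while
the whole suite stays in the low seconds.  There is no floating point
anywhere; all comparisons are exact set comparisons.  Ties in symmetric
axioms are broken lexicographically; degenerate inputs (empty graphs,
title-only cards, empty seed lists) are all defined and tested.

## Known limitations

* The reasoner is a rule engine for the fragment described above, not a
  DL reasoner; axioms outside the fragment are surfaced, not interpreted.
* Subset extraction is upward (superclass) closure only; it does not
  preserve logical entailment the way locality-based module extraction
  does, and sub-property hierarchies are not traversed.
* RDF/XML, N-Triples and JSON-LD are not read or written; Turtle is the
  interchange format and OWL/XML is export-only.
* The bundled sample cards mirror the published samples' titles and
  section layout, but their body prose is short placeholder text.
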