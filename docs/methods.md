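# Methods

This note records the design of the conversion toolkit: the hub data
model, the conventions each directed conversion applies, the
normalizations under which documents are compared, the fidelity
checks, and the scope of the synthetic corpus generator.

## 1. Hub model

`InteropDocument` is the format-neutral meeting point of the three
platform families. It holds:

* the document **text** (never normalized, trimmed or re-encoded; any
  whitespace difference is a semantic difference) and an optional
  source id;
* **annotations**: text-anchored units with a span (one segment, or
  several for discontinuous mentions; 0-based half-open code-point
  offsets), a short type label, an optional absolute type URI, a
  feature map, and a layer id;
* **relations**: typed, directed, binary edges between annotations,
  with their own features;
* **chains**: ordered linked sequences of mention annotations (e.g.
  coreference chains); each element may carry a span label, and each
  link *into* an element may carry a link label (element 0 therefore
  never has one);
* **layers**: groupings of annotations by producing component — LIF
  views; PubAnnotation and the CAS have no native equivalent;
* **document attributes**: predicate/value pairs whose subject is the
  document itself;
* a **namespace table** mapping prefixes (and a `_base` default) to
  URIs, making short type tags lexically resolvable.

Feature values are primitives, references to annotations (`Ref`),
nested maps, ordered lists, or unordered sets (`FSet`). Validity rules
(`validate_document`) are checked as data, never raised: span bounds
and segment ordering, id uniqueness, layer existence and rank
monotonicity, reference resolution, absolute type URIs, non-empty
chains.

Names beginning with `_` are reserved for toolkit conventions and are
rejected in user data at read time.

## 2. Conversion conventions

Each directed conversion is read → lift → rewrite → lower → write
through the hub. The conventions bridge structural mismatches:

* **Chain codec** (hub ↔ PubAnnotation). A chain of *n* mentions
  becomes *n* denotations connected by exactly *n − 1* relations with
  the reserved predicate `_next`; the chain type rides in a `_chain`
  attribute on the first mention, a link label in a `_link` attribute
  on its relation. Decoding chases maximal `_next` paths rooted at a
  `_chain`-marked annotation; branching or cycles under `_next` are
  errors (lenient mode leaves branching relations unconverted).
* **Feature flattening** (hub ↔ PubAnnotation). Nested maps flatten to
  dotted attribute names (`author.first`); multi-valued features to
  repeated attributes under the same name, with set semantics. Keys
  containing `.` are ambiguous and rejected in strict mode.
* **View collapse/expand** (hub ↔ PubAnnotation). Layers merge into one
  collection; each annotation keeps its view id (and producer) in
  reserved `_view`/`_producer` attributes, emitted in layer-rank order
  so expansion recovers the original view order from first appearance.
  Views containing no annotations have nowhere to store their identity
  and are a predicted loss.
* **Relations and chains in LIF**. The view model anchors annotations
  by offsets; a relation becomes an *unanchored* annotation whose type
  is the predicate, with reserved `_subj`/`_obj` reference features; a
  chain becomes an unanchored annotation with an ordered `mentions`
  reference list. Links between chain elements are not modelled in
  this format, so link labels are a predicted loss of every conversion
  into it.
* **Latest-view rule** (hub → CAS). The CAS editor model keeps a single
  collection per annotation type. When the same type occurs in several
  views, only the highest-ranked view's occurrences survive; every
  shadowed annotation — and any relation, chain or reference feature
  touching one — is a predicted `shadowed_by_later_view` loss.
* **CAS lowering**. Span types live in the `custom` package
  (`custom.gene`) unless the label is already dotted; a relation
  predicate `p` becomes the TOP subtype `rel.p` with `subj`/`obj`
  reference features; chains use fixed `chain.Chain`/`chain.Link`
  types; document attributes live on a `meta.DocumentMetaData`
  structure whose `documentId` carries the source id. A minimal type
  system is generated per document; integer and floating-point values
  merge to `uima.cas.Double` when a feature carries both. The subset
  has no provisions for discontinuous spans, nested features, set
  semantics, type URIs, namespaces or views.
* **Type ↔ object**. A schemaless denotation stores its type as the
  `obj` string: the absolute type URI when one is known, else the
  short tag, which the document's namespace table may make resolvable.
  Resolution is strictly lexical (no case folding, nothing
  dereferenced).
* **Renamer tables**. Table-driven type/feature renaming between
  vocabularies; tables must have distinct source types and injective
  feature maps, so every table is invertible. A table for the four
  basic types shared by the interchange vocabulary and a common
  editor-side type system ships with the package.

## 3. Loss accounting

The model comparison is encoded as a per-format capability matrix
(`CAPABILITIES`): views, producers, discontinuous spans, ordered
lists, unordered sets, nested features, chain link labels, type URIs,
namespaces, latest-view-only. Two derived operations share it:

* `predict_loss(doc, fmt)` enumerates every construct the target
  cannot express, using a closed vocabulary of eight loss kinds
  (`view_structure`, `chain_link_label`, `discontinuous_span`,
  `multi_valued_feature`, `nested_feature`, `provenance`, `type_uri`,
  `shadowed_by_later_view`). Dropping an annotation cascades: relations
  and chains touching it, and features referencing it, are predicted
  losses too.
* `project(doc, fmt)` applies exactly those losses, yielding the
  document's image in the target's expressible subset. Projection is
  idempotent, and set-valued features targeted at an ordered-array
  format are coerced to a canonically sorted list (reported as a
  `multi_valued_feature` loss of set semantics).

Strict mode raises a `ConversionError` naming the construct only for
discontinuous spans targeted at the CAS model, where silent dropping
would remove an anchored unit of annotation; all other losses are
convention-level and always accompanied by loss entries.

## 4. Canonical equality and fidelity checks

`semantic_key` maps a document to a nested-tuple canonical form:
annotations keyed by (layer rank, span, type, features) as multisets,
references resolved to their target's local structural key (so
equality is modulo ids), relations and chains keyed through their
endpoints. Three documented normalizations keep the formats'
encodings comparable:

1. a singleton set equals its single element (the repeated-attribute
   encoding cannot distinguish them);
2. integers equal the corresponding floating-point values (XML and
   JSON round numeric types differently);
3. unordered sets compare sorted by canonical key; a chain element's
   absent span label equals the chain type (the label the codec
   assigns when re-encoding).

`semantic_diff` reports multiset differences per construct kind plus
feature-level differences for annotations that match structurally.

**Round trip** a→b→a: the verdict is PASS iff the source and the
returned document agree *after projection onto b's expressible
subset* — equivalently, iff the actual loss is contained in the
predicted loss (differential completeness).

**Proxy consistency** a→via→c vs a→c: both results are projected onto
the expressible subsets of all three formats in sequence, and must
agree there.

## 5. Synthetic corpus generator

The generator (`annbridge.synth`) produces valid hub documents,
deterministically under a seed, from a fixed word list — span
boundaries always fall on code points, with no attempt at realistic
text or corpus statistics. Its job is coverage: contiguous and
discontinuous spans, relations, labeled chains, nested and
multi-valued features, reference features, multiple producer views,
namespaces, type URIs, and document attributes, with per-construct
probabilities exposed in `GeneratorConfig`.

Three structural disciplines keep generated documents inside the
well-defined conversion space: chain mentions are dedicated
annotations typed by their span label (or the chain type) and are not
reused as relation endpoints or reference targets; discontinuous
annotations are standalone; a given feature name always carries one
value shape, so every document admits a consistent CAS type system.

## 6. Numerical and serialization choices

* Offsets are character (code point) offsets; no byte/UTF-16 ambiguity
  enters because both JSON readers and `lxml` deliver Python strings.
* Floating-point feature values are serialized with `repr` (shortest
  round-tripping form) in XMI and native JSON floats elsewhere, so
  values survive bit-exactly; no tolerance-based comparison is needed
  or used.
* All writers emit sorted keys/ids and fixed indentation, so writing
  the same document twice is byte-identical, and conversion results
  are diffable.

## 7. Limitations

* The XMI subset is deliberately minimal: one sofa, no nested TOP
  structures, no multiple-inheritance type systems, no binary blobs.
* Chain link labels cannot pass through LIF; round trips through it
  preserve them only up to the predicted loss.
* PubAnnotation's repeated-attribute encoding cannot distinguish a
  singleton set from a plain value; the canonical form equates them.
* The latest-view rule resolves type shadowing by layer rank only; no
  merging of same-type annotations across views is attempted.
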