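# annbridge

Cross-platform conversion for standoff text annotations, with exact
loss accounting.

Three annotation platform families serialize the same conceptual
content — text, span annotations, binary relations, coreference-style
chains, attributes — in structurally different ways:

* **PubAnnotation JSON**: a schemaless repository format of denotations,
  relations and subject/predicate/object attributes over canonical text;
* **LIF JSON-LD**: a pipeline interchange format whose annotations live
  in ordered, append-only *views*, one per producing component;
* **a UIMA XMI subset**: a typed CAS (feature structures over a sofa
  text plus a generated type-system file), as used by CAS-based
  annotation editors.

`annbridge` converts documents between all six directed pairs through a
format-neutral hub model (`InteropDocument`), and treats information
loss as a first-class result: every conversion returns a loss report,
the report is *predictable before converting*, and the fidelity tools
verify that nothing beyond the predicted loss ever changes.

## A worked example

```python
from annbridge import (
    Annotation, ConversionOptions, InteropDocument, Layer, TextSpan,
    from_hub, to_hub,
)

text = "BRCA1 mutations increase breast cancer risk"
doc = InteropDocument(text=text, source_id="example-1")
doc.layers = [Layer(id="ner", producer="ner-2.1", rank=0)]
doc.annotations = [
    Annotation("T1", TextSpan.single(0, 5), "gene", layer_id="ner"),
    Annotation("T2", TextSpan.single(25, 38), "disease", layer_id="ner"),
]

opts = ConversionOptions(strict=False)
result = from_hub(doc, "cas", opts)       # serialize as typed CAS/XMI
for entry in result.loss:
    print(entry.construct_kind, entry.construct_id, entry.detail)
back = to_hub(result.data, "cas", opts)   # and read it back
```

prints the one thing the CAS model cannot keep:

```
provenance ner producer 'ner-2.1' dropped
```

`examples/` contains three short runnable scripts: converting a
document through all three formats, predicting loss before converting,
and running fidelity checks over a synthetic corpus.

## The pieces

* `annbridge.model` — the hub model, validity rules, and a canonical
  form (`semantic_key`) under which documents compare *semantically*,
  modulo annotation ids and serialization details.
* `annbridge.formats` — readers/writers and hub lift/lower for the
  three serializations. All writers are deterministic: writing the same
  document twice is byte-identical.
* `annbridge.rewrite` — the conventions that bridge structural
  mismatches: chains as denotations linked by reserved `_next`
  relations, nested features as dotted attribute names, views collapsed
  into reserved provenance attributes, the latest-view rule, and
  table-driven type renaming.
* `annbridge.capabilities` — the per-format capability matrix as data,
  with `predict_loss` (what a target cannot express) and `project`
  (the document's image in the target's expressible subset).
* `annbridge.fidelity` — `semantic_diff`, plus `check_roundtrip`
  (a→b→a passes iff every difference is explained by predicted loss)
  and `check_proxy` (a→via→c agrees with a→c on the common subset).
* `annbridge.synth` — a seeded generator of synthetic documents
  covering every construct and every predictable loss kind.

Strict mode (the default) raises a `ConversionError` when a construct
cannot be converted — notably discontinuous spans targeted at the CAS
model; lenient mode (`ConversionOptions(strict=False)` or `--lenient`)
drops such constructs with a loss record instead.

## Command line

```bash
annbridge convert --from pubann --to lif doc.json doc.lif.json
annbridge roundtrip --a pubann --b cas --lenient doc.json
annbridge proxy --a cas --via lif --c pubann --lenient doc.xmi
annbridge lossreport --to cas doc.json
annbridge gen --seed 7 --out corpus/ --format pubann
annbridge validate doc.json
```

Exit codes: 0 pass/success, 1 a fidelity check failed, 2 input or usage
error. CAS input/output uses a sibling type-system file
(`doc.xmi` + `doc.ts.xml`), overridable with `--typesystem` /
`--out-typesystem`.

## Tests and the acceptance script

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates a 500-document seeded corpus and
writes the toolkit's headline quantities (round-trip and proxy pass
rates, chain codec conformance, feature-flattening bijection rate,
serialization stability) as JSON, each with the number of cases behind
it.

`docs/methods.md` describes the data model, the conversion
conventions, the canonical-equality normalizations, and the scope and
limits of the synthetic corpus generator.
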