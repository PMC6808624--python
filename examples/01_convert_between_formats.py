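"""Convert one document through all three formats.

Builds a small annotated document in the hub model, serializes it as
PubAnnotation JSON, LIF JSON-LD and the XMI subset, and prints what
each conversion had to give up.
"""

from annbridge import (
    Annotation,
    ChainAnnotation,
    ChainElement,
    ConversionOptions,
    InteropDocument,
    Layer,
    RelationEdge,
    TextSpan,
    from_hub,
    to_hub,
)
from annbridge.pipeline import unpack_cas

text = "BRCA1 mutations increase breast cancer risk"
doc = InteropDocument(text=text, source_id="example-1")
doc.layers = [Layer(id="ner", producer="ner-2.1", rank=0)]
doc.annotations = [
    Annotation("T1", TextSpan.single(0, 5), "gene", layer_id="ner"),
    Annotation("T2", TextSpan.single(25, 38), "disease", layer_id="ner",
               features={"confidence": 0.93}),
    Annotation("T3", TextSpan.single(39, 43), "risk", layer_id="ner"),
]
doc.relations = [RelationEdge("R1", "increases", subj="T1", obj_ref="T2")]
doc.chains = [
    ChainAnnotation(
        "C1", "coref",
        [ChainElement("T2", span_label="antecedent"),
         ChainElement("T3", span_label="anaphor", link_label="anaphora")],
    )
]

opts = ConversionOptions(strict=False)

for fmt in ("pubann", "lif", "cas"):
    result = from_hub(doc, fmt, opts)
    print(f"--- {fmt}: {len(result.data)} bytes, {len(result.loss)} loss entries")
    for entry in result.loss:
        print(f"    lost {entry.construct_kind} at {entry.construct_id}: {entry.detail}")

# The CAS serialization is two files: a type system and the XMI itself.
ts_bytes, xmi_bytes = unpack_cas(from_hub(doc, "cas", opts).data)
print("\nGenerated type system (first lines):")
print("\n".join(ts_bytes.decode().splitlines()[:8]))

# Reading any serialization back yields a hub document again.
back = to_hub(from_hub(doc, "lif", opts).data, "lif", opts)
print(f"\nRead back from LIF: {len(back.annotations)} annotations, "
      f"{len(back.relations)} relations, {len(back.chains)} chains")
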