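"""Predict what a conversion will lose, before converting.

The capability matrix drives both the prediction and the conversion
itself, so the loss report is exact: whatever it lists is dropped, and
nothing else is.
"""

from annbridge import (
    Annotation,
    ConversionOptions,
    FSet,
    InteropDocument,
    Layer,
    TextSpan,
    predict_loss,
    project,
    semantic_diff,
)

text = "tumor necrosis factor alpha binds its receptor"
doc = InteropDocument(text=text)
doc.namespaces["_base"] = "https://example.org/schema/"
doc.layers = [
    Layer(id="tok", producer="tokenizer-1.0", rank=0),
    Layer(id="ner", producer="ner-2.1", rank=1),
]
doc.annotations = [
    # a discontinuous mention: "tumor ... factor"
    Annotation("T1", TextSpan(((0, 5), (15, 21))), "protein", layer_id="ner"),
    Annotation("T2", TextSpan.single(38, 46), "receptor", layer_id="ner",
               type_uri="https://example.org/schema/receptor",
               features={"tags": FSet(["membrane", "signaling"]),
                         "author": {"first": "ada", "last": "byron"}}),
]

opts = ConversionOptions(strict=False)

for fmt in ("pubann", "lif", "cas"):
    entries = predict_loss(doc, fmt, opts)
    print(f"--- converting to {fmt}: {len(entries)} predicted losses")
    for e in entries:
        print(f"    {e.construct_kind:24s} {e.construct_id:6s} {e.detail}")

# project() applies exactly those losses; the projected document is the
# image of the original in the target's expressible subset.
projected = project(doc, "cas", opts)
print("\nafter projecting onto the CAS subset:")
print(f"  annotations: {[a.id for a in projected.annotations]}")
print(f"  features of T2: {sorted(projected.annotation_by_id()['T2'].features)}")
print(f"  projection is idempotent: "
      f"{semantic_diff(projected, project(projected, 'cas', opts)).empty}")
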