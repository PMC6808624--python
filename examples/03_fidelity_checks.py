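"""Round-trip and proxy-consistency checks over a synthetic corpus.

A round trip a→b→a passes when every difference between the source and
the returned document is explained by a predicted loss (differential
completeness).  A proxy check passes when a→via→c agrees with a→c on
the constructs all three formats can express.
"""

from annbridge import ConversionOptions, GeneratorConfig, from_hub, generate_corpus
from annbridge.fidelity import check_proxy, check_roundtrip

opts = ConversionOptions(strict=False)
corpus = generate_corpus(GeneratorConfig(seed=11, n_documents=25))

print(f"corpus: {len(corpus)} documents")

for a, b in (("pubann", "lif"), ("lif", "pubann"), ("cas", "lif")):
    passed = sum(
        check_roundtrip(from_hub(d, a, opts).data, a, b, opts).verdict == "PASS"
        for d in corpus
    )
    print(f"roundtrip {a:7s} -> {b:7s} -> {a}: {passed}/{len(corpus)} pass")

passed = sum(
    check_proxy(from_hub(d, "cas", opts).data, "cas", "lif", "pubann", opts).verdict
    == "PASS"
    for d in corpus
)
print(f"proxy cas -> lif -> pubann vs cas -> pubann: {passed}/{len(corpus)} pass")

# inspect one report in full
report = check_roundtrip(from_hub(corpus[0], "cas", opts).data, "cas", "lif", opts)
print(f"\nfirst document: verdict {report.verdict}, "
      f"{len(report.predicted)} predicted losses, "
      f"unexplained differences: {not report.diff.empty}")
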