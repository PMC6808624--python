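"""Fidelity checks: semantic diffs, round trips, proxy consistency.

The central questions a conversion toolkit must answer: what exactly
does a conversion drop, is everything it drops announced beforehand
(differential completeness), and does converting A→C directly agree
with converting A→B→C through an intermediate platform (proxy
consistency) on the constructs all three can express?
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .capabilities import LossEntry, predict_loss, project
from .model import InteropDocument, semantic_key, validate_document
from .pipeline import FORMATS, convert, to_hub
from .rewrite import ConversionOptions, invert_renamer

__all__ = [
    "DiffReport",
    "semantic_diff",
    "check_roundtrip",
    "check_proxy",
    "RoundtripResult",
    "ProxyResult",
]

# exit codes for CI use (mirrored by the command-line interface)
EXIT_PASS = 0
EXIT_FAIL = 1
EXIT_INPUT_ERROR = 2


@dataclass
class DiffReport:
    """Semantic difference between two documents: entries present only
    on one side (canonical-form entries), plus per-entry feature-level
    differences for annotations that match structurally."""

    only_in_a: list = field(default_factory=list)
    only_in_b: list = field(default_factory=list)
    feature_diffs: list = field(default_factory=list)  # (entry, feature, va, vb)

    @property
    def empty(self) -> bool:
        return not (self.only_in_a or self.only_in_b or self.feature_diffs)

    def to_json(self) -> dict:
        return {
            "only_in_a": [repr(e) for e in self.only_in_a],
            "only_in_b": [repr(e) for e in self.only_in_b],
            "feature_diffs": [
                {"entry": repr(e), "feature": f, "a": repr(va), "b": repr(vb)}
                for e, f, va, vb in self.feature_diffs
            ],
        }


def _multiset_diff(a: list, b: list) -> tuple:
    """Multiset difference preserving multiplicity."""
    from collections import Counter

    ca, cb = Counter(a), Counter(b)
    only_a = list((ca - cb).elements())
    only_b = list((cb - ca).elements())
    return only_a, only_b


def semantic_diff(a: InteropDocument, b: InteropDocument) -> DiffReport:
    """Compare two documents canonically.  Symmetric: swapping the
    arguments swaps ``only_in_a``/``only_in_b``.  Empty iff the
    canonical forms are identical."""
    for name, doc in (("a", a), ("b", b)):
        violations = validate_document(doc)
        if violations:
            raise ValueError(f"document {name} does not validate: {violations[:3]}")

    ka, kb = semantic_key(a), semantic_key(b)
    report = DiffReport()
    if ka == kb:
        return report

    # document-scalar differences
    labels = ["text", "source_id", "layers", "annotations", "relations", "chains",
              "doc_attributes", "namespaces"]
    for label, va, vb in zip(labels, ka[1:], kb[1:]):
        if label in ("text", "source_id", "namespaces", "layers") and va != vb:
            report.feature_diffs.append((("document",), label, va, vb))

    # entry-level multiset differences
    for idx, label in ((4, "annotations"), (5, "relations"), (6, "chains"), (7, "doc_attributes")):
        only_a, only_b = _multiset_diff(list(ka[idx]), list(kb[idx]))
        if label == "annotations":
            # pair up annotations that differ only in features
            def locator(entry):
                return entry[1:6]  # (rank pos, layer, span, label, uri)

            matched_a, matched_b = set(), set()
            for i, ea in enumerate(only_a):
                for j, eb in enumerate(only_b):
                    if j in matched_b:
                        continue
                    if locator(ea) == locator(eb):
                        fa, fb = dict(ea[6]), dict(eb[6])
                        for fname in sorted(set(fa) | set(fb)):
                            if fa.get(fname) != fb.get(fname):
                                report.feature_diffs.append(
                                    (locator(ea), fname, fa.get(fname), fb.get(fname))
                                )
                        matched_a.add(i)
                        matched_b.add(j)
                        break
            only_a = [e for i, e in enumerate(only_a) if i not in matched_a]
            only_b = [e for j, e in enumerate(only_b) if j not in matched_b]
        report.only_in_a.extend(only_a)
        report.only_in_b.extend(only_b)
    return report


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------

@dataclass
class RoundtripResult:
    diff: DiffReport
    predicted: list
    verdict: str  # "PASS" | "FAIL"

    def to_json(self) -> dict:
        return {
            "verdict": self.verdict,
            "predicted_loss": [e.to_json() for e in self.predicted],
            "unexplained": self.diff.to_json(),
        }


def _backward_opts(opts: ConversionOptions) -> ConversionOptions:
    if opts.renamer is None:
        return opts
    from dataclasses import replace

    return replace(opts, renamer=invert_renamer(opts.renamer))


def check_roundtrip(
    doc_bytes: bytes,
    format_a: str,
    format_b: str,
    opts: Optional[ConversionOptions] = None,
) -> RoundtripResult:
    """Convert a→b→a and verify differential completeness: the verdict
    is PASS iff every difference between the source and the returned
    document is explained by a predicted loss, i.e. the two agree after
    projection onto format b's expressible subset."""
    opts = opts or ConversionOptions()
    original = to_hub(doc_bytes, format_a, opts)
    forward = convert(doc_bytes, format_a, format_b, opts)
    back = convert(forward.data, format_b, format_a, _backward_opts(opts))
    returned = to_hub(back.data, format_a, opts)

    predicted = predict_loss(original, format_b, opts)
    proj_a = project(original, format_b, opts)
    proj_b = project(returned, format_b, opts)
    diff = semantic_diff(proj_a, proj_b)
    verdict = "PASS" if diff.empty else "FAIL"
    return RoundtripResult(diff=diff, predicted=predicted, verdict=verdict)


@dataclass
class ProxyResult:
    diff: DiffReport
    excluded: list  # loss entries defining the excluded constructs
    verdict: str

    def to_json(self) -> dict:
        return {
            "verdict": self.verdict,
            "excluded": [e.to_json() for e in self.excluded],
            "diff": self.diff.to_json(),
        }


def check_proxy(
    doc_bytes: bytes,
    a: str,
    via: str,
    c: str,
    opts: Optional[ConversionOptions] = None,
) -> ProxyResult:
    """Compare convert(a→via→c) against convert(a→c) on the common
    subset — the constructs with no predicted loss in any of the three
    formats.  PASS iff they agree there."""
    opts = opts or ConversionOptions()
    source = to_hub(doc_bytes, a, opts)

    step1 = convert(doc_bytes, a, via, opts)
    step2 = convert(step1.data, via, c, opts)
    direct = convert(doc_bytes, a, c, opts)

    def restrict(doc: InteropDocument) -> InteropDocument:
        for fmt in (a, via, c):
            doc = project(doc, fmt, opts)
        return doc

    excluded = []
    for fmt in (a, via, c):
        excluded.extend(predict_loss(source, fmt, opts))

    via_doc = restrict(to_hub(step2.data, c, opts))
    direct_doc = restrict(to_hub(direct.data, c, opts))
    diff = semantic_diff(via_doc, direct_doc)
    verdict = "PASS" if diff.empty else "FAIL"
    return ProxyResult(diff=diff, excluded=excluded, verdict=verdict)
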