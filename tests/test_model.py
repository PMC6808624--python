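"""Model invariants, type resolution and the canonical form."""

import random

import pytest

from annbridge.model import (
    Annotation,
    ChainAnnotation,
    DocumentAttribute,
    FSet,
    InteropDocument,
    Layer,
    Ref,
    RelationEdge,
    TextSpan,
    resolve_type_uri,
    reverse_resolve_type_uri,
    semantic_key,
    validate_document,
)
from annbridge.synth import GeneratorConfig, generate_corpus

from conftest import build_small_doc


# ---------------------------------------------------------------------------
# TextSpan
# ---------------------------------------------------------------------------

def test_textspan_single():
    s = TextSpan.single(3, 9)
    assert not s.discontinuous
    assert (s.begin, s.end) == (3, 9)
    assert s.covered_text("0123456789abcd") == "345678"


def test_textspan_discontinuous():
    s = TextSpan(((0, 2), (5, 7)))
    assert s.discontinuous
    assert (s.begin, s.end) == (0, 7)
    assert s.covered_text("abcdefgh") == "abfg"


def test_textspan_requires_segment():
    with pytest.raises(ValueError):
        TextSpan(())


# ---------------------------------------------------------------------------
# validate_document
# ---------------------------------------------------------------------------

def _codes(doc):
    return {v.code for v in validate_document(doc)}


def test_valid_small_doc(small_doc):
    assert validate_document(small_doc) == []


def test_duplicate_id():
    doc = InteropDocument(text="ab", layers=[Layer("l0")])
    doc.annotations = [
        Annotation("T1", TextSpan.single(0, 1), "x"),
        Annotation("T1", TextSpan.single(1, 2), "y"),
    ]
    assert "id.duplicate" in _codes(doc)


def test_span_out_of_bounds():
    doc = InteropDocument(text="ab", layers=[Layer("l0")])
    doc.annotations = [Annotation("T1", TextSpan.single(0, 5), "x")]
    assert "span.bounds" in _codes(doc)


def test_overlapping_segments():
    doc = InteropDocument(text="abcdef", layers=[Layer("l0")])
    doc.annotations = [Annotation("T1", TextSpan(((0, 4), (2, 6))), "x")]
    assert "span.order" in _codes(doc)


def test_dangling_layer():
    doc = InteropDocument(text="ab", layers=[Layer("l0")])
    doc.annotations = [Annotation("T1", TextSpan.single(0, 1), "x", layer_id="nope")]
    assert "layer.dangling" in _codes(doc)


def test_dangling_relation_endpoint():
    doc = InteropDocument(text="ab", layers=[Layer("l0")])
    doc.annotations = [Annotation("T1", TextSpan.single(0, 1), "x")]
    doc.relations = [RelationEdge("R1", "p", "T1", "T9")]
    assert "ref.dangling" in _codes(doc)


def test_dangling_feature_ref():
    doc = InteropDocument(text="ab", layers=[Layer("l0")])
    doc.annotations = [
        Annotation("T1", TextSpan.single(0, 1), "x", features={"p": Ref("T9")})
    ]
    assert "ref.dangling" in _codes(doc)


def test_dangling_doc_attribute_ref():
    doc = InteropDocument(text="ab", layers=[Layer("l0")])
    doc.doc_attributes = [DocumentAttribute("p", FSet([Ref("T9")]))]
    assert "ref.dangling" in _codes(doc)


def test_empty_chain():
    doc = InteropDocument(text="ab", layers=[Layer("l0")])
    doc.chains = [ChainAnnotation("C1", "coref", [])]
    assert "chain.empty" in _codes(doc)


def test_relative_type_uri_rejected():
    doc = InteropDocument(text="ab", layers=[Layer("l0")])
    doc.annotations = [
        Annotation("T1", TextSpan.single(0, 1), "x", type_uri="not a uri")
    ]
    assert "type.uri" in _codes(doc)


def test_layer_rank_order():
    doc = InteropDocument(text="ab", layers=[Layer("a", rank=1), Layer("b", rank=0)])
    assert "layer.rank-order" in _codes(doc)


# ---------------------------------------------------------------------------
# type resolution (strictly lexical)
# ---------------------------------------------------------------------------

def test_resolve_absolute_uri_passthrough():
    assert resolve_type_uri("https://x.org/a", {}) == "https://x.org/a"


def test_resolve_prefix():
    ns = {"ex": "https://x.org/"}
    assert resolve_type_uri("ex:Gene", ns) == "https://x.org/Gene"


def test_resolve_default_base():
    ns = {"_base": "https://x.org/"}
    assert resolve_type_uri("Gene", ns) == "https://x.org/Gene"


def test_resolve_unresolved():
    assert resolve_type_uri("Gene", {}) is None
    assert resolve_type_uri("unknown:Gene", {}) is None


def test_resolve_no_case_folding():
    ns = {"_base": "https://x.org/"}
    assert resolve_type_uri("gene", ns) == "https://x.org/gene"
    assert resolve_type_uri("Gene", ns) != resolve_type_uri("gene", ns)


def test_reverse_resolve_inverts():
    ns = {"_base": "https://x.org/", "ex": "https://x.org/ext/"}
    for label in ("Gene", "ex:Deep"):
        uri = resolve_type_uri(label, ns)
        assert reverse_resolve_type_uri(uri, ns) == label


def test_reverse_resolve_longest_base_wins():
    ns = {"a": "https://x.org/", "b": "https://x.org/sub/"}
    assert reverse_resolve_type_uri("https://x.org/sub/T", ns) == "b:T"


def test_resolve_empty_label_raises():
    with pytest.raises(ValueError):
        resolve_type_uri("", {})


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------

def _rename_ids(doc, mapping):
    from dataclasses import replace

    doc = replace(
        doc,
        annotations=[
            replace(
                a,
                id=mapping.get(a.id, a.id),
                features={
                    k: (Ref(mapping.get(v.target, v.target)) if isinstance(v, Ref) else v)
                    for k, v in a.features.items()
                },
            )
            for a in doc.annotations
        ],
        relations=[
            replace(
                r,
                id=mapping.get(r.id, r.id),
                subj=mapping.get(r.subj, r.subj),
                obj_ref=mapping.get(r.obj_ref, r.obj_ref),
            )
            for r in doc.relations
        ],
        chains=[
            replace(
                c,
                id=mapping.get(c.id, c.id),
                elements=[
                    replace(el, mention=mapping.get(el.mention, el.mention))
                    for el in c.elements
                ],
            )
            for c in doc.chains
        ],
    )
    return doc


def test_semantic_key_invariant_under_id_renaming(small_doc):
    mapping = {"T1": "X9", "T2": "X8", "T3": "X7", "T4": "X6", "T5": "X5",
               "R1": "Y1", "C1": "Z1"}
    renamed = _rename_ids(small_doc, mapping)
    assert semantic_key(small_doc) == semantic_key(renamed)


def test_semantic_key_invariant_under_order(small_doc):
    from dataclasses import replace

    rng = random.Random(3)
    shuffled = replace(
        small_doc,
        annotations=rng.sample(small_doc.annotations, len(small_doc.annotations)),
        relations=rng.sample(small_doc.relations, len(small_doc.relations)),
        doc_attributes=rng.sample(small_doc.doc_attributes, len(small_doc.doc_attributes)),
    )
    assert semantic_key(small_doc) == semantic_key(shuffled)


def test_semantic_key_detects_feature_change(small_doc):
    changed = build_small_doc()
    changed.annotations[0].features["confidence"] = 0.1
    assert semantic_key(small_doc) != semantic_key(changed)


def test_semantic_key_singleton_set_equals_element():
    a = InteropDocument(text="ab", layers=[Layer("l0")])
    a.annotations = [Annotation("T1", TextSpan.single(0, 1), "x", features={"p": "v"})]
    b = InteropDocument(text="ab", layers=[Layer("l0")])
    b.annotations = [
        Annotation("T1", TextSpan.single(0, 1), "x", features={"p": FSet(["v"])})
    ]
    assert semantic_key(a) == semantic_key(b)


def test_semantic_key_int_float_equal():
    a = InteropDocument(text="ab", layers=[Layer("l0")])
    a.doc_attributes = [DocumentAttribute("n", 3)]
    b = InteropDocument(text="ab", layers=[Layer("l0")])
    b.doc_attributes = [DocumentAttribute("n", 3.0)]
    assert semantic_key(a) == semantic_key(b)


def test_semantic_key_set_order_insensitive():
    a = InteropDocument(text="ab", layers=[Layer("l0")])
    a.doc_attributes = [DocumentAttribute("k", FSet(["x", "y"]))]
    b = InteropDocument(text="ab", layers=[Layer("l0")])
    b.doc_attributes = [DocumentAttribute("k", FSet(["y", "x"]))]
    assert semantic_key(a) == semantic_key(b)


def test_semantic_key_rejects_invalid():
    doc = InteropDocument(text="ab", layers=[Layer("l0")])
    doc.relations = [RelationEdge("R1", "p", "T1", "T2")]
    with pytest.raises(ValueError):
        semantic_key(doc)


def test_semantic_key_invariance_on_generated_corpus():
    rng = random.Random(99)
    for doc in generate_corpus(GeneratorConfig(seed=5, n_documents=10)):
        ids = [a.id for a in doc.annotations]
        mapping = {old: f"Q{i}" for i, old in enumerate(rng.sample(ids, len(ids)))}
        assert semantic_key(doc) == semantic_key(_rename_ids(doc, mapping))
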