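"""Conventions: chain codec, feature flattening, views, renamers."""

import random
from dataclasses import replace

import pytest

from annbridge.model import (
    Annotation,
    ChainAnnotation,
    ChainElement,
    FSet,
    InteropDocument,
    Layer,
    RelationEdge,
    TextSpan,
    semantic_key,
)
from annbridge.rewrite import (
    ConversionError,
    ConversionOptions,
    RenamerEntry,
    RenamerTable,
    apply_renamer,
    collapse_views,
    decode_chains,
    encode_chains,
    expand_views,
    flatten_features,
    invert_renamer,
    obj_to_type,
    select_latest_views,
    type_to_obj,
    unflatten_features,
    wsev_dkpro_renamer,
)


def _chain_doc(n, rng):
    """A document holding a single chain of n mentions."""
    text = "word " * (n + 2)
    doc = InteropDocument(text=text, layers=[Layer("l0")])
    elements = []
    for i in range(n):
        span_label = rng.choice(("anaphor", "antecedent", None))
        mention = Annotation(
            id=f"T{i}",
            span=TextSpan.single(5 * i, 5 * i + 4),
            type_label=span_label if span_label is not None else "coref",
        )
        doc.annotations.append(mention)
        elements.append(
            ChainElement(
                mention=mention.id,
                span_label=span_label,
                link_label=rng.choice(("anaphora", None)) if i > 0 else None,
            )
        )
    doc.chains.append(ChainAnnotation("C1", "coref", elements))
    return doc


# ---------------------------------------------------------------------------
# chain codec
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n", range(1, 11))
def test_chain_codec_law(n):
    opts = ConversionOptions()
    rng = random.Random(n)
    doc = _chain_doc(n, rng)
    encoded = encode_chains(doc, opts)
    assert not encoded.chains
    assert len(encoded.annotations) == n
    link_rels = [r for r in encoded.relations if r.predicate == opts.chain_link_predicate]
    assert len(link_rels) == n - 1
    starts = [
        a for a in encoded.annotations if opts.chain_type_predicate in a.features
    ]
    assert len(starts) == 1 and starts[0].id == "T0"

    decoded = decode_chains(encoded, opts)
    assert semantic_key(decoded) == semantic_key(doc)


def test_chain_codec_preserves_link_labels():
    opts = ConversionOptions()
    doc = _chain_doc(4, random.Random(0))
    for i, el in enumerate(doc.chains[0].elements):
        el.link_label = "anaphora" if i > 0 else None
    encoded = encode_chains(doc, opts)
    labeled = [
        r
        for r in encoded.relations
        if r.predicate == opts.chain_link_predicate
        and r.features.get(opts.link_label_predicate) == "anaphora"
    ]
    assert len(labeled) == 3
    assert semantic_key(decode_chains(encoded, opts)) == semantic_key(doc)


def test_decode_branching_strict_raises():
    opts = ConversionOptions(strict=True)
    doc = InteropDocument(text="aa bb cc", layers=[Layer("l0")])
    for i in range(3):
        doc.annotations.append(
            Annotation(f"T{i}", TextSpan.single(3 * i, 3 * i + 2), "m")
        )
    doc.annotations[0].features[opts.chain_type_predicate] = "coref"
    doc.relations = [
        RelationEdge("R1", opts.chain_link_predicate, "T0", "T1"),
        RelationEdge("R2", opts.chain_link_predicate, "T0", "T2"),
    ]
    with pytest.raises(ConversionError):
        decode_chains(doc, opts)
    # lenient: everything left as-is
    lenient = decode_chains(doc, replace(opts, strict=False))
    assert not lenient.chains and len(lenient.relations) == 2


def test_decode_cycle_raises():
    opts = ConversionOptions()
    doc = InteropDocument(text="aa bb", layers=[Layer("l0")])
    doc.annotations = [
        Annotation("T0", TextSpan.single(0, 2), "m"),
        Annotation("T1", TextSpan.single(3, 5), "m"),
    ]
    doc.annotations[0].features[opts.chain_type_predicate] = "coref"
    doc.relations = [
        RelationEdge("R1", opts.chain_link_predicate, "T0", "T1"),
        RelationEdge("R2", opts.chain_link_predicate, "T1", "T0"),
    ]
    with pytest.raises(ConversionError):
        decode_chains(doc, opts)


def test_chain_codec_many_random_cases():
    opts = ConversionOptions()
    rng = random.Random(42)
    for _ in range(200):
        n = rng.randint(1, 10)
        doc = _chain_doc(n, rng)
        encoded = encode_chains(doc, opts)
        assert len([r for r in encoded.relations if r.predicate == "_next"]) == n - 1
        assert semantic_key(decode_chains(encoded, opts)) == semantic_key(doc)


# ---------------------------------------------------------------------------
# feature flattening
# ---------------------------------------------------------------------------

_SCALARS = ("tok", "tag", 1, 2.5, True, False)


def _random_nested(rng, depth):
    if depth == 0 or rng.random() < 0.4:
        if rng.random() < 0.25:
            # multi-valued leaf: at least two values so that the repeated
            # attribute encoding is unambiguous
            return FSet([rng.choice(_SCALARS) for _ in range(rng.randint(2, 4))])
        return rng.choice(_SCALARS)
    return {
        f"k{rng.randint(0, 30)}": _random_nested(rng, depth - 1)
        for _ in range(rng.randint(1, 3))
    }


def test_flatten_unflatten_bijection_random():
    rng = random.Random(7)
    for _ in range(300):
        features = {
            f"f{i}": _random_nested(rng, rng.randint(0, 4)) for i in range(rng.randint(1, 4))
        }
        pairs = flatten_features(features)
        assert unflatten_features(pairs) == features


def test_flatten_nested_map():
    pairs = flatten_features({"author": {"first": "a", "last": "b"}})
    assert sorted(pairs) == [("author.first", "a"), ("author.last", "b")]


def test_flatten_set_becomes_repeated_pairs():
    pairs = flatten_features({"tags": FSet(["x", "y"])})
    assert pairs == [("tags", "x"), ("tags", "y")]
    assert unflatten_features(pairs) == {"tags": FSet(["x", "y"])}


def test_flatten_dotted_key_rejected_strict():
    with pytest.raises(ConversionError):
        flatten_features({"a.b": 1}, strict=True)
    with pytest.raises(ConversionError):
        flatten_features({"outer": {"a.b": 1}}, strict=True)


def test_flatten_dotted_key_skipped_lenient():
    assert flatten_features({"a.b": 1, "ok": 2}, strict=False) == [("ok", 2)]


# ---------------------------------------------------------------------------
# views
# ---------------------------------------------------------------------------

def _view_doc(k, rng):
    text = "word " * 10
    doc = InteropDocument(text=text)
    for v in range(k):
        doc.layers.append(
            Layer(id=f"v{v}", producer=f"tool-{v}" if rng.random() < 0.5 else None, rank=v)
        )
    n = 0
    for v in range(k):
        for _ in range(rng.randint(1, 3)):  # every view populated
            doc.annotations.append(
                Annotation(
                    id=f"T{n}",
                    span=TextSpan.single(0, 4),
                    type_label=rng.choice(("Token", "Sentence", "gene")),
                    layer_id=f"v{v}",
                )
            )
            n += 1
    return doc


@pytest.mark.parametrize("k", range(1, 6))
def test_collapse_expand_inverse(k):
    opts = ConversionOptions()
    rng = random.Random(k)
    doc = _view_doc(k, rng)
    collapsed = collapse_views(doc, opts)
    assert len(collapsed.layers) == 1
    assert all(opts.provenance_predicate in a.features for a in collapsed.annotations)
    restored = expand_views(collapsed, opts)
    assert semantic_key(restored) == semantic_key(doc)


def test_latest_view_rule():
    opts = ConversionOptions()
    doc = InteropDocument(text="aa bb cc")
    doc.layers = [Layer("v0", rank=0), Layer("v1", rank=1)]
    doc.annotations = [
        Annotation("T0", TextSpan.single(0, 2), "Token", layer_id="v0"),
        Annotation("T1", TextSpan.single(3, 5), "Token", layer_id="v1"),
        Annotation("T2", TextSpan.single(6, 8), "gene", layer_id="v0"),
    ]
    selected, shadowed = select_latest_views(doc, opts)
    kept = {a.id for a in selected.annotations}
    assert kept == {"T1", "T2"}  # v1's Token shadows v0's; gene only in v0
    assert [(a.id, winner) for a, winner in shadowed] == [("T0", "v1")]


def test_latest_view_rule_disabled():
    opts = ConversionOptions(latest_view_only=False)
    doc = InteropDocument(text="aa bb")
    doc.layers = [Layer("v0", rank=0), Layer("v1", rank=1)]
    doc.annotations = [
        Annotation("T0", TextSpan.single(0, 2), "Token", layer_id="v0"),
        Annotation("T1", TextSpan.single(3, 5), "Token", layer_id="v1"),
    ]
    selected, shadowed = select_latest_views(doc, opts)
    assert len(selected.annotations) == 2 and shadowed == []


def test_latest_view_drops_dependent_relations_and_chains():
    opts = ConversionOptions()
    doc = InteropDocument(text="aa bb cc")
    doc.layers = [Layer("v0", rank=0), Layer("v1", rank=1)]
    doc.annotations = [
        Annotation("T0", TextSpan.single(0, 2), "Token", layer_id="v0"),
        Annotation("T1", TextSpan.single(3, 5), "Token", layer_id="v1"),
        Annotation("T2", TextSpan.single(6, 8), "gene", layer_id="v0"),
    ]
    doc.relations = [RelationEdge("R1", "p", "T2", "T0")]
    doc.chains = [
        ChainAnnotation("C1", "coref", [ChainElement("T0"), ChainElement("T2")])
    ]
    selected, _ = select_latest_views(doc, opts)
    assert selected.relations == [] and selected.chains == []


# ---------------------------------------------------------------------------
# renamer
# ---------------------------------------------------------------------------

def test_renamer_roundtrip():
    table = wsev_dkpro_renamer()
    doc = InteropDocument(text="aa bb", layers=[Layer("l0")])
    doc.annotations = [
        Annotation("T0", TextSpan.single(0, 2), "POS", features={"pos": "NN"}),
        Annotation("T1", TextSpan.single(3, 5), "custom", features={"pos": "x"}),
    ]
    renamed = apply_renamer(doc, table)
    assert renamed.annotations[0].type_label.endswith(".pos.POS")
    assert renamed.annotations[0].features == {"PosValue": "NN"}
    # unmatched annotation passes through untouched
    assert renamed.annotations[1].type_label == "custom"
    back = apply_renamer(renamed, invert_renamer(table))
    assert semantic_key(back) == semantic_key(doc)


def test_renamer_duplicate_sources_rejected():
    with pytest.raises(ConversionError):
        RenamerTable((RenamerEntry("A", "X"), RenamerEntry("A", "Y")))


def test_renamer_non_injective_feature_map_rejected():
    with pytest.raises(ConversionError):
        RenamerTable((RenamerEntry("A", "X", (("a", "t"), ("b", "t"))),))


# ---------------------------------------------------------------------------
# type <-> obj
# ---------------------------------------------------------------------------

def test_type_to_obj_prefers_uri():
    a = Annotation("T0", TextSpan.single(0, 1), "gene", type_uri="https://x.org/gene")
    assert type_to_obj(a, {}) == "https://x.org/gene"


def test_type_to_obj_falls_back_to_label():
    a = Annotation("T0", TextSpan.single(0, 1), "gene")
    assert type_to_obj(a, {}) == "gene"


def test_obj_to_type_roundtrip():
    ns = {"_base": "https://x.org/"}
    label, uri = obj_to_type("https://x.org/gene", ns)
    assert (label, uri) == ("gene", "https://x.org/gene")
    assert obj_to_type("gene", ns) == ("gene", None)


def test_obj_to_type_unknown_uri_uses_local_name():
    label, uri = obj_to_type("https://other.org/vocab#Disease", {})
    assert label == "Disease" and uri == "https://other.org/vocab#Disease"
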