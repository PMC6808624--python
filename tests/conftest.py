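"""Shared fixtures: a small hand-built document exercising every
construct, plus lenient conversion options."""

import pytest

from annbridge.model import (
    Annotation,
    ChainAnnotation,
    ChainElement,
    DocumentAttribute,
    FSet,
    InteropDocument,
    Layer,
    Ref,
    RelationEdge,
    TextSpan,
)
from annbridge.rewrite import ConversionOptions


@pytest.fixture
def lenient():
    return ConversionOptions(strict=False)


@pytest.fixture
def strict():
    return ConversionOptions(strict=True)


def build_small_doc(discontinuous: bool = False) -> InteropDocument:
    """A compact document with two views, a relation, a chain, nested and
    multi-valued features, a reference feature, namespaces and
    document-level attributes."""
    text = "alpha kinase binds beta receptor in tumor cells"
    doc = InteropDocument(text=text, source_id="DOC-small")
    doc.namespaces["_base"] = "https://example.org/schema/"
    doc.layers = [
        Layer(id="v0", producer="tokenizer-1.0", rank=0),
        Layer(id="v1", producer="ner-2.1", rank=1),
    ]
    doc.annotations = [
        Annotation(
            id="T1",
            span=TextSpan.single(0, 12),
            type_label="gene",
            type_uri="https://example.org/schema/gene",
            features={"confidence": 0.9, "author": {"first": "ada", "last": "byron"}},
            layer_id="v0",
        ),
        Annotation(
            id="T2",
            span=TextSpan.single(19, 32),
            type_label="protein",
            features={"tags": FSet(["x", "y"]), "pointer": Ref("T1")},
            layer_id="v1",
        ),
        Annotation(id="T3", span=TextSpan.single(36, 41), type_label="disease", layer_id="v1"),
        Annotation(id="T4", span=TextSpan.single(42, 47), type_label="anaphor", layer_id="v1"),
        Annotation(id="T5", span=TextSpan.single(36, 41), type_label="antecedent", layer_id="v1"),
    ]
    if discontinuous:
        doc.annotations.append(
            Annotation(
                id="T6",
                span=TextSpan(((0, 5), (19, 23))),
                type_label="split",
                layer_id="v0",
            )
        )
    doc.relations = [
        RelationEdge(
            id="R1", predicate="causes", subj="T1", obj_ref="T3",
            features={"confidence": 0.7},
        )
    ]
    doc.chains = [
        ChainAnnotation(
            id="C1",
            chain_type="coref",
            elements=[
                ChainElement(mention="T5", span_label="antecedent"),
                ChainElement(mention="T4", span_label="anaphor", link_label="anaphora"),
            ],
        )
    ]
    doc.doc_attributes = [
        DocumentAttribute("language", "en"),
        DocumentAttribute("keywords", FSet(["kinase", "annotation"])),
    ]
    return doc


@pytest.fixture
def small_doc():
    return build_small_doc()


@pytest.fixture
def small_doc_discontinuous():
    return build_small_doc(discontinuous=True)
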