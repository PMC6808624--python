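"""Seeded synthetic document generator covering the full feature matrix.

The generator emulates the constructs the three annotation models trade
in — contiguous and discontinuous spans, binary relations, labeled
chains, nested and multi-valued attributes, multiple producer views,
namespace tables, and document-level metadata — over text built from a
fixed word list so that span boundaries always fall on code points.  It
makes no attempt at realistic biomedical text or corpus statistics; its
job is to exercise every conversion rule and every predictable loss
kind, deterministically under a fixed seed.

A few structural disciplines keep generated documents inside the
well-defined conversion space: chain mentions are dedicated annotations
typed by their span label (or the chain type), and are not reused as
relation endpoints or reference targets; discontinuous annotations are
standalone; a given feature name always carries one value shape, so
generated documents always admit a consistent CAS type system.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from typing import Optional

from .model import (
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
    resolve_type_uri,
)

__all__ = ["GeneratorConfig", "generate_corpus", "generate_document"]

_WORDS = (
    "alpha beta gamma delta kinase receptor binding domain protein gene "
    "expression pathway signal cell tissue tumor growth factor complex "
    "membrane nucleus transcript variant sequence motif residue cluster "
    "assay sample control patient cohort dose response marker level "
    "therapy target inhibitor agonist"
).split()

_PRODUCERS = ("tokenizer-1.0", "tagger-0.3", "ner-2.1")
_CHAIN_TYPES = ("coref", "bridging")
_SPAN_LABELS = ("anaphor", "antecedent", None)
_LINK_LABELS = ("anaphora", "cataphora")
_PREDICATES = ("relatedTo", "causes", "partOf")
_DEFAULT_BASE = "https://example.org/schema/"


@dataclass
class GeneratorConfig:
    """Knobs of the corpus generator.  Ranges are inclusive (lo, hi)
    pairs; probabilities are in [0, 1].  Identical config and seed yield
    a byte-identical corpus."""

    seed: int = 0
    n_documents: int = 20
    text_length: tuple = (20, 60)  # words
    n_annotations: tuple = (3, 10)
    p_discontinuous: float = 0.1
    p_chain: float = 0.4
    p_relation: float = 0.25
    p_nested_feature: float = 0.25
    p_multivalued: float = 0.25
    p_doc_attribute: float = 0.5
    n_views: tuple = (1, 3)
    vocabulary: tuple = (
        "Token",
        "Sentence",
        "POS",
        "NamedEntity",
        "person",
        "disease",
        "gene",
    )

    def validate(self) -> None:
        for name in (
            "p_discontinuous",
            "p_chain",
            "p_relation",
            "p_nested_feature",
            "p_multivalued",
            "p_doc_attribute",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("text_length", "n_annotations", "n_views"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty")
        if self.n_documents < 0:
            raise ValueError("n_documents must be non-negative")
        if not self.vocabulary:
            raise ValueError("vocabulary must be non-empty")

    @classmethod
    def from_file(cls, path: str) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = json.loads(value.strip())
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        cfg.validate()
        return cfg


def _rand_span(rng: random.Random, bounds: list, discontinuous: bool) -> TextSpan:
    """Pick a word-aligned span; ``bounds`` is the list of word (begin,
    end) character offsets."""
    n = len(bounds)
    if discontinuous and n >= 4:
        i1 = rng.randrange(0, n - 3)
        j1 = min(n - 3, i1 + rng.randint(0, 1))
        i2 = rng.randrange(j1 + 2, n)
        j2 = min(n - 1, i2 + rng.randint(0, 1))
        return TextSpan(((bounds[i1][0], bounds[j1][1]), (bounds[i2][0], bounds[j2][1])))
    i = rng.randrange(0, n)
    j = min(n - 1, i + rng.randint(0, 2))
    return TextSpan.single(bounds[i][0], bounds[j][1])


def _make_features(
    rng: random.Random, cfg: GeneratorConfig, ref_pool: list
) -> dict:
    """Feature map with a stable value shape per feature name."""
    feats: dict = {}
    if rng.random() < 0.4:
        feats["category"] = rng.choice(("PER", "ORG", "GPE", "MISC"))
    if rng.random() < 0.3:
        feats["confidence"] = round(rng.random(), 3)
    if rng.random() < 0.2:
        feats["score"] = rng.randint(0, 100)
    if rng.random() < 0.2:
        feats["negated"] = rng.random() < 0.5
    if rng.random() < cfg.p_nested_feature:
        author: dict = {
            "first": rng.choice(_WORDS),
            "last": rng.choice(_WORDS),
        }
        if rng.random() < 0.4:
            author = {"name": author, "affil": rng.choice(_WORDS)}
        feats["author"] = author
    if rng.random() < cfg.p_multivalued:
        items = [rng.choice(_WORDS) for _ in range(rng.randint(2, 4))]
        feats["tags"] = FSet(items) if rng.random() < 0.5 else items
    if ref_pool and rng.random() < 0.2:
        feats["pointer"] = Ref(rng.choice(ref_pool))
    return feats


def generate_document(rng: random.Random, cfg: GeneratorConfig, index: int) -> InteropDocument:
    n_words = rng.randint(*cfg.text_length)
    words = [rng.choice(_WORDS) for _ in range(n_words)]
    bounds = []
    pos = 0
    for w in words:
        bounds.append((pos, pos + len(w)))
        pos += len(w) + 1
    text = " ".join(words)

    doc = InteropDocument(text=text)
    if rng.random() < 0.8:
        doc.source_id = f"DOC{index}"
    if rng.random() < 0.5:
        doc.namespaces["_base"] = _DEFAULT_BASE
        if rng.random() < 0.3:
            doc.namespaces["ex"] = "https://example.org/ext/"

    k = rng.randint(*cfg.n_views)
    for v in range(k):
        doc.layers.append(
            Layer(
                id=f"v{v}",
                producer=rng.choice(_PRODUCERS) if rng.random() < 0.5 else None,
                rank=v,
            )
        )
    layer_ids = [l.id for l in doc.layers]

    ann_n = [0]

    def fresh_tid() -> str:
        ann_n[0] += 1
        return f"T{ann_n[0]}"

    plain_ids: list = []  # contiguous, non-chain annotations: ref/relation pool
    for _ in range(rng.randint(*cfg.n_annotations)):
        disc = rng.random() < cfg.p_discontinuous
        label = rng.choice(cfg.vocabulary)
        uri = None
        if doc.namespaces and not disc and rng.random() < 0.3:
            uri = resolve_type_uri(label, doc.namespaces)
        a = Annotation(
            id=fresh_tid(),
            span=_rand_span(rng, bounds, disc),
            type_label=label,
            type_uri=uri,
            features={} if disc else _make_features(rng, cfg, plain_ids),
            layer_id=rng.choice(layer_ids),
        )
        doc.annotations.append(a)
        if not disc:
            plain_ids.append(a.id)

    rel_n = 0
    for aid in list(plain_ids):
        if len(plain_ids) >= 2 and rng.random() < cfg.p_relation:
            target = rng.choice([x for x in plain_ids if x != aid])
            rel_n += 1
            feats = {}
            if rng.random() < 0.3:
                feats["confidence"] = round(rng.random(), 3)
            doc.relations.append(
                RelationEdge(
                    id=f"R{rel_n}",
                    predicate=rng.choice(_PREDICATES),
                    subj=aid,
                    obj_ref=target,
                    features=feats,
                )
            )

    if rng.random() < cfg.p_chain and n_words >= 6:
        chain_type = rng.choice(_CHAIN_TYPES)
        layer = rng.choice(layer_ids)
        m = rng.randint(1, 5)
        labeled_links = rng.random() < 0.5
        elements = []
        for i in range(m):
            span_label = rng.choice(_SPAN_LABELS)
            mention = Annotation(
                id=fresh_tid(),
                span=_rand_span(rng, bounds, False),
                type_label=span_label if span_label is not None else chain_type,
                layer_id=layer,
            )
            doc.annotations.append(mention)
            elements.append(
                ChainElement(
                    mention=mention.id,
                    span_label=span_label,
                    link_label=(
                        rng.choice(_LINK_LABELS) if i > 0 and labeled_links else None
                    ),
                )
            )
        doc.chains.append(
            ChainAnnotation(id="C1", chain_type=chain_type, elements=elements)
        )

    if rng.random() < cfg.p_doc_attribute:
        doc.doc_attributes.append(DocumentAttribute("language", "en"))
        if rng.random() < 0.5:
            doc.doc_attributes.append(
                DocumentAttribute("keywords", FSet([rng.choice(_WORDS), "annotation"]))
            )
        if rng.random() < 0.3:
            doc.doc_attributes.append(
                DocumentAttribute("revision", rng.randint(1, 9))
            )
    return doc


def generate_corpus(config: Optional[GeneratorConfig] = None) -> list:
    """Generate ``config.n_documents`` valid hub documents,
    deterministically under ``config.seed``."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = random.Random(cfg.seed)
    return [generate_document(rng, cfg, i) for i in range(cfg.n_documents)]
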