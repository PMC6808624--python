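"""LIF: JSON-LD interchange documents with ordered, append-only views.

A document carries a text payload and a list of *views*, each produced
by one pipeline component and holding its own metadata (producer,
``contains`` type declarations) and annotation list.  Any string or URI
may specify an annotation type; features may be nested maps, ordered
lists, or unordered sets (encoded here as ``{"@set": [...]}``).

Constructs the view model has no native record for use toolkit
conventions: a relation is an unanchored annotation whose type is the
predicate with reserved ``_subj``/``_obj`` reference features; a chain
is an unanchored annotation whose type is the chain type with an
ordered ``mentions`` reference list (links between chain elements are
not modelled and cannot be labeled).  Discontinuous spans carry their
segments in ``targets`` with envelope ``start``/``end``.

The exact ``@context`` and discriminator spellings are configurable
module constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional

from ..model import (
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
from ..rewrite import ConversionOptions, ConversionError, obj_to_type, type_to_obj
from .pubann import FormatError, REF_MARKER

__all__ = [
    "LifDocument",
    "LifView",
    "LifAnnotation",
    "DEFAULT_CONTEXT",
    "DEFAULT_DISCRIMINATOR",
    "read_lif",
    "write_lif",
    "lift_lif",
    "lower_lif",
]

DEFAULT_CONTEXT = "http://vocab.lappsgrid.org/context-1.0.0.jsonld"
DEFAULT_DISCRIMINATOR = "http://vocab.lappsgrid.org/ns/media/jsonld#lif"

#: reserved metadata keys carrying hub-level document state
_META_SOURCE = "_source_id"
_META_NAMESPACES = "_namespaces"
_META_DOC_ATTRS = "_doc_attributes"

_SUBJ = "_subj"
_OBJ = "_obj"
_MENTIONS = "mentions"


@dataclass
class LifAnnotation:
    id: str
    at_type: str
    start: Optional[int] = None
    end: Optional[int] = None
    targets: Optional[list] = None  # [(begin, end), ...] for discontinuous
    label: Optional[str] = None
    features: dict = field(default_factory=dict)


@dataclass
class LifView:
    id: str
    metadata: dict = field(default_factory=dict)
    annotations: list = field(default_factory=list)


@dataclass
class LifDocument:
    text: str = ""
    language: Optional[str] = None
    metadata: dict = field(default_factory=dict)
    views: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def _encode_feature(v: Any) -> Any:
    if isinstance(v, Ref):
        return REF_MARKER + v.target
    if isinstance(v, FSet):
        return {"@set": [_encode_feature(x) for x in v.items]}
    if isinstance(v, dict):
        return {k: _encode_feature(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_encode_feature(x) for x in v]
    return v


def _decode_feature(v: Any) -> Any:
    if isinstance(v, str) and v.startswith(REF_MARKER):
        return Ref(v[len(REF_MARKER):])
    if isinstance(v, dict):
        if set(v.keys()) == {"@set"}:
            return FSet(_decode_feature(x) for x in v["@set"])
        return {k: _decode_feature(x) for k, x in v.items()}
    if isinstance(v, list):
        return [_decode_feature(x) for x in v]
    return v


def read_lif(data: bytes) -> LifDocument:
    try:
        obj = json.loads(data.decode("utf-8") if isinstance(data, (bytes, bytearray)) else data)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON at byte offset {exc.pos}: {exc.msg}") from exc
    payload = obj.get("payload", obj)
    if "text" not in payload or "@value" not in payload["text"]:
        raise FormatError("LIF document lacks a text payload")
    doc = LifDocument(
        text=payload["text"]["@value"],
        language=payload["text"].get("@language"),
        metadata=payload.get("metadata", {}),
    )
    seen = set()
    for view in payload.get("views", []):
        vid = view["id"]
        if vid in seen:
            raise FormatError(f"duplicate view id {vid!r}")
        seen.add(vid)
        lv = LifView(id=vid, metadata=view.get("metadata", {}))
        ann_ids = set()
        for ann in view.get("annotations", []):
            if ann["id"] in ann_ids:
                raise FormatError(f"duplicate annotation id {ann['id']!r} in view {vid!r}")
            ann_ids.add(ann["id"])
            lv.annotations.append(
                LifAnnotation(
                    id=ann["id"],
                    at_type=ann["@type"],
                    start=ann.get("start"),
                    end=ann.get("end"),
                    targets=[tuple(t) for t in ann["targets"]] if "targets" in ann else None,
                    label=ann.get("label"),
                    features={
                        k: _decode_feature(v)
                        for k, v in ann.get("features", {}).items()
                    },
                )
            )
        doc.views.append(lv)
    return doc


def write_lif(doc: LifDocument) -> bytes:
    text: dict = {"@value": doc.text}
    if doc.language is not None:
        text["@language"] = doc.language
    views = []
    for v in doc.views:
        anns = []
        for a in v.annotations:
            rec: dict = {"id": a.id, "@type": a.at_type}
            if a.label is not None:
                rec["label"] = a.label
            if a.start is not None:
                rec["start"] = a.start
                rec["end"] = a.end
            if a.targets is not None:
                rec["targets"] = [list(t) for t in a.targets]
            if a.features:
                rec["features"] = {
                    k: _encode_feature(val) for k, val in sorted(a.features.items())
                }
            anns.append(rec)
        views.append({"id": v.id, "metadata": v.metadata, "annotations": anns})
    out = {
        "discriminator": DEFAULT_DISCRIMINATOR,
        "payload": {
            "@context": DEFAULT_CONTEXT,
            "metadata": doc.metadata,
            "text": text,
            "views": views,
        },
    }
    return (json.dumps(out, ensure_ascii=False, indent=1, sort_keys=False) + "\n").encode(
        "utf-8"
    )


# ---------------------------------------------------------------------------
# lift / lower
# ---------------------------------------------------------------------------

def lift_lif(lif: LifDocument, opts: Optional[ConversionOptions] = None) -> InteropDocument:
    """Lift to the hub: views become layers (rank = view position),
    relation- and chain-shaped unanchored annotations are rebuilt into
    native relations and chains."""
    opts = opts or ConversionOptions()
    namespaces = dict(lif.metadata.get(_META_NAMESPACES, {}))
    doc = InteropDocument(
        text=lif.text,
        source_id=lif.metadata.get(_META_SOURCE),
        namespaces=namespaces,
    )
    for pred, raw in sorted(lif.metadata.get(_META_DOC_ATTRS, {}).items()):
        doc.doc_attributes.append(
            DocumentAttribute(predicate=pred, value=_decode_feature(raw))
        )

    chain_shaped = []
    for rank, view in enumerate(lif.views):
        doc.layers.append(
            Layer(
                id=view.id,
                producer=view.metadata.get("producer"),
                contains=frozenset(view.metadata.get("contains", {}) or {}),
                rank=rank,
            )
        )
        for ann in view.annotations:
            anchored = ann.start is not None or ann.targets is not None
            if not anchored and _SUBJ in ann.features and _OBJ in ann.features:
                feats = dict(ann.features)
                subj = feats.pop(_SUBJ)
                obj = feats.pop(_OBJ)
                if not isinstance(subj, Ref) or not isinstance(obj, Ref):
                    raise FormatError(
                        f"relation annotation {ann.id!r} endpoints must be references"
                    )
                doc.relations.append(
                    RelationEdge(
                        id=ann.id,
                        predicate=ann.at_type,
                        subj=subj.target,
                        obj_ref=obj.target,
                        features=feats,
                    )
                )
            elif not anchored and _MENTIONS in ann.features:
                chain_shaped.append(ann)
            else:
                if ann.targets is not None:
                    span = TextSpan(tuple(ann.targets))
                else:
                    span = TextSpan.single(ann.start, ann.end)
                label, uri = obj_to_type(ann.at_type, namespaces)
                if ann.label is not None:
                    label = ann.label
                doc.annotations.append(
                    Annotation(
                        id=ann.id,
                        span=span,
                        type_label=label,
                        type_uri=uri,
                        features=dict(ann.features),
                        layer_id=view.id,
                    )
                )

    anns_by_id = doc.annotation_by_id()
    for ann in chain_shaped:
        mentions = ann.features[_MENTIONS]
        if isinstance(mentions, FSet):
            raise FormatError(f"chain {ann.id!r}: mention order is significant")
        elements = []
        for m in mentions:
            if not isinstance(m, Ref) or m.target not in anns_by_id:
                raise FormatError(f"chain {ann.id!r}: bad mention {m!r}")
            elements.append(
                ChainElement(
                    mention=m.target,
                    span_label=anns_by_id[m.target].type_label,
                    link_label=None,  # links cannot be labeled in this format
                )
            )
        label, _ = obj_to_type(ann.at_type, namespaces)
        doc.chains.append(
            ChainAnnotation(id=ann.id, chain_type=label, elements=elements)
        )
    doc.ensure_default_layer()
    return doc


def lower_lif(doc: InteropDocument, opts: Optional[ConversionOptions] = None) -> LifDocument:
    """Lower a hub document: layers become views in rank order; each
    relation is written into its subject's view, each chain into its
    first mention's view.  Chain link labels are not expressible and are
    dropped here (the fidelity layer predicts and reports this)."""
    opts = opts or ConversionOptions()
    lif = LifDocument(text=doc.text)
    if doc.source_id is not None:
        lif.metadata[_META_SOURCE] = doc.source_id
    if doc.namespaces:
        lif.metadata[_META_NAMESPACES] = dict(sorted(doc.namespaces.items()))
    if doc.doc_attributes:
        lif.metadata[_META_DOC_ATTRS] = {
            da.predicate: _encode_feature_raw(da.value)
            for da in sorted(doc.doc_attributes, key=lambda d: d.predicate)
        }

    idmap = {a.id: f"a{i}" for i, a in enumerate(doc.annotations, start=1)}
    layers = sorted(doc.layers, key=lambda l: l.rank) if doc.layers else [Layer(id="l0")]
    views = {l.id: LifView(id=l.id) for l in layers}
    for l in layers:
        md: dict = {}
        if l.producer is not None:
            md["producer"] = l.producer
        contains = sorted(
            {a.type_label for a in doc.annotations if a.layer_id == l.id}
        )
        if contains:
            md["contains"] = {t: {} for t in contains}
        views[l.id].metadata = md

    def encode_feats(features: dict) -> dict:
        return {k: _map_refs(v, idmap) for k, v in features.items()}

    for a in doc.annotations:
        rec = LifAnnotation(
            id=idmap[a.id],
            at_type=type_to_obj(a, doc.namespaces),
            features=encode_feats(a.features),
        )
        if a.span.discontinuous:
            rec.start, rec.end = a.span.begin, a.span.end
            rec.targets = list(a.span.segments)
        else:
            rec.start, rec.end = a.span.begin, a.span.end
        views[a.layer_id].annotations.append(rec)

    fallback_view = layers[0].id
    for i, r in enumerate(doc.relations, start=1):
        rid = f"r{i}"
        feats = encode_feats(r.features)
        feats[_SUBJ] = Ref(idmap[r.subj])
        feats[_OBJ] = Ref(idmap[r.obj_ref])
        host = doc.annotation_by_id()[r.subj].layer_id
        views.get(host, views[fallback_view]).annotations.append(
            LifAnnotation(id=rid, at_type=r.predicate, features=feats)
        )
    anns_by_id = doc.annotation_by_id()
    for i, c in enumerate(doc.chains, start=1):
        cid = f"c{i}"
        feats = {_MENTIONS: [Ref(idmap[el.mention]) for el in c.elements]}
        host = anns_by_id[c.elements[0].mention].layer_id if c.elements else fallback_view
        views.get(host, views[fallback_view]).annotations.append(
            LifAnnotation(id=cid, at_type=c.chain_type, features=feats)
        )

    lif.views = [views[l.id] for l in layers]
    return lif


def _map_refs(v: Any, idmap: dict) -> Any:
    if isinstance(v, Ref):
        return Ref(idmap.get(v.target, v.target))
    if isinstance(v, dict):
        return {k: _map_refs(x, idmap) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_map_refs(x, idmap) for x in v]
    if isinstance(v, FSet):
        return FSet(_map_refs(x, idmap) for x in v.items)
    return v


def _encode_feature_raw(v: Any) -> Any:
    return _encode_feature(v)
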