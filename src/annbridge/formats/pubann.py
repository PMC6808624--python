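"""PubAnnotation JSON: schemaless triples over canonical text.

A document is text plus three record kinds — *denotations* connecting a
span (or a set of spans, for discontinuous mentions) to an object,
*relations* (typed, directed, binary edges between denotations), and
*attributes* (subject/predicate/object assertions adding information to
a denotation, a relation, or the document itself, whose subject is the
reserved marker ``"_doc"``).  An optional ``namespaces`` table makes
short object tags resolvable to schema URIs.

Multi-valued information uses set semantics: the same (subject,
predicate) pair may occur in several attributes with different objects.
Nested feature sets use the dotted-name convention (``author.first``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional

from ..model import (
    Annotation,
    DEFAULT_LAYER_ID,
    DOC_SUBJECT,
    DocumentAttribute,
    FSet,
    InteropDocument,
    Layer,
    Ref,
    RelationEdge,
    RESERVED_PREFIX,
    TextSpan,
)
from ..rewrite import (
    ConversionOptions,
    ConversionError,
    flatten_features,
    obj_to_type,
    type_to_obj,
    unflatten_features,
)

__all__ = [
    "PubAnnDocument",
    "Denotation",
    "PubAnnRelation",
    "PubAnnAttribute",
    "FormatError",
    "read_pubann",
    "write_pubann",
    "lift_pubann",
    "lower_pubann",
]

#: String prefix marking an annotation-id reference in an attribute obj.
REF_MARKER = "_ref:"


class FormatError(ValueError):
    """Structural problem in a serialized document."""


@dataclass
class Denotation:
    id: str
    span: TextSpan
    obj: str
    #: whether the span was serialized as a single object rather than a list
    single_arity: bool = True


@dataclass
class PubAnnRelation:
    id: str
    pred: str
    subj: str
    obj: str


@dataclass
class PubAnnAttribute:
    id: str
    subj: str
    pred: str
    obj: Any


@dataclass
class PubAnnDocument:
    text: str = ""
    sourcedb: Optional[str] = None
    sourceid: Optional[str] = None
    project: Optional[str] = None
    denotations: list = field(default_factory=list)
    relations: list = field(default_factory=list)
    attributes: list = field(default_factory=list)
    namespaces: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def _parse_span(raw: Any, did: str) -> tuple:
    if isinstance(raw, dict):
        return TextSpan.single(raw["begin"], raw["end"]), True
    if isinstance(raw, list) and raw:
        return TextSpan(tuple((s["begin"], s["end"]) for s in raw)), False
    raise FormatError(f"denotation {did!r}: malformed span {raw!r}")


def _check_user_name(name: str, where: str, allowed: frozenset) -> None:
    if name.startswith(RESERVED_PREFIX) and name not in allowed:
        raise FormatError(
            f"{where}: name {name!r} uses the reserved '_' prefix, "
            "which is limited to toolkit-internal conventions"
        )


def read_pubann(data: bytes, opts: Optional[ConversionOptions] = None) -> PubAnnDocument:
    """Parse PubAnnotation JSON.  Accepts documents lacking the optional
    keys (schemaless model); rejects dangling references and user names
    beginning with the reserved underscore prefix."""
    opts = opts or ConversionOptions()
    try:
        obj = json.loads(data.decode("utf-8") if isinstance(data, (bytes, bytearray)) else data)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON at byte offset {exc.pos}: {exc.msg}") from exc
    if not isinstance(obj, dict) or "text" not in obj:
        raise FormatError("PubAnnotation document must be an object with a 'text' key")

    doc = PubAnnDocument(
        text=obj["text"],
        sourcedb=obj.get("sourcedb"),
        sourceid=obj.get("sourceid"),
        project=obj.get("project"),
    )
    for ns in obj.get("namespaces", []):
        doc.namespaces[ns["prefix"]] = ns["uri"]

    reserved_attr = opts.reserved_names()
    reserved_rel = frozenset({opts.chain_link_predicate})

    for d in obj.get("denotations", []):
        span, single = _parse_span(d["span"], d.get("id", "?"))
        _check_user_name(d["obj"], f"denotation {d['id']!r} obj", frozenset())
        doc.denotations.append(
            Denotation(id=d["id"], span=span, obj=d["obj"], single_arity=single)
        )
    den_ids = {d.id for d in doc.denotations}

    dangling = []
    for r in obj.get("relations", []):
        _check_user_name(r["pred"], f"relation {r['id']!r} pred", reserved_rel)
        for endpoint in (r["subj"], r["obj"]):
            if endpoint not in den_ids:
                dangling.append(endpoint)
        doc.relations.append(
            PubAnnRelation(id=r["id"], pred=r["pred"], subj=r["subj"], obj=r["obj"])
        )
    rel_ids = {r.id for r in doc.relations}

    for a in obj.get("attributes", []):
        subj = a.get("subj", DOC_SUBJECT)
        _check_user_name(a["pred"], f"attribute {a['id']!r} pred", reserved_attr)
        if isinstance(a["obj"], str) and a["obj"].startswith(RESERVED_PREFIX):
            if not a["obj"].startswith(REF_MARKER):
                raise FormatError(
                    f"attribute {a['id']!r}: value {a['obj']!r} uses the reserved prefix"
                )
        if subj != DOC_SUBJECT and subj not in den_ids and subj not in rel_ids:
            dangling.append(subj)
        doc.attributes.append(
            PubAnnAttribute(id=a["id"], subj=subj, pred=a["pred"], obj=a["obj"])
        )

    if dangling:
        raise FormatError(f"dangling references: {sorted(set(dangling))}")
    return doc


def write_pubann(doc: PubAnnDocument) -> bytes:
    """Serialize deterministically (stable key order and id order), so
    writing the same document twice is byte-identical."""
    out: dict = {"text": doc.text}
    if doc.sourcedb is not None:
        out["sourcedb"] = doc.sourcedb
    if doc.sourceid is not None:
        out["sourceid"] = doc.sourceid
    if doc.project is not None:
        out["project"] = doc.project
    if doc.namespaces:
        out["namespaces"] = [
            {"prefix": p, "uri": u} for p, u in sorted(doc.namespaces.items())
        ]
    if doc.denotations:
        out["denotations"] = [
            {
                "id": d.id,
                "span": (
                    {"begin": d.span.begin, "end": d.span.end}
                    if d.single_arity and not d.span.discontinuous
                    else [{"begin": b, "end": e} for b, e in d.span.segments]
                ),
                "obj": d.obj,
            }
            for d in doc.denotations
        ]
    if doc.relations:
        out["relations"] = [
            {"id": r.id, "pred": r.pred, "subj": r.subj, "obj": r.obj}
            for r in doc.relations
        ]
    if doc.attributes:
        out["attributes"] = [
            {"id": a.id, "subj": a.subj, "pred": a.pred, "obj": a.obj}
            for a in doc.attributes
        ]
    return (json.dumps(out, ensure_ascii=False, indent=1) + "\n").encode("utf-8")


# ---------------------------------------------------------------------------
# lift / lower
# ---------------------------------------------------------------------------

def _decode_value(v: Any) -> Any:
    if isinstance(v, str) and v.startswith(REF_MARKER):
        return Ref(v[len(REF_MARKER):])
    return v


def _encode_value(v: Any, idmap: dict) -> Any:
    if isinstance(v, Ref):
        return REF_MARKER + idmap.get(v.target, v.target)
    if isinstance(v, bool) or isinstance(v, (int, float, str)):
        return v
    raise ConversionError(f"value {v!r} is not attribute-encodable")


def lift_pubann(
    pub: PubAnnDocument, opts: Optional[ConversionOptions] = None
) -> InteropDocument:
    """Lift to the hub model.  Attributes become features (dotted names
    rebuilt into nested maps, repeated predicates into unordered sets);
    document-subject attributes become document attributes; denotation
    objects split into a short type tag and an optional resolvable URI
    via the namespace table.  Reserved provenance/chain attributes are
    kept as flat features for the later expand/decode rewrites."""
    opts = opts or ConversionOptions()
    doc = InteropDocument(
        text=pub.text,
        source_id=pub.sourceid,
        namespaces=dict(pub.namespaces),
        layers=[Layer(id=DEFAULT_LAYER_ID, rank=0)],
    )

    reserved = opts.reserved_names()
    by_subj: dict = {}
    for a in pub.attributes:
        by_subj.setdefault(a.subj, []).append((a.pred, _decode_value(a.obj)))

    def build_features(subj: str) -> dict:
        pairs = by_subj.get(subj, [])
        flat_reserved = [(p, v) for p, v in pairs if p in reserved]
        user = [(p, v) for p, v in pairs if p not in reserved]
        feats = unflatten_features(user)
        for p, v in flat_reserved:
            feats[p] = v
        return feats

    for d in pub.denotations:
        label, uri = obj_to_type(d.obj, pub.namespaces)
        doc.annotations.append(
            Annotation(
                id=d.id,
                span=d.span,
                type_label=label,
                type_uri=uri,
                features=build_features(d.id),
                layer_id=DEFAULT_LAYER_ID,
            )
        )
    for r in pub.relations:
        doc.relations.append(
            RelationEdge(
                id=r.id,
                predicate=r.pred,
                subj=r.subj,
                obj_ref=r.obj,
                features=build_features(r.id),
            )
        )
    for pred, value in sorted(build_features(DOC_SUBJECT).items()):
        doc.doc_attributes.append(DocumentAttribute(predicate=pred, value=value))
    return doc


def lower_pubann(
    doc: InteropDocument, opts: Optional[ConversionOptions] = None
) -> PubAnnDocument:
    """Lower a hub document (chains already encoded, views already
    collapsed) to the PubAnnotation shape: features flatten into dotted,
    possibly repeated attributes; annotation types become denotation
    objects (a resolvable URI when known).  Ids are renumbered
    T1../R1../A1.. in document order."""
    opts = opts or ConversionOptions()
    if doc.chains:
        raise ConversionError("chains must be encoded before lowering to PubAnnotation")
    if len(doc.layers) > 1:
        raise ConversionError("views must be collapsed before lowering to PubAnnotation")

    pub = PubAnnDocument(
        text=doc.text,
        sourceid=doc.source_id,
        namespaces=dict(doc.namespaces),
    )
    idmap: dict = {}
    for i, a in enumerate(doc.annotations, start=1):
        idmap[a.id] = f"T{i}"
    for i, r in enumerate(doc.relations, start=1):
        idmap[r.id] = f"R{i}"

    attr_n = [0]

    def emit_attrs(subj: str, features: dict) -> None:
        for name, value in flatten_features(features, strict=opts.strict):
            attr_n[0] += 1
            pub.attributes.append(
                PubAnnAttribute(
                    id=f"A{attr_n[0]}",
                    subj=subj,
                    pred=name,
                    obj=_encode_value(value, idmap),
                )
            )

    for a in doc.annotations:
        pub.denotations.append(
            Denotation(
                id=idmap[a.id],
                span=a.span,
                obj=type_to_obj(a, doc.namespaces),
                single_arity=not a.span.discontinuous,
            )
        )
        emit_attrs(idmap[a.id], a.features)
    for r in doc.relations:
        pub.relations.append(
            PubAnnRelation(
                id=idmap[r.id],
                pred=r.predicate,
                subj=idmap[r.subj],
                obj=idmap[r.obj_ref],
            )
        )
        emit_attrs(idmap[r.id], r.features)
    for da in doc.doc_attributes:
        emit_attrs(DOC_SUBJECT, {da.predicate: da.value})
    return pub
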