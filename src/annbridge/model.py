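"""Format-neutral document model for standoff text annotation.

Three annotation platforms — a schemaless JSON repository (PubAnnotation),
a JSON-LD pipeline interchange format with append-only views (LIF), and a
UIMA-CAS-based editor format (XMI) — share a common conceptual core: text,
span annotations, typed binary relations, linked chains, and attribute
data attached to annotations or to the document itself.  This module
defines that core as :class:`InteropDocument`, the hub every converter
passes through, together with its validity rules and a canonical form
under which two documents are compared *semantically*, i.e. modulo
annotation identifiers and serialization details.

Offsets are 0-based half-open character (code point) offsets into the
document text.  The text itself is never normalized, trimmed or
re-encoded: any whitespace difference is a semantic difference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Optional, Union

__all__ = [
    "TextSpan",
    "Ref",
    "FSet",
    "FeatureValue",
    "Annotation",
    "RelationEdge",
    "ChainElement",
    "ChainAnnotation",
    "Layer",
    "DocumentAttribute",
    "InteropDocument",
    "Violation",
    "validate_document",
    "resolve_type_uri",
    "reverse_resolve_type_uri",
    "semantic_key",
    "DEFAULT_LAYER_ID",
    "DOC_SUBJECT",
    "RESERVED_PREFIX",
]

#: Marker used as the attribute subject when the subject is the document.
DOC_SUBJECT = "_doc"

#: Names beginning with this prefix are reserved for toolkit conventions
#: (chain links, provenance, references); user data may not use them.
RESERVED_PREFIX = "_"

#: Layer id used when a format has no native grouping (PubAnnotation
#: collections, CAS documents collapse to a single layer of this name).
DEFAULT_LAYER_ID = "l0"

_ABSOLUTE_URI = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*:(//|[^/])")


@dataclass(frozen=True)
class TextSpan:
    """An anchor over the text: one segment, or several for a
    discontinuous span.  Segments are (begin, end) pairs, 0-based
    half-open, sorted and non-overlapping."""

    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("TextSpan requires at least one segment")
        object.__setattr__(
            self, "segments", tuple((int(b), int(e)) for b, e in self.segments)
        )

    @classmethod
    def single(cls, begin: int, end: int) -> "TextSpan":
        return cls(((begin, end),))

    @property
    def discontinuous(self) -> bool:
        return len(self.segments) > 1

    @property
    def begin(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    def covered_text(self, text: str) -> str:
        return "".join(text[b:e] for b, e in self.segments)


@dataclass(frozen=True)
class Ref:
    """A feature value referencing another annotation by id."""

    target: str


@dataclass(frozen=True)
class FSet:
    """An unordered multi-valued feature value (set semantics)."""

    items: tuple

    def __init__(self, items: Iterable[Any]):
        object.__setattr__(self, "items", tuple(items))


# A feature value is a primitive, a reference, a nested map, an ordered
# list, or an unordered set.  (Type alias for documentation purposes.)
FeatureValue = Union[str, int, float, bool, Ref, dict, list, FSet]


@dataclass
class Annotation:
    """A text-anchored annotation: PubAnnotation denotation, LIF
    annotation, or CAS feature structure descending from Annotation."""

    id: str
    span: TextSpan
    type_label: str
    type_uri: Optional[str] = None
    features: dict = field(default_factory=dict)
    layer_id: str = DEFAULT_LAYER_ID


@dataclass
class RelationEdge:
    """A typed, directed, binary relation between two annotations."""

    id: str
    predicate: str
    subj: str
    obj_ref: str
    features: dict = field(default_factory=dict)


@dataclass
class ChainElement:
    mention: str
    span_label: Optional[str] = None
    link_label: Optional[str] = None


@dataclass
class ChainAnnotation:
    """An ordered linked sequence of mention annotations (e.g. a
    coreference chain); spans and links may carry labels."""

    id: str
    chain_type: str
    elements: list = field(default_factory=list)


@dataclass
class Layer:
    """A grouping of annotations by producer — a LIF view.  PubAnnotation
    and CAS have no native equivalent; converters encode/drop it."""

    id: str
    producer: Optional[str] = None
    contains: frozenset = frozenset()
    rank: int = 0


@dataclass
class DocumentAttribute:
    """An attribute whose subject is the document itself."""

    predicate: str
    value: Any = None


@dataclass
class InteropDocument:
    """The conversion hub: text plus every construct the three formats
    share or encode by convention."""

    text: str = ""
    source_id: Optional[str] = None
    layers: list = field(default_factory=list)
    annotations: list = field(default_factory=list)
    relations: list = field(default_factory=list)
    chains: list = field(default_factory=list)
    doc_attributes: list = field(default_factory=list)
    namespaces: dict = field(default_factory=dict)

    # -- convenience lookups -------------------------------------------
    def annotation_by_id(self) -> dict:
        return {a.id: a for a in self.annotations}

    def layer_by_id(self) -> dict:
        return {l.id: l for l in self.layers}

    def all_ids(self) -> Iterator[str]:
        for a in self.annotations:
            yield a.id
        for r in self.relations:
            yield r.id
        for c in self.chains:
            yield c.id

    def ensure_default_layer(self) -> None:
        if not self.layers:
            self.layers.append(Layer(id=DEFAULT_LAYER_ID, rank=0))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    code: str
    ref: str
    message: str


def _iter_feature_refs(value: Any) -> Iterator[str]:
    if isinstance(value, Ref):
        yield value.target
    elif isinstance(value, dict):
        for v in value.values():
            yield from _iter_feature_refs(v)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _iter_feature_refs(v)
    elif isinstance(value, FSet):
        for v in value.items:
            yield from _iter_feature_refs(v)


def validate_document(doc: InteropDocument) -> list:
    """Check every model invariant; violations are returned as data,
    never raised.  An empty list means the document is valid."""
    out: list[Violation] = []
    n = len(doc.text)

    layer_ids = set()
    prev_rank = None
    for layer in doc.layers:
        if layer.id in layer_ids:
            out.append(Violation("layer.duplicate-id", layer.id, "duplicate layer id"))
        layer_ids.add(layer.id)
        if prev_rank is not None and layer.rank <= prev_rank:
            out.append(
                Violation(
                    "layer.rank-order",
                    layer.id,
                    "layer ranks must strictly increase with creation order",
                )
            )
        prev_rank = layer.rank

    seen_ids: set[str] = set()
    for oid in doc.all_ids():
        if oid in seen_ids:
            out.append(Violation("id.duplicate", oid, "duplicate id"))
        seen_ids.add(oid)

    ann_ids = {a.id for a in doc.annotations}

    for a in doc.annotations:
        prev_end = None
        for b, e in a.span.segments:
            if not (0 <= b <= e <= n):
                out.append(
                    Violation(
                        "span.bounds",
                        a.id,
                        f"segment ({b},{e}) outside text of length {n}",
                    )
                )
            if prev_end is not None and b < prev_end:
                out.append(
                    Violation(
                        "span.order",
                        a.id,
                        "segments must be sorted and non-overlapping",
                    )
                )
            prev_end = e
        if a.layer_id not in layer_ids:
            out.append(
                Violation("layer.dangling", a.id, f"unknown layer {a.layer_id!r}")
            )
        if a.type_uri is not None and not _ABSOLUTE_URI.match(a.type_uri):
            out.append(
                Violation("type.uri", a.id, f"type_uri {a.type_uri!r} is not absolute")
            )
        for tgt in _iter_feature_refs(a.features):
            if tgt not in ann_ids:
                out.append(
                    Violation("ref.dangling", a.id, f"feature references unknown id {tgt!r}")
                )

    for r in doc.relations:
        for endpoint in (r.subj, r.obj_ref):
            if endpoint not in ann_ids:
                out.append(
                    Violation("ref.dangling", r.id, f"relation endpoint {endpoint!r} unknown")
                )
        for tgt in _iter_feature_refs(r.features):
            if tgt not in ann_ids:
                out.append(
                    Violation("ref.dangling", r.id, f"feature references unknown id {tgt!r}")
                )

    for c in doc.chains:
        if not c.elements:
            out.append(Violation("chain.empty", c.id, "chain has no elements"))
        for el in c.elements:
            if el.mention not in ann_ids:
                out.append(
                    Violation("ref.dangling", c.id, f"chain mention {el.mention!r} unknown")
                )

    for da in doc.doc_attributes:
        for tgt in _iter_feature_refs(da.value):
            if tgt not in ann_ids:
                out.append(
                    Violation(
                        "ref.dangling",
                        DOC_SUBJECT,
                        f"document attribute {da.predicate!r} references unknown id {tgt!r}",
                    )
                )

    return out


# ---------------------------------------------------------------------------
# Type label <-> URI resolution (strictly lexical; never touches the network)
# ---------------------------------------------------------------------------

#: Returned by :func:`resolve_type_uri` when no rule applies.
UNRESOLVED = None


def resolve_type_uri(label: str, namespaces: dict) -> Optional[str]:
    """Resolve a short type tag to an absolute URI using a namespace map.

    Resolution is purely lexical: an absolute URI passes through; a
    ``prefix:rest`` label concatenates the prefix's base; otherwise the
    default base (key ``"_base"``) is prepended.  No case folding is
    performed and nothing is dereferenced.  Returns ``None`` when no
    rule applies.
    """
    if not label:
        raise ValueError("label must be non-empty")
    if _ABSOLUTE_URI.match(label) and "://" in label:
        return label
    if ":" in label:
        prefix, rest = label.split(":", 1)
        base = namespaces.get(prefix)
        if base is not None:
            return base + rest
    base = namespaces.get("_base")
    if base is not None and ":" not in label:
        return base + label
    return UNRESOLVED


def reverse_resolve_type_uri(uri: str, namespaces: dict) -> Optional[str]:
    """Invert :func:`resolve_type_uri`: recover the short tag a URI was
    built from, preferring the longest matching base.  Returns ``None``
    when no namespace entry matches."""
    candidates = []
    for prefix, base in namespaces.items():
        if base and uri.startswith(base) and len(uri) > len(base):
            rest = uri[len(base):]
            label = rest if prefix == "_base" else f"{prefix}:{rest}"
            candidates.append((len(base), prefix != "_base", label))
    if not candidates:
        return None
    # longest base wins; the default base wins ties
    candidates.sort(key=lambda t: (-t[0], t[1]))
    return candidates[0][2]


# ---------------------------------------------------------------------------
# Canonical (semantic) form
# ---------------------------------------------------------------------------

def _sort_key(frozen: Any) -> str:
    return repr(frozen)


def freeze_value(value: Any, resolve) -> Any:
    """Canonicalize a feature value into nested hashable tuples.

    ``resolve`` maps an annotation id to its local structural key so that
    references compare by *what* they point at, not by id.  Two
    documented normalizations keep the three formats' encodings
    comparable: an unordered set compares sorted by canonical key, and a
    singleton set equals its single element (the repeated-attribute
    encoding cannot distinguish them).
    """
    if isinstance(value, bool):
        return ("b", value)
    if isinstance(value, int):
        return ("n", float(value))
    if isinstance(value, float):
        return ("n", value)
    if isinstance(value, str):
        return ("s", value)
    if value is None:
        return ("z",)
    if isinstance(value, Ref):
        return ("ref", resolve(value.target))
    if isinstance(value, dict):
        return (
            "m",
            tuple(sorted(((k, freeze_value(v, resolve)) for k, v in value.items()))),
        )
    if isinstance(value, (list, tuple)):
        return ("l", tuple(freeze_value(v, resolve) for v in value))
    if isinstance(value, FSet):
        items = [freeze_value(v, resolve) for v in value.items]
        if len(items) == 1:
            return items[0]
        return ("st", tuple(sorted(items, key=_sort_key)))
    raise TypeError(f"unsupported feature value {value!r}")


def _freeze_features(features: dict, resolve) -> tuple:
    return tuple(sorted((k, freeze_value(v, resolve)) for k, v in features.items()))


def semantic_key(doc: InteropDocument) -> tuple:
    """Canonical form of a document: identical for two documents iff they
    are semantically equal (equal modulo ids and serialization).

    Annotations are keyed by (layer, span, type, features); references
    resolve to the target's local key; multisets are kept (two identical
    annotations with different ids stay two entries).  Raises
    ``ValueError`` on a non-validating document.
    """
    violations = validate_document(doc)
    if violations:
        raise ValueError(f"document does not validate: {violations[:3]}")

    anns = doc.annotation_by_id()
    layer_rank_pos = {
        l.id: pos for pos, l in enumerate(sorted(doc.layers, key=lambda l: l.rank))
    }

    def local(aid: str) -> tuple:
        a = anns[aid]
        return ("@", a.span.segments, a.type_label, a.type_uri)

    ann_keys = sorted(
        (
            (
                "a",
                layer_rank_pos[a.layer_id],
                a.layer_id,
                a.span.segments,
                a.type_label,
                a.type_uri,
                _freeze_features(a.features, local),
            )
            for a in doc.annotations
        ),
        key=_sort_key,
    )
    rel_keys = sorted(
        (
            ("r", r.predicate, local(r.subj), local(r.obj_ref), _freeze_features(r.features, local))
            for r in doc.relations
        ),
        key=_sort_key,
    )
    chain_keys = sorted(
        (
            (
                "c",
                c.chain_type,
                tuple(
                    (
                        local(el.mention),
                        el.span_label if el.span_label is not None else c.chain_type,
                        el.link_label,
                    )
                    for el in c.elements
                ),
            )
            for c in doc.chains
        ),
        key=_sort_key,
    )
    da_keys = sorted(
        (("d", da.predicate, freeze_value(da.value, local)) for da in doc.doc_attributes),
        key=_sort_key,
    )
    layer_keys = tuple(
        (pos, l.id, l.producer)
        for pos, l in enumerate(sorted(doc.layers, key=lambda l: l.rank))
    )
    ns_key = tuple(sorted(doc.namespaces.items()))
    return (
        "doc",
        doc.text,
        doc.source_id,
        layer_keys,
        tuple(ann_keys),
        tuple(rel_keys),
        tuple(chain_keys),
        tuple(da_keys),
        ns_key,
    )
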