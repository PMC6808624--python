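"""Hub-level rewrites implementing the conversion conventions.

Each convention bridges a structural mismatch between the three
platforms' annotation models:

* **Chain codec** — chains (linked lists of labeled spans) have no
  dedicated construct in the repository model, but can be represented by
  denotations sequentially connected by relations.  The chain type is
  kept in a reserved ``_chain`` attribute on the first mention; each
  link is a ``_next`` relation whose optional ``_link`` attribute holds
  the link label.
* **Feature flattening** — the repository model has no nested feature
  sets; nested maps are flattened into dotted attribute names
  (``author.first``) and multi-valued features into repeated attributes
  with set semantics.
* **View collapse/expand** — LIF views become one flat collection, with
  the original view id and producer retained in reserved ``_view`` /
  ``_producer`` attributes so the views can be restored on the way back.
* **Latest-view rule** — the CAS editor model keeps one annotation
  collection per type; when several views carry the same type, only the
  highest-ranked view's occurrences survive.
* **Renamer tables** — table-driven type/feature renaming between
  vocabularies (e.g. the interchange vocabulary's four basic types and
  their editor-side counterparts).
* **type_to_obj / obj_to_type** — a schemaless denotation stores its
  type as the ``obj`` string, either a resolvable URI or a short tag
  made resolvable through the document's namespace map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .model import (
    Annotation,
    ChainAnnotation,
    ChainElement,
    DEFAULT_LAYER_ID,
    FSet,
    InteropDocument,
    Layer,
    Ref,
    RelationEdge,
    resolve_type_uri,
    reverse_resolve_type_uri,
)

__all__ = [
    "ConversionOptions",
    "RenamerTable",
    "RenamerEntry",
    "ConversionError",
    "encode_chains",
    "decode_chains",
    "flatten_features",
    "unflatten_features",
    "collapse_views",
    "expand_views",
    "select_latest_views",
    "apply_renamer",
    "invert_renamer",
    "wsev_dkpro_renamer",
    "type_to_obj",
    "obj_to_type",
]


class ConversionError(ValueError):
    """A construct cannot be converted under the active options."""


@dataclass(frozen=True)
class RenamerEntry:
    source_type: str
    target_type: str
    feature_map: tuple = ()  # tuple of (source_feature, target_feature)


@dataclass(frozen=True)
class RenamerTable:
    entries: tuple = ()

    def __post_init__(self):
        sources = [e.source_type for e in self.entries]
        if len(set(sources)) != len(sources):
            raise ConversionError("renamer entries must have distinct source types")
        for e in self.entries:
            targets = [t for _, t in e.feature_map]
            if len(set(targets)) != len(targets):
                raise ConversionError(
                    f"feature map for {e.source_type!r} is not injective"
                )

    def lookup(self, type_label: str) -> Optional[RenamerEntry]:
        for e in self.entries:
            if e.source_type == type_label:
                return e
        return None


@dataclass
class ConversionOptions:
    """Tunable conventions for a conversion run.  Reserved predicate
    names start with an underscore so they can never collide with user
    vocabulary (user data using the prefix is rejected at read time)."""

    chain_link_predicate: str = "_next"
    chain_type_predicate: str = "_chain"
    link_label_predicate: str = "_link"
    provenance_predicate: str = "_view"
    producer_predicate: str = "_producer"
    latest_view_only: bool = True
    renamer: Optional[RenamerTable] = None
    strict: bool = True

    def reserved_names(self) -> frozenset:
        return frozenset(
            {
                self.chain_link_predicate,
                self.chain_type_predicate,
                self.link_label_predicate,
                self.provenance_predicate,
                self.producer_predicate,
            }
        )


# ---------------------------------------------------------------------------
# Chain codec
# ---------------------------------------------------------------------------

def encode_chain(
    chain: ChainAnnotation,
    mentions: dict,
    opts: ConversionOptions,
    next_rel_id,
) -> tuple:
    """Encode one chain as denotation-style annotations plus sequential
    link relations.

    Returns ``(annotations, relations)``: one annotation per mention
    whose type is the element's span label (or the chain type when
    unlabeled), the first carrying the reserved chain-type attribute,
    plus exactly ``n - 1`` link relations in mention order.
    """
    out_anns = []
    out_rels = []
    for i, el in enumerate(chain.elements):
        m = mentions[el.mention]
        feats = dict(m.features)
        if i == 0:
            feats[opts.chain_type_predicate] = chain.chain_type
        out_anns.append(
            replace(
                m,
                type_label=el.span_label if el.span_label is not None else chain.chain_type,
                features=feats,
            )
        )
    for i in range(len(chain.elements) - 1):
        feats = {}
        link_label = chain.elements[i + 1].link_label
        # the label of the link *into* element i+1 rides on relation i
        if link_label is not None:
            feats[opts.link_label_predicate] = link_label
        out_rels.append(
            RelationEdge(
                id=next_rel_id(),
                predicate=opts.chain_link_predicate,
                subj=chain.elements[i].mention,
                obj_ref=chain.elements[i + 1].mention,
                features=feats,
            )
        )
    return out_anns, out_rels


def encode_chains(doc: InteropDocument, opts: ConversionOptions) -> InteropDocument:
    """Rewrite every chain into denotations + link relations (in place on
    a shallow copy).  First-element link labels are undefined by the
    model (a link label labels the link *into* its element), so element
    0's ``link_label`` is required to be ``None``."""
    if not doc.chains:
        return doc
    mentions = doc.annotation_by_id()
    counter = [0]
    existing = set(doc.all_ids())

    def next_rel_id() -> str:
        while True:
            counter[0] += 1
            rid = f"RL{counter[0]}"
            if rid not in existing:
                existing.add(rid)
                return rid

    ann_by_id = {a.id: a for a in doc.annotations}
    new_rels = list(doc.relations)
    for chain in doc.chains:
        anns, rels = encode_chain(chain, mentions, opts, next_rel_id)
        for a in anns:
            ann_by_id[a.id] = a
        new_rels.extend(rels)
    return replace(
        doc,
        annotations=[ann_by_id[a.id] for a in doc.annotations],
        relations=new_rels,
        chains=[],
    )


def decode_chains(doc: InteropDocument, opts: ConversionOptions) -> InteropDocument:
    """Inverse of :func:`encode_chains`: every maximal path of link
    relations (in-degree and out-degree at most 1 under the link
    predicate) rooted at an annotation carrying the chain-type attribute
    becomes one chain in path order.  Consumed relations and reserved
    attributes are removed.

    Branching under the link predicate is an error in strict mode; in
    lenient mode the affected relations are left unconverted.
    """
    link_pred = opts.chain_link_predicate
    links = [r for r in doc.relations if r.predicate == link_pred]
    if not links and not any(
        opts.chain_type_predicate in a.features for a in doc.annotations
    ):
        return doc

    out_deg: dict = {}
    in_deg: dict = {}
    succ: dict = {}
    for r in links:
        out_deg[r.subj] = out_deg.get(r.subj, 0) + 1
        in_deg[r.obj_ref] = in_deg.get(r.obj_ref, 0) + 1
        succ[r.subj] = r

    branching = {n for n, d in out_deg.items() if d > 1} | {
        n for n, d in in_deg.items() if d > 1
    }
    if branching:
        if opts.strict:
            raise ConversionError(
                f"chain link predicate {link_pred!r} branches at {sorted(branching)}"
            )
        return doc  # lenient: leave everything unconverted

    anns = doc.annotation_by_id()
    consumed_rels: set = set()
    chains = list(doc.chains)
    new_ann_features: dict = {}
    chain_n = 0

    for a in doc.annotations:
        chain_type = a.features.get(opts.chain_type_predicate)
        if chain_type is None:
            continue
        if in_deg.get(a.id, 0) > 0:
            # chain-start attribute on a non-root node: malformed
            if opts.strict:
                raise ConversionError(
                    f"annotation {a.id} marked as chain start but has an incoming link"
                )
            continue
        elements = []
        node = a.id
        link_label = None
        visited = set()
        while True:
            if node in visited:
                raise ConversionError(f"chain link cycle at {node}")
            visited.add(node)
            ann = anns[node]
            feats = {
                k: v
                for k, v in ann.features.items()
                if k != opts.chain_type_predicate
            }
            new_ann_features[node] = feats
            elements.append(
                ChainElement(
                    mention=node,
                    span_label=ann.type_label,
                    link_label=link_label,
                )
            )
            rel = succ.get(node)
            if rel is None:
                break
            consumed_rels.add(rel.id)
            link_label = rel.features.get(opts.link_label_predicate)
            node = rel.obj_ref
        chain_n += 1
        existing = set(doc.all_ids())
        cid = f"C{chain_n}"
        while cid in existing:
            chain_n += 1
            cid = f"C{chain_n}"
        chains.append(ChainAnnotation(id=cid, chain_type=chain_type, elements=elements))

    if not chains and not consumed_rels:
        return doc
    new_anns = [
        replace(a, features=new_ann_features.get(a.id, a.features))
        for a in doc.annotations
    ]
    new_rels = [r for r in doc.relations if r.id not in consumed_rels]
    return replace(doc, annotations=new_anns, relations=new_rels, chains=chains)


# ---------------------------------------------------------------------------
# Feature flattening (dotted-name convention)
# ---------------------------------------------------------------------------

def flatten_features(features: dict, strict: bool = True) -> list:
    """Flatten a (possibly nested) feature map into ``(dotted_name,
    value)`` pairs suitable for simple subject/predicate/object
    attributes.  Nested maps join path segments with ``"."``; lists and
    sets become repeated pairs under the same name (set semantics).

    Keys containing ``"."`` are ambiguous and rejected in strict mode.
    """
    out = []

    def walk(prefix: str, value) -> None:
        if isinstance(value, dict):
            for k in value:
                if "." in k:
                    if strict:
                        raise ConversionError(
                            f"feature name {k!r} contains '.', which collides with "
                            "the dotted flattening convention"
                        )
                    continue
                walk(f"{prefix}.{k}" if prefix else k, value[k])
        elif isinstance(value, (list, tuple)):
            for v in value:
                walk(prefix, v)
        elif isinstance(value, FSet):
            for v in value.items:
                walk(prefix, v)
        else:
            out.append((prefix, value))

    walk("", features)
    return out


def unflatten_features(pairs: list) -> dict:
    """Invert :func:`flatten_features`: dotted names rebuild nested maps;
    repeated names rebuild unordered sets.  Exact inverse when no key
    contains a dot and multi-valued features have at least two values
    (a singleton set is indistinguishable from a plain value, and the
    canonical form treats them as equal)."""
    grouped: dict = {}
    order: list = []
    for name, value in pairs:
        if name not in grouped:
            grouped[name] = []
            order.append(name)
        grouped[name].append(value)

    root: dict = {}
    for name in order:
        parts = name.split(".")
        node = root
        for p in parts[:-1]:
            nxt = node.get(p)
            if not isinstance(nxt, dict):
                nxt = {}
                node[p] = nxt
            node = nxt
        values = grouped[name]
        node[parts[-1]] = values[0] if len(values) == 1 else FSet(values)
    return root


# ---------------------------------------------------------------------------
# Views
# ---------------------------------------------------------------------------

def collapse_views(doc: InteropDocument, opts: ConversionOptions) -> InteropDocument:
    """Merge all layers into one flat collection, retaining each
    annotation's original view id (and producer, when set) in reserved
    attributes so that :func:`expand_views` can restore the views."""
    doc.ensure_default_layer()
    layer_by_id = doc.layer_by_id()
    # emit in layer-rank order so that expand_views recovers the original
    # view order from first appearance of the provenance values
    rank = {l.id: l.rank for l in doc.layers}
    ordered = sorted(
        enumerate(doc.annotations), key=lambda t: (rank[t[1].layer_id], t[0])
    )
    new_anns = []
    for _, a in ordered:
        feats = dict(a.features)
        feats[opts.provenance_predicate] = a.layer_id
        producer = layer_by_id[a.layer_id].producer
        if producer is not None:
            feats[opts.producer_predicate] = producer
        new_anns.append(replace(a, features=feats, layer_id=DEFAULT_LAYER_ID))
    return replace(
        doc,
        layers=[Layer(id=DEFAULT_LAYER_ID, rank=0)],
        annotations=new_anns,
    )


def expand_views(doc: InteropDocument, opts: ConversionOptions) -> InteropDocument:
    """Restore layers from reserved provenance attributes.  Annotations
    without provenance stay in (or create) the default layer.  View rank
    order follows first appearance order of the view ids, with the
    default layer first."""
    if not any(opts.provenance_predicate in a.features for a in doc.annotations):
        doc.ensure_default_layer()
        return doc

    view_order: list = []
    producers: dict = {}
    new_anns = []
    for a in doc.annotations:
        feats = dict(a.features)
        view_id = feats.pop(opts.provenance_predicate, a.layer_id)
        producer = feats.pop(opts.producer_predicate, None)
        if view_id not in view_order:
            view_order.append(view_id)
        if producer is not None:
            producers[view_id] = producer
        new_anns.append(replace(a, features=feats, layer_id=view_id))

    layers = [
        Layer(id=vid, producer=producers.get(vid), rank=i)
        for i, vid in enumerate(view_order)
    ]
    return replace(doc, layers=layers, annotations=new_anns)


def select_latest_views(doc: InteropDocument, opts: ConversionOptions) -> tuple:
    """Apply the latest-view rule: for every annotation type present in
    more than one layer, keep only the occurrences from the
    highest-ranked layer containing that type.

    Returns ``(document, shadowed)`` where ``shadowed`` lists
    ``(annotation, shadowing_layer_id)`` pairs for the dropped
    occurrences.  A no-op (empty ``shadowed``) when
    ``opts.latest_view_only`` is false.
    """
    if not opts.latest_view_only or len(doc.layers) <= 1:
        return doc, []
    rank = {l.id: l.rank for l in doc.layers}
    latest: dict = {}
    for a in doc.annotations:
        r = rank[a.layer_id]
        key = a.type_label
        if key not in latest or r > rank[latest[key]]:
            latest[key] = a.layer_id
    shadowed = [
        (a, latest[a.type_label])
        for a in doc.annotations
        if a.layer_id != latest[a.type_label]
    ]
    if not shadowed:
        return doc, []
    dropped_ids = {a.id for a, _ in shadowed}
    new_anns = [a for a in doc.annotations if a.id not in dropped_ids]
    new_rels = [
        r
        for r in doc.relations
        if r.subj not in dropped_ids and r.obj_ref not in dropped_ids
    ]
    new_chains = [
        c
        for c in doc.chains
        if not any(el.mention in dropped_ids for el in c.elements)
    ]
    return (
        replace(doc, annotations=new_anns, relations=new_rels, chains=new_chains),
        shadowed,
    )


# ---------------------------------------------------------------------------
# Renamer
# ---------------------------------------------------------------------------

def apply_renamer(doc: InteropDocument, table: RenamerTable) -> InteropDocument:
    """Rename annotation types and their features per the table;
    unmatched annotations pass through unchanged."""
    new_anns = []
    for a in doc.annotations:
        entry = table.lookup(a.type_label)
        if entry is None:
            new_anns.append(a)
            continue
        fmap = dict(entry.feature_map)
        feats = {fmap.get(k, k): v for k, v in a.features.items()}
        new_anns.append(replace(a, type_label=entry.target_type, features=feats))
    return replace(doc, annotations=new_anns)


def invert_renamer(table: RenamerTable) -> RenamerTable:
    return RenamerTable(
        tuple(
            RenamerEntry(
                source_type=e.target_type,
                target_type=e.source_type,
                feature_map=tuple((t, s) for s, t in e.feature_map),
            )
            for e in table.entries
        )
    )


def wsev_dkpro_renamer() -> RenamerTable:
    """The shipped table for the four basic types (tokens, sentences,
    part-of-speech, named entities) whose interchange-vocabulary and
    editor-side type systems correspond one-to-one."""
    seg = "de.tudarmstadt.ukp.dkpro.core.api.segmentation.type"
    return RenamerTable(
        (
            RenamerEntry("Token", f"{seg}.Token"),
            RenamerEntry("Sentence", f"{seg}.Sentence"),
            RenamerEntry(
                "POS",
                "de.tudarmstadt.ukp.dkpro.core.api.lexmorph.type.pos.POS",
                (("pos", "PosValue"),),
            ),
            RenamerEntry(
                "NamedEntity",
                "de.tudarmstadt.ukp.dkpro.core.api.ner.type.NamedEntity",
                (("category", "value"),),
            ),
        )
    )


# ---------------------------------------------------------------------------
# Type <-> obj convention
# ---------------------------------------------------------------------------

def type_to_obj(ann: Annotation, namespaces: dict) -> str:
    """Compute the ``obj`` value of a denotation: the resolvable type URI
    when one is known (preserving interchange-vocabulary links), else the
    short tag, which the document's namespace map may make resolvable."""
    if ann.type_uri is not None:
        return ann.type_uri
    if not ann.type_label:
        raise ConversionError(f"annotation {ann.id} has neither label nor type URI")
    return ann.type_label


def obj_to_type(obj: str, namespaces: dict) -> tuple:
    """Invert :func:`type_to_obj`: returns ``(type_label, type_uri)``.
    An absolute URI is kept as the type URI and reverse-resolved through
    the namespace map to recover the short tag (falling back to the
    URI's local name)."""
    from .model import _ABSOLUTE_URI  # lexical check shared with the model

    if _ABSOLUTE_URI.match(obj) and "://" in obj:
        label = reverse_resolve_type_uri(obj, namespaces)
        if label is None:
            tail = obj.rstrip("/").rsplit("#", 1)[-1].rsplit("/", 1)[-1]
            label = tail or obj
        return label, obj
    return obj, None
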