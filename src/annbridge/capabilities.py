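"""The capability matrix: what each format can and cannot express.

The comparison of the three annotation models is literally a feature
matrix — spans (contiguous/discontinuous), relations, chains and link
labels, nested and multi-valued attributes, views and producers,
document-level metadata, type URIs.  This module encodes that matrix as
data and derives from it:

* :func:`predict_loss` — enumerate every construct of a document that a
  target format cannot express (the closed ``LossEntry`` vocabulary);
* :func:`project` — apply exactly those losses, yielding the document's
  image in the target's expressible subset.

``project`` is what the conversion pipeline performs in lenient mode,
and what the fidelity checks compare against: a round trip passes iff
the source and the returned document agree after projection, i.e. the
actual loss is contained in the predicted loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Optional

from .model import (
    DEFAULT_LAYER_ID,
    DOC_SUBJECT,
    FSet,
    InteropDocument,
    Layer,
    Ref,
)
from .rewrite import ConversionOptions, select_latest_views

__all__ = [
    "LOSS_KINDS",
    "CAPABILITIES",
    "LossEntry",
    "predict_loss",
    "project",
]

LOSS_KINDS = (
    "view_structure",
    "chain_link_label",
    "discontinuous_span",
    "multi_valued_feature",
    "nested_feature",
    "provenance",
    "type_uri",
    "shadowed_by_later_view",
)

#: Per-format expressibility, straight from the model comparison.
#: "views" / "producers": native grouping of annotations by producing
#: component; "ordered_lists": multi-valued features with significant
#: order; "unordered_sets": set-semantics multi-valued features;
#: "nested": nested feature maps; "latest_view_only": the format keeps a
#: single collection per annotation type.
CAPABILITIES = {
    "pubann": {
        "views": True,  # via reserved provenance attributes (non-empty only)
        "empty_views": False,
        "producers": True,
        "discontinuous": True,
        "ordered_lists": False,  # repeated attributes resemble a set
        "unordered_sets": True,
        "nested": True,  # dotted-name convention
        "chain_link_labels": True,  # attribute on the link relation
        "type_uris": True,
        "namespaces": True,
        "latest_view_only": False,
    },
    "lif": {
        "views": True,
        "empty_views": True,
        "producers": True,
        "discontinuous": True,
        "ordered_lists": True,
        "unordered_sets": True,
        "nested": True,
        "chain_link_labels": False,  # links are not modelled
        "type_uris": True,
        "namespaces": True,
        "latest_view_only": False,
    },
    "cas": {
        "views": False,
        "empty_views": False,
        "producers": False,
        "discontinuous": False,
        "ordered_lists": True,  # homogeneous arrays
        "unordered_sets": False,  # arrays are ordered
        "nested": False,  # the XMI subset excludes TOP structures
        "chain_link_labels": True,  # label on the chain link
        "type_uris": False,
        "namespaces": False,
        "latest_view_only": True,
    },
}


@dataclass(frozen=True)
class LossEntry:
    construct_kind: str
    construct_id: str
    direction: tuple  # (from_format_or_hub, to_format)
    detail: str = ""

    def __post_init__(self):
        if self.construct_kind not in LOSS_KINDS:
            raise ValueError(f"unknown construct kind {self.construct_kind!r}")

    def to_json(self) -> dict:
        return {
            "construct_kind": self.construct_kind,
            "construct_id": self.construct_id,
            "direction": list(self.direction),
            "detail": self.detail,
        }


# ---------------------------------------------------------------------------
# feature-value scans
# ---------------------------------------------------------------------------

def _scan_value(value: Any, caps: dict, problems: list, path: str) -> None:
    """Collect (problem, path) pairs for a feature value under a
    capability profile."""
    if isinstance(value, dict):
        if not caps["nested"]:
            problems.append(("nested", path))
            return
        for k, v in value.items():
            _scan_value(v, caps, problems, f"{path}.{k}")
    elif isinstance(value, (list, tuple)):
        if not caps["ordered_lists"] or len(value) == 0:
            problems.append(("list", path))
        for v in value:
            if isinstance(v, (dict, list, tuple, FSet)):
                problems.append(("deep_multi", path))
                return
    elif isinstance(value, FSet):
        if not caps["unordered_sets"] or len(value.items) == 0:
            problems.append(("set", path))
        for v in value.items:
            if isinstance(v, (dict, list, tuple, FSet)):
                problems.append(("deep_multi", path))
                return


def _scan_features(features: dict, caps: dict, problems: list) -> None:
    for k, v in features.items():
        _scan_value(v, caps, problems, k)


_PROBLEM_KIND = {
    "nested": "nested_feature",
    "list": "multi_valued_feature",
    "set": "multi_valued_feature",
    "deep_multi": "multi_valued_feature",
}


# ---------------------------------------------------------------------------
# predict_loss
# ---------------------------------------------------------------------------

def predict_loss(
    doc: InteropDocument,
    to_format: str,
    opts: Optional[ConversionOptions] = None,
) -> list:
    """Enumerate every construct the target format cannot express, per
    the capability matrix.  Monotone: adding a construct to a document
    never removes a predicted entry."""
    if to_format not in CAPABILITIES:
        raise ValueError(f"unknown format {to_format!r}")
    opts = opts or ConversionOptions()
    caps = CAPABILITIES[to_format]
    direction = ("hub", to_format)
    out: list = []

    def add(kind: str, cid: str, detail: str) -> None:
        out.append(LossEntry(kind, cid, direction, detail))

    # views / producers / latest-view rule
    shadowed_ids: set = set()
    if caps["latest_view_only"] and opts.latest_view_only and len(doc.layers) > 1:
        _, shadowed = select_latest_views(doc, opts)
        for a, winner in shadowed:
            add(
                "shadowed_by_later_view",
                a.id,
                f"type {a.type_label!r} in view {a.layer_id!r} shadowed by later view {winner!r}",
            )
            shadowed_ids.add(a.id)
        if shadowed_ids:
            for r in doc.relations:
                if r.subj in shadowed_ids or r.obj_ref in shadowed_ids:
                    add(
                        "shadowed_by_later_view",
                        r.id,
                        "relation endpoint is a shadowed annotation",
                    )
            for c in doc.chains:
                if any(el.mention in shadowed_ids for el in c.elements):
                    add(
                        "shadowed_by_later_view",
                        c.id,
                        "chain mention is a shadowed annotation",
                    )
    if not caps["views"] and len(doc.layers) > 1:
        for layer in doc.layers:
            add("view_structure", layer.id, "view structure is collapsed")
    if not caps["empty_views"]:
        populated = {a.layer_id for a in doc.annotations}
        for layer in doc.layers:
            if layer.id not in populated and len(doc.layers) > 1:
                add(
                    "view_structure",
                    layer.id,
                    "empty view leaves no annotation to carry provenance",
                )
    if not caps["producers"]:
        for layer in doc.layers:
            if layer.producer is not None:
                add("provenance", layer.id, f"producer {layer.producer!r} dropped")

    # spans
    disc_ids: set = set()
    for a in doc.annotations:
        if a.span.discontinuous and not caps["discontinuous"]:
            add(
                "discontinuous_span",
                a.id,
                "no provisions for discontinuous annotations",
            )
            disc_ids.add(a.id)
    if disc_ids:
        for r in doc.relations:
            if r.subj in disc_ids or r.obj_ref in disc_ids:
                add(
                    "discontinuous_span",
                    r.id,
                    "relation endpoint is a dropped discontinuous annotation",
                )
        for c in doc.chains:
            if any(el.mention in disc_ids for el in c.elements):
                add(
                    "discontinuous_span",
                    c.id,
                    "chain mention is a dropped discontinuous annotation",
                )

    # chain link labels
    if not caps["chain_link_labels"]:
        for c in doc.chains:
            for i, el in enumerate(c.elements):
                if el.link_label is not None:
                    add(
                        "chain_link_label",
                        c.id,
                        f"link label {el.link_label!r} into element {i} cannot be labeled",
                    )

    # features
    for a in doc.annotations:
        problems: list = []
        _scan_features(a.features, caps, problems)
        for problem, path in problems:
            add(_PROBLEM_KIND[problem], a.id, f"feature {path!r}")
    for r in doc.relations:
        problems = []
        _scan_features(r.features, caps, problems)
        for problem, path in problems:
            add(_PROBLEM_KIND[problem], r.id, f"feature {path!r}")
    for da in doc.doc_attributes:
        problems = []
        _scan_value(da.value, caps, problems, da.predicate)
        for problem, path in problems:
            add(_PROBLEM_KIND[problem], DOC_SUBJECT, f"document attribute {path!r}")

    # features referencing dropped annotations are themselves dropped
    dropped = shadowed_ids | disc_ids
    if dropped:
        removed_rel = {
            r.id
            for r in doc.relations
            if r.subj in dropped or r.obj_ref in dropped
        }

        def ref_cascade(owner_id: str, features: dict) -> None:
            for fname, value in features.items():
                for target in sorted(_collect_refs(value)):
                    if target in dropped:
                        kind = (
                            "shadowed_by_later_view"
                            if target in shadowed_ids
                            else "discontinuous_span"
                        )
                        add(
                            kind,
                            owner_id,
                            f"feature {fname!r} references dropped annotation {target!r}",
                        )

        for a in doc.annotations:
            if a.id not in dropped:
                ref_cascade(a.id, a.features)
        for r in doc.relations:
            if r.id not in removed_rel:
                ref_cascade(r.id, r.features)
        for da in doc.doc_attributes:
            ref_cascade(DOC_SUBJECT, {da.predicate: da.value})

    # type URIs and the namespace table
    if not caps["type_uris"]:
        for a in doc.annotations:
            if a.type_uri is not None:
                add("type_uri", a.id, f"type URI {a.type_uri!r} dropped")
    if not caps["namespaces"] and doc.namespaces:
        add("type_uri", DOC_SUBJECT, "namespace table dropped")
    return out


# ---------------------------------------------------------------------------
# project
# ---------------------------------------------------------------------------

def _collect_refs(value: Any) -> set:
    out: set = set()
    if isinstance(value, Ref):
        out.add(value.target)
    elif isinstance(value, dict):
        for v in value.values():
            out |= _collect_refs(v)
    elif isinstance(value, (list, tuple)):
        for v in value:
            out |= _collect_refs(v)
    elif isinstance(value, FSet):
        for v in value.items:
            out |= _collect_refs(v)
    return out


def _sortkey(v: Any) -> str:
    return repr(v)


def _project_value(value: Any, caps: dict):
    """Project a feature value; returns a sentinel ``_DROP`` when the
    value cannot be expressed at all."""
    if isinstance(value, dict):
        if not caps["nested"]:
            return _DROP
        out = {}
        for k, v in value.items():
            pv = _project_value(v, caps)
            if pv is not _DROP:
                out[k] = pv
        return out
    if isinstance(value, (list, tuple)):
        if any(isinstance(v, (dict, list, tuple, FSet)) for v in value):
            return _DROP
        if len(value) == 0:
            return _DROP
        if not caps["ordered_lists"]:
            return FSet(value)
        return list(value)
    if isinstance(value, FSet):
        if any(isinstance(v, (dict, list, tuple, FSet)) for v in value.items):
            return _DROP
        if len(value.items) == 0:
            return _DROP
        if not caps["unordered_sets"]:
            return sorted(value.items, key=_sortkey)
        return value
    return value


class _Drop:
    def __repr__(self):
        return "<drop>"


_DROP = _Drop()


def _project_features(features: dict, caps: dict) -> dict:
    out = {}
    for k, v in features.items():
        pv = _project_value(v, caps)
        if pv is not _DROP:
            out[k] = pv
    return out


def project(
    doc: InteropDocument,
    to_format: str,
    opts: Optional[ConversionOptions] = None,
) -> InteropDocument:
    """Project a hub document onto the subset the target format can
    express — exactly the constructs :func:`predict_loss` does *not*
    list survive.  Deterministic and idempotent."""
    if to_format not in CAPABILITIES:
        raise ValueError(f"unknown format {to_format!r}")
    opts = opts or ConversionOptions()
    caps = CAPABILITIES[to_format]

    original_ids = {a.id for a in doc.annotations}
    if caps["latest_view_only"] and opts.latest_view_only:
        doc, _ = select_latest_views(doc, opts)

    annotations = list(doc.annotations)
    relations = list(doc.relations)
    chains = list(doc.chains)
    layers = list(doc.layers)
    doc_attributes = list(doc.doc_attributes)
    namespaces = dict(doc.namespaces)

    if not caps["discontinuous"]:
        disc = {a.id for a in annotations if a.span.discontinuous}
        if disc:
            annotations = [a for a in annotations if a.id not in disc]
            relations = [
                r for r in relations if r.subj not in disc and r.obj_ref not in disc
            ]
            chains = [
                c for c in chains if not any(el.mention in disc for el in c.elements)
            ]

    if not caps["views"]:
        layers = [Layer(id=DEFAULT_LAYER_ID, rank=0)]
        annotations = [replace(a, layer_id=DEFAULT_LAYER_ID) for a in annotations]
    elif not caps["empty_views"] and len(layers) > 1:
        populated = {a.layer_id for a in annotations}
        layers = [l for l in layers if l.id in populated]
        if not layers:
            layers = [Layer(id=DEFAULT_LAYER_ID, rank=0)]
            annotations = [replace(a, layer_id=DEFAULT_LAYER_ID) for a in annotations]

    if not caps["producers"]:
        layers = [replace(l, producer=None) for l in layers]

    if not caps["chain_link_labels"]:
        chains = [
            replace(
                c,
                elements=[replace(el, link_label=None) for el in c.elements],
            )
            for c in chains
        ]

    # drop features referencing annotations removed above
    surviving = {a.id for a in annotations}
    dropped_any = original_ids - surviving

    def strip_refs(features: dict) -> dict:
        if not dropped_any:
            return features
        return {
            k: v
            for k, v in features.items()
            if not (_collect_refs(v) & dropped_any)
        }

    annotations = [
        replace(
            a,
            features=_project_features(strip_refs(a.features), caps),
            type_uri=a.type_uri if caps["type_uris"] else None,
        )
        for a in annotations
    ]
    relations = [
        replace(r, features=_project_features(strip_refs(r.features), caps))
        for r in relations
    ]
    new_das = []
    for da in doc_attributes:
        if _collect_refs(da.value) & dropped_any:
            continue
        pv = _project_value(da.value, caps)
        if pv is not _DROP:
            new_das.append(replace(da, value=pv))
    if not caps["namespaces"]:
        namespaces = {}

    return replace(
        doc,
        layers=layers,
        annotations=annotations,
        relations=relations,
        chains=chains,
        doc_attributes=new_das,
        namespaces=namespaces,
    )
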