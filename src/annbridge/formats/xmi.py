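"""UIMA XMI subset: a CAS serialized as XML plus a type-system file.

The CAS data model anchors typed feature structures on a single subject
of analysis (the sofa text).  This module implements the subset a text
annotation round trip requires: one sofa, primitive features, reference
features, homogeneous arrays, and linked-list chain types.  Multiple
sofas, nested TOP structures, and binary blobs are out of scope.

Conventions used by the hub lift/lower:

* span annotations are subtypes of ``uima.tcas.Annotation`` with
  ``begin``/``end``; a bare hub type label lives in the ``custom``
  package (``custom.person``), a dotted label is used verbatim;
* a relation predicate ``p`` becomes the TOP subtype ``rel.p`` carrying
  exactly two reference features ``subj`` and ``obj`` (plus optional
  extra primitives);
* chains use the fixed types ``chain.Chain`` (features ``first``,
  ``kind``) and ``chain.Link`` (``target``, ``next``, ``label``), links
  referencing their mention annotation directly;
* document-level attributes live on a single
  ``meta.DocumentMetaData`` subtype of ``uima.cas.AnnotationBase``, one
  feature per predicate, with ``documentId`` reserved for the source id.

There are no provisions for discontinuous annotations; converters must
reject or drop them (with a loss record) before lowering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Optional

from lxml import etree

from ..model import (
    Annotation,
    ChainAnnotation,
    ChainElement,
    DEFAULT_LAYER_ID,
    DOC_SUBJECT,
    DocumentAttribute,
    FSet,
    InteropDocument,
    Layer,
    Ref,
    RelationEdge,
    TextSpan,
)
from ..rewrite import ConversionOptions, ConversionError
from .pubann import FormatError

__all__ = [
    "CasDocument",
    "TypeDescriptor",
    "FeatureStructure",
    "XmiRef",
    "read_xmi",
    "write_xmi",
    "lift_cas",
    "lower_cas",
]

NS_XMI = "http://www.omg.org/XMI"
NS_CAS = "http:///uima/cas.ecore"
NS_RS = "http://uima.apache.org/resourceSpecifier"

TOP = "uima.cas.TOP"
ANNOTATION_BASE = "uima.cas.AnnotationBase"
ANNOTATION = "uima.tcas.Annotation"
BUILTIN_SUPERTYPES = {TOP: None, ANNOTATION_BASE: TOP, ANNOTATION: ANNOTATION_BASE}

R_STRING = "uima.cas.String"
R_INTEGER = "uima.cas.Integer"
R_DOUBLE = "uima.cas.Double"
R_BOOLEAN = "uima.cas.Boolean"
R_FSARRAY = "uima.cas.FSArray"
_ARRAY_OF = {
    R_STRING: "uima.cas.StringArray",
    R_INTEGER: "uima.cas.IntegerArray",
    R_DOUBLE: "uima.cas.DoubleArray",
    R_BOOLEAN: "uima.cas.BooleanArray",
}
_ARRAY_ELEM = {v: k for k, v in _ARRAY_OF.items()}

CHAIN_TYPE = "chain.Chain"
LINK_TYPE = "chain.Link"
META_TYPE = "meta.DocumentMetaData"
REL_PACKAGE = "rel"
CUSTOM_PACKAGE = "custom"

_NCNAME = re.compile(r"^[A-Za-z_][A-Za-z0-9_.-]*$")
_FEATURE_NAME = re.compile(r"^[A-Za-z_][A-Za-z0-9_-]*$")


@dataclass(frozen=True)
class XmiRef:
    target: int


@dataclass
class TypeDescriptor:
    name: str
    supertype: str = ANNOTATION
    features: dict = field(default_factory=dict)  # name -> rangeTypeName


@dataclass
class FeatureStructure:
    xmi_id: int
    type: str
    begin: Optional[int] = None
    end: Optional[int] = None
    features: dict = field(default_factory=dict)


@dataclass
class CasDocument:
    typesystem: dict = field(default_factory=dict)  # name -> TypeDescriptor
    sofa_text: str = ""
    feature_structures: list = field(default_factory=list)

    def is_annotation_type(self, name: str) -> bool:
        seen = set()
        while name is not None and name not in seen:
            if name == ANNOTATION:
                return True
            seen.add(name)
            td = self.typesystem.get(name)
            name = td.supertype if td else BUILTIN_SUPERTYPES.get(name)
        return False


# ---------------------------------------------------------------------------
# name <-> XML namespace mapping
# ---------------------------------------------------------------------------

def _split_type(name: str) -> tuple:
    if "." in name:
        pkg, short = name.rsplit(".", 1)
    else:
        pkg, short = CUSTOM_PACKAGE, name
    return pkg, short


def _pkg_to_ns(pkg: str) -> str:
    return "http:///" + pkg.replace(".", "/") + ".ecore"


def _ns_to_pkg(ns: str) -> str:
    assert ns.startswith("http:///") and ns.endswith(".ecore")
    return ns[len("http:///"):-len(".ecore")].replace("/", ".")


# ---------------------------------------------------------------------------
# write
# ---------------------------------------------------------------------------

def write_xmi(cas: CasDocument) -> tuple:
    """Serialize to ``(typesystem_bytes, xmi_bytes)``.  Output is
    deterministic: types, features and structures are written in sorted
    or xmi-id order, so identical documents yield identical bytes."""
    # --- typesystem -----------------------------------------------------
    rs = "{%s}" % NS_RS
    ts_root = etree.Element(rs + "typeSystemDescription", nsmap={None: NS_RS})
    types_el = etree.SubElement(ts_root, rs + "types")
    for name in sorted(cas.typesystem):
        td = cas.typesystem[name]
        t_el = etree.SubElement(types_el, rs + "typeDescription")
        etree.SubElement(t_el, rs + "name").text = td.name
        etree.SubElement(t_el, rs + "supertypeName").text = td.supertype
        if td.features:
            feats_el = etree.SubElement(t_el, rs + "features")
            for fname in sorted(td.features):
                f_el = etree.SubElement(feats_el, rs + "featureDescription")
                etree.SubElement(f_el, rs + "name").text = fname
                etree.SubElement(f_el, rs + "rangeTypeName").text = td.features[fname]
    ts_bytes = etree.tostring(
        ts_root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )

    # --- xmi ------------------------------------------------------------
    packages = sorted({_split_type(n)[0] for n in cas.typesystem})
    nsmap = {"xmi": NS_XMI, "cas": NS_CAS}
    prefix_of = {}
    for pkg in packages:
        base = re.sub(r"[^A-Za-z0-9_]", "_", pkg.rsplit(".", 1)[-1]) or "p"
        prefix = base
        i = 1
        while prefix in nsmap:
            i += 1
            prefix = f"{base}{i}"
        nsmap[prefix] = _pkg_to_ns(pkg)
        prefix_of[pkg] = prefix

    root = etree.Element("{%s}XMI" % NS_XMI, nsmap=nsmap)
    root.set("{%s}version" % NS_XMI, "2.0")
    sofa = etree.SubElement(root, "{%s}Sofa" % NS_CAS)
    sofa.set("{%s}id" % NS_XMI, "1")
    sofa.set("sofaNum", "1")
    sofa.set("sofaID", "_InitialView")
    sofa.set("mimeType", "text")
    sofa.set("sofaString", cas.sofa_text)

    def prim_str(v: Any) -> str:
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, float):
            return repr(v)
        if isinstance(v, XmiRef):
            return str(v.target)
        return str(v)

    for fs in sorted(cas.feature_structures, key=lambda f: f.xmi_id):
        td = cas.typesystem.get(fs.type)
        if td is None:
            raise ConversionError(f"feature structure {fs.xmi_id} has unknown type {fs.type!r}")
        pkg, short = _split_type(fs.type)
        el = etree.SubElement(root, "{%s}%s" % (_pkg_to_ns(pkg), short))
        el.set("{%s}id" % NS_XMI, str(fs.xmi_id))
        el.set("sofa", "1")
        if fs.begin is not None:
            el.set("begin", str(fs.begin))
            el.set("end", str(fs.end))
        for fname in sorted(fs.features):
            value = fs.features[fname]
            if value is None:
                continue
            if isinstance(value, list):
                for item in value:
                    sub = etree.SubElement(el, fname)
                    sub.text = prim_str(item)
                    # preserve empty strings explicitly
                    if sub.text == "":
                        sub.text = None
            else:
                el.set(fname, prim_str(value))

    view = etree.SubElement(root, "{%s}View" % NS_CAS)
    view.set("sofa", "1")
    members = " ".join(
        str(fs.xmi_id) for fs in sorted(cas.feature_structures, key=lambda f: f.xmi_id)
    )
    if members:
        view.set("members", members)
    xmi_bytes = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    return ts_bytes, xmi_bytes


# ---------------------------------------------------------------------------
# read
# ---------------------------------------------------------------------------

def _read_typesystem(ts_bytes: bytes) -> dict:
    try:
        root = etree.fromstring(ts_bytes)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed type system XML: {exc}") from exc
    rs = "{%s}" % NS_RS
    out: dict = {}
    for t_el in root.iter(rs + "typeDescription"):
        name = t_el.findtext(rs + "name")
        supertype = t_el.findtext(rs + "supertypeName") or ANNOTATION
        feats: dict = {}
        for f_el in t_el.iter(rs + "featureDescription"):
            feats[f_el.findtext(rs + "name")] = f_el.findtext(rs + "rangeTypeName")
        out[name] = TypeDescriptor(name=name, supertype=supertype, features=feats)
    return out


def _parse_prim(text: str, rng: str, where: str):
    try:
        if rng == R_INTEGER:
            return int(text)
        if rng == R_DOUBLE:
            return float(text)
        if rng == R_BOOLEAN:
            if text not in ("true", "false"):
                raise ValueError(text)
            return text == "true"
    except ValueError as exc:
        raise FormatError(f"{where}: value {text!r} violates range {rng}") from exc
    return text


def read_xmi(ts_bytes: bytes, xmi_bytes: bytes, strict: bool = True) -> CasDocument:
    """Materialize all feature structures of declared types.  Unknown
    types are an error in strict mode and skipped in lenient mode."""
    typesystem = _read_typesystem(ts_bytes)
    try:
        root = etree.fromstring(xmi_bytes)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XMI: {exc}") from exc

    cas = CasDocument(typesystem=typesystem)
    seen_ids: set = set()
    sofa_seen = False
    for el in root:
        qname = etree.QName(el)
        if qname.namespace == NS_CAS and qname.localname == "Sofa":
            if sofa_seen:
                raise FormatError("XMI must reference a single sofa")
            sofa_seen = True
            cas.sofa_text = el.get("sofaString", "")
            continue
        if qname.namespace == NS_CAS and qname.localname == "View":
            continue
        pkg = _ns_to_pkg(qname.namespace)
        tname = f"{pkg}.{qname.localname}"
        td = typesystem.get(tname)
        if td is None:
            if strict:
                raise FormatError(f"feature structure of undeclared type {tname!r}")
            continue

        xmi_id_raw = el.get("{%s}id" % NS_XMI)
        if xmi_id_raw is None:
            raise FormatError(f"feature structure of type {tname!r} lacks xmi:id")
        xmi_id = int(xmi_id_raw)
        if xmi_id in seen_ids:
            raise FormatError(f"xmi:id collision: {xmi_id}")
        seen_ids.add(xmi_id)

        fs = FeatureStructure(xmi_id=xmi_id, type=tname)
        is_ann = cas.is_annotation_type(tname)
        for attr, raw in el.attrib.items():
            if attr == "{%s}id" % NS_XMI or attr == "sofa":
                continue
            if is_ann and attr in ("begin", "end"):
                setattr(fs, attr, int(raw))
                continue
            rng = td.features.get(attr)
            if rng is None:
                if strict:
                    raise FormatError(f"{tname}: undeclared feature {attr!r}")
                continue
            if rng in (R_STRING, R_INTEGER, R_DOUBLE, R_BOOLEAN):
                fs.features[attr] = _parse_prim(raw, rng, f"{tname}.{attr}")
            elif rng in _ARRAY_ELEM or rng == R_FSARRAY:
                raise FormatError(f"{tname}.{attr}: array range serialized as attribute")
            else:
                fs.features[attr] = XmiRef(int(raw))
        for child in el:
            fname = child.tag
            rng = td.features.get(fname)
            if rng is None:
                if strict:
                    raise FormatError(f"{tname}: undeclared feature element {fname!r}")
                continue
            text = child.text or ""
            if rng == R_FSARRAY:
                item: Any = XmiRef(int(text))
            elif rng in _ARRAY_ELEM:
                item = _parse_prim(text, _ARRAY_ELEM[rng], f"{tname}.{fname}")
            else:
                raise FormatError(f"{tname}.{fname}: scalar range serialized as element")
            fs.features.setdefault(fname, []).append(item)
        cas.feature_structures.append(fs)

    ids = seen_ids
    for fs in cas.feature_structures:
        for fname, value in fs.features.items():
            targets = value if isinstance(value, list) else [value]
            for t in targets:
                if isinstance(t, XmiRef) and t.target not in ids:
                    raise FormatError(
                        f"{fs.type}.{fname}: dangling reference to xmi:id {t.target}"
                    )
    return cas


# ---------------------------------------------------------------------------
# lift / lower
# ---------------------------------------------------------------------------

def _label_of(type_name: str) -> str:
    if type_name.startswith(CUSTOM_PACKAGE + "."):
        return type_name[len(CUSTOM_PACKAGE) + 1:]
    return type_name


def lift_cas(cas: CasDocument, opts: Optional[ConversionOptions] = None) -> InteropDocument:
    """Lift to the hub model: one layer (the CAS has no view/provenance
    structure), chains chased through their linked lists, relation types
    rebuilt into relation edges, document metadata into document
    attributes."""
    opts = opts or ConversionOptions()
    doc = InteropDocument(text=cas.sofa_text)
    doc.layers.append(Layer(id=DEFAULT_LAYER_ID, rank=0))

    by_id = {fs.xmi_id: fs for fs in cas.feature_structures}
    hub_id: dict = {}
    spans, rels, chains_fs, links, metas = [], [], [], [], []
    for fs in cas.feature_structures:
        if fs.type == META_TYPE:
            metas.append(fs)
        elif fs.type == CHAIN_TYPE:
            chains_fs.append(fs)
        elif fs.type == LINK_TYPE:
            links.append(fs)
        elif fs.type.startswith(REL_PACKAGE + "."):
            rels.append(fs)
        elif cas.is_annotation_type(fs.type):
            spans.append(fs)
        else:
            raise FormatError(
                f"feature structure {fs.xmi_id} of type {fs.type!r} "
                "is not expressible in the hub model"
            )

    for i, fs in enumerate(spans, start=1):
        hub_id[fs.xmi_id] = f"T{i}"

    def decode(v: Any) -> Any:
        if isinstance(v, XmiRef):
            if v.target not in hub_id:
                raise FormatError(
                    f"reference to xmi:id {v.target} which is not a span annotation"
                )
            return Ref(hub_id[v.target])
        if isinstance(v, list):
            return [decode(x) for x in v]
        return v

    for fs in spans:
        if fs.begin is None:
            raise FormatError(f"annotation {fs.xmi_id} lacks begin/end")
        doc.annotations.append(
            Annotation(
                id=hub_id[fs.xmi_id],
                span=TextSpan.single(fs.begin, fs.end),
                type_label=_label_of(fs.type),
                features={k: decode(v) for k, v in fs.features.items()},
                layer_id=DEFAULT_LAYER_ID,
            )
        )

    for i, fs in enumerate(rels, start=1):
        feats = dict(fs.features)
        subj = feats.pop("subj", None)
        obj = feats.pop("obj", None)
        if not isinstance(subj, XmiRef) or not isinstance(obj, XmiRef):
            raise FormatError(
                f"relation {fs.xmi_id}: needs exactly two reference features subj/obj"
            )
        doc.relations.append(
            RelationEdge(
                id=f"R{i}",
                predicate=fs.type.rsplit(".", 1)[-1],
                subj=hub_id[subj.target],
                obj_ref=hub_id[obj.target],
                features={k: decode(v) for k, v in feats.items()},
            )
        )

    for i, fs in enumerate(chains_fs, start=1):
        first = fs.features.get("first")
        kind = fs.features.get("kind", "chain")
        elements = []
        node = first
        seen: set = set()
        while isinstance(node, XmiRef):
            if node.target in seen:
                raise FormatError(f"chain {fs.xmi_id}: link cycle")
            seen.add(node.target)
            link = by_id.get(node.target)
            if link is None or link.type != LINK_TYPE:
                raise FormatError(f"chain {fs.xmi_id}: bad link {node.target}")
            target = link.features.get("target")
            if not isinstance(target, XmiRef) or target.target not in hub_id:
                raise FormatError(f"link {link.xmi_id}: bad target")
            mention_id = hub_id[target.target]
            mention = next(a for a in doc.annotations if a.id == mention_id)
            elements.append(
                ChainElement(
                    mention=mention_id,
                    span_label=mention.type_label,
                    link_label=link.features.get("label"),
                )
            )
            node = link.features.get("next")
        if not elements:
            raise FormatError(f"chain {fs.xmi_id}: empty chain")
        doc.chains.append(
            ChainAnnotation(id=f"C{i}", chain_type=kind, elements=elements)
        )

    for fs in metas:
        for fname in sorted(fs.features):
            value = decode(fs.features[fname])
            if fname == "documentId":
                doc.source_id = value
            else:
                doc.doc_attributes.append(
                    DocumentAttribute(predicate=fname, value=value)
                )
    return doc


def _check_feature_name(name: str, where: str) -> None:
    if not _FEATURE_NAME.match(name):
        raise ConversionError(
            f"{where}: feature name {name!r} is not expressible as a CAS feature"
        )


def _range_of(value: Any, where: str) -> str:
    if isinstance(value, bool):
        return R_BOOLEAN
    if isinstance(value, int):
        return R_INTEGER
    if isinstance(value, float):
        return R_DOUBLE
    if isinstance(value, str):
        return R_STRING
    if isinstance(value, (Ref, XmiRef)):
        return ANNOTATION
    if isinstance(value, list):
        if not value:
            raise ConversionError(f"{where}: empty arrays are not representable")
        elem = {_range_of(v, where) for v in value}
        if elem == {ANNOTATION}:
            return R_FSARRAY
        if elem <= {R_INTEGER, R_DOUBLE} and len(elem) == 2:
            return _ARRAY_OF[R_DOUBLE]
        if len(elem) == 1:
            e = elem.pop()
            if e in _ARRAY_OF:
                return _ARRAY_OF[e]
        raise ConversionError(f"{where}: heterogeneous array is not representable")
    raise ConversionError(f"{where}: value {value!r} is not representable in the CAS subset")


def _merge_range(a: Optional[str], b: str, where: str) -> str:
    if a is None or a == b:
        return b
    if {a, b} == {R_INTEGER, R_DOUBLE}:
        return R_DOUBLE
    if {a, b} == {_ARRAY_OF[R_INTEGER], _ARRAY_OF[R_DOUBLE]}:
        return _ARRAY_OF[R_DOUBLE]
    raise ConversionError(f"{where}: conflicting feature ranges {a} vs {b}")


def _type_name_for_label(label: str) -> str:
    if "." in label and all(_FEATURE_NAME.match(p) for p in label.split(".")):
        return label
    safe = re.sub(r"[^A-Za-z0-9_]", "_", label)
    if not re.match(r"^[A-Za-z_]", safe):
        safe = "x" + safe
    return f"{CUSTOM_PACKAGE}.{safe}"


def lower_cas(doc: InteropDocument, opts: Optional[ConversionOptions] = None) -> CasDocument:
    """Lower a hub document to a CAS with a generated minimal type
    system.  The document must already be within the CAS-expressible
    subset (single layer, contiguous spans, flat features, no unordered
    sets); the conversion pipeline projects and reports losses first."""
    opts = opts or ConversionOptions()
    for a in doc.annotations:
        if a.span.discontinuous:
            raise ConversionError(
                f"discontinuous span on annotation {a.id!r} cannot be "
                "represented: the CAS model has no provisions for "
                "discontinuous annotations"
            )

    cas = CasDocument(sofa_text=doc.text)
    ts = cas.typesystem
    next_id = [1]

    def fresh_id() -> int:
        next_id[0] += 1
        return next_id[0]

    xmi_of: dict = {a.id: fresh_id() for a in doc.annotations}

    def encode(v: Any, where: str) -> Any:
        if isinstance(v, Ref):
            if v.target not in xmi_of:
                raise ConversionError(f"{where}: reference to unknown annotation {v.target!r}")
            return XmiRef(xmi_of[v.target])
        if isinstance(v, list):
            return [encode(x, where) for x in v]
        if isinstance(v, (dict, FSet)):
            raise ConversionError(
                f"{where}: nested or unordered feature values are not in the CAS subset"
            )
        return v

    def declare(type_name: str, supertype: str, features_seen: dict) -> TypeDescriptor:
        td = ts.get(type_name)
        if td is None:
            td = TypeDescriptor(name=type_name, supertype=supertype, features={})
            ts[type_name] = td
        for fname, value in features_seen.items():
            _check_feature_name(fname, type_name)
            if supertype == ANNOTATION and fname in ("begin", "end", "sofa"):
                raise ConversionError(
                    f"{type_name}: feature name {fname!r} collides with a built-in"
                )
            rng = _range_of(value, f"{type_name}.{fname}")
            td.features[fname] = _merge_range(
                td.features.get(fname), rng, f"{type_name}.{fname}"
            )
        return td

    for a in doc.annotations:
        tname = _type_name_for_label(a.type_label)
        feats = {k: encode(v, f"{a.id}.{k}") for k, v in a.features.items()}
        declare(tname, ANNOTATION, feats)
        cas.feature_structures.append(
            FeatureStructure(
                xmi_id=xmi_of[a.id],
                type=tname,
                begin=a.span.begin,
                end=a.span.end,
                features=feats,
            )
        )

    for r in doc.relations:
        tname = _type_name_for_label(r.predicate)
        short = tname.rsplit(".", 1)[-1]
        tname = f"{REL_PACKAGE}.{short}"
        feats = {k: encode(v, f"{r.id}.{k}") for k, v in r.features.items()}
        if "subj" in feats or "obj" in feats:
            raise ConversionError(
                f"relation {r.id!r}: feature names 'subj'/'obj' are reserved for endpoints"
            )
        feats["subj"] = XmiRef(xmi_of[r.subj])
        feats["obj"] = XmiRef(xmi_of[r.obj_ref])
        declare(tname, TOP, feats)
        cas.feature_structures.append(
            FeatureStructure(xmi_id=fresh_id(), type=tname, features=feats)
        )

    if doc.chains:
        ts[CHAIN_TYPE] = TypeDescriptor(
            name=CHAIN_TYPE, supertype=TOP, features={"first": LINK_TYPE, "kind": R_STRING}
        )
        ts[LINK_TYPE] = TypeDescriptor(
            name=LINK_TYPE,
            supertype=TOP,
            features={"target": ANNOTATION, "next": LINK_TYPE, "label": R_STRING},
        )
        for c in doc.chains:
            link_ids = [fresh_id() for _ in c.elements]
            for i, el in enumerate(c.elements):
                feats = {"target": XmiRef(xmi_of[el.mention])}
                if el.link_label is not None:
                    feats["label"] = el.link_label
                if i + 1 < len(link_ids):
                    feats["next"] = XmiRef(link_ids[i + 1])
                cas.feature_structures.append(
                    FeatureStructure(xmi_id=link_ids[i], type=LINK_TYPE, features=feats)
                )
            cas.feature_structures.append(
                FeatureStructure(
                    xmi_id=fresh_id(),
                    type=CHAIN_TYPE,
                    features={"first": XmiRef(link_ids[0]), "kind": c.chain_type},
                )
            )

    if doc.doc_attributes or doc.source_id is not None:
        feats = {}
        if doc.source_id is not None:
            feats["documentId"] = doc.source_id
        for da in doc.doc_attributes:
            if da.predicate == "documentId":
                raise ConversionError(
                    "document attribute name 'documentId' is reserved for the source id"
                )
            feats[da.predicate] = encode(da.value, f"{DOC_SUBJECT}.{da.predicate}")
        declare(META_TYPE, ANNOTATION_BASE, feats)
        cas.feature_structures.append(
            FeatureStructure(xmi_id=fresh_id(), type=META_TYPE, features=feats)
        )
    return cas
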