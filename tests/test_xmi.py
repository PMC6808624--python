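"""XMI subset serialization, checked against an independent
``xml.etree.ElementTree`` reparse oracle."""

import xml.etree.ElementTree as ET

import pytest

from annbridge.formats.pubann import FormatError
from annbridge.formats.xmi import lower_cas, read_xmi, write_xmi
from annbridge.model import semantic_key
from annbridge.pipeline import from_hub, to_hub, unpack_cas
from annbridge.rewrite import ConversionError, ConversionOptions
from annbridge.synth import GeneratorConfig, generate_corpus

NS_XMI = "http://www.omg.org/XMI"
NS_CAS = "http:///uima/cas.ecore"
NS_RS = "http://uima.apache.org/resourceSpecifier"


def _cas_files(doc, opts):
    return unpack_cas(from_hub(doc, "cas", opts).data)


def test_write_read_identity(small_doc, lenient):
    ts, xmi = _cas_files(small_doc, lenient)
    cas = read_xmi(ts, xmi, strict=True)
    assert write_xmi(cas) == (ts, xmi)


def test_independent_etree_oracle(small_doc, lenient):
    ts, xmi = _cas_files(small_doc, lenient)
    root = ET.fromstring(xmi)

    sofas = root.findall(f"{{{NS_CAS}}}Sofa")
    assert len(sofas) == 1
    assert sofas[0].get("sofaString") == small_doc.text

    # every annotation-looking element has sane begin/end over the sofa
    n = len(small_doc.text)
    spans = []
    for el in root:
        if el.get("begin") is not None:
            b, e = int(el.get("begin")), int(el.get("end"))
            assert 0 <= b <= e <= n
            spans.append((b, e))
    assert (0, 12) in spans and (19, 32) in spans

    # xmi:ids are unique and the View element indexes them all
    ids = [el.get(f"{{{NS_XMI}}}id") for el in root if el.get(f"{{{NS_XMI}}}id")]
    assert len(ids) == len(set(ids))
    view = root.find(f"{{{NS_CAS}}}View")
    members = set(view.get("members").split())
    assert members == set(ids) - {"1"}  # all but the sofa

    # the typesystem declares every custom namespace used in the XMI
    ts_root = ET.fromstring(ts)
    declared = {
        t.findtext(f"{{{NS_RS}}}name")
        for t in ts_root.iter(f"{{{NS_RS}}}typeDescription")
    }
    for el in root:
        tag_ns = el.tag.split("}")[0][1:]
        if tag_ns == NS_CAS:
            continue
        pkg = tag_ns[len("http:///"):-len(".ecore")].replace("/", ".")
        local = el.tag.split("}")[1]
        assert f"{pkg}.{local}" in declared


def test_chain_types_in_xmi(small_doc, lenient):
    ts, xmi = _cas_files(small_doc, lenient)
    root = ET.fromstring(xmi)
    chain_ns = "{http:///chain.ecore}"
    chains = root.findall(chain_ns + "Chain")
    links = root.findall(chain_ns + "Link")
    assert len(chains) == 1 and len(links) == 2
    assert chains[0].get("kind") == "coref"
    # chain head points at the first link; links carry labels where set
    assert chains[0].get("first") in {l.get(f"{{{NS_XMI}}}id") for l in links}
    assert "anaphora" in {l.get("label") for l in links}


def test_relation_types_in_xmi(small_doc, lenient):
    ts, xmi = _cas_files(small_doc, lenient)
    root = ET.fromstring(xmi)
    rels = root.findall("{http:///rel.ecore}causes")
    assert len(rels) == 1
    ids = {el.get(f"{{{NS_XMI}}}id") for el in root}
    assert rels[0].get("subj") in ids and rels[0].get("obj") in ids


def test_multivalued_feature_as_repeated_elements(small_doc, lenient):
    ts, xmi = _cas_files(small_doc, lenient)
    root = ET.fromstring(xmi)
    tagged = [el for el in root if el.findall("tags")]
    assert len(tagged) == 1
    assert sorted(t.text for t in tagged[0].findall("tags")) == ["x", "y"]


def test_source_id_in_document_metadata(small_doc, lenient):
    ts, xmi = _cas_files(small_doc, lenient)
    root = ET.fromstring(xmi)
    meta = root.findall("{http:///meta.ecore}DocumentMetaData")
    assert len(meta) == 1 and meta[0].get("documentId") == "DOC-small"


def test_newlines_survive_attribute_encoding(lenient):
    from annbridge.model import Annotation, InteropDocument, Layer, TextSpan

    doc = InteropDocument(text="line one\nline\ttwo", layers=[Layer("l0")])
    doc.annotations = [
        Annotation("T1", TextSpan.single(0, 4), "seg", features={"note": "a\nb\tc"})
    ]
    data = from_hub(doc, "cas", lenient).data
    hub = to_hub(data, "cas", lenient)
    assert hub.text == "line one\nline\ttwo"
    assert hub.annotations[0].features["note"] == "a\nb\tc"


def test_discontinuous_strict_raises(small_doc_discontinuous, strict):
    with pytest.raises(ConversionError, match="T6"):
        from_hub(small_doc_discontinuous, "cas", strict)


def test_lower_cas_rejects_discontinuous_directly(small_doc_discontinuous, lenient):
    with pytest.raises(ConversionError):
        lower_cas(small_doc_discontinuous, lenient)


def test_undeclared_type_strict_vs_lenient(small_doc, lenient):
    ts, xmi = _cas_files(small_doc, lenient)
    rogue = xmi.replace(
        b"</xmi:XMI>",
        b'<x:Thing xmlns:x="http:///rogue.ecore" xmi:id="999" sofa="1"/></xmi:XMI>',
    )
    with pytest.raises(FormatError, match="undeclared"):
        read_xmi(ts, rogue, strict=True)
    cas = read_xmi(ts, rogue, strict=False)
    assert all(fs.type != "rogue.Thing" for fs in cas.feature_structures)


def test_dangling_xmi_reference_rejected(small_doc, lenient):
    ts, xmi = _cas_files(small_doc, lenient)
    root = ET.fromstring(xmi)
    rel = root.find("{http:///rel.ecore}causes")
    subj = rel.get("subj").encode()
    broken = xmi.replace(b'subj="' + subj + b'"', b'subj="4242"')
    with pytest.raises(FormatError, match="dangling"):
        read_xmi(ts, broken, strict=True)


def test_xmi_id_collision_rejected(small_doc, lenient):
    import re as _re

    ts, xmi = _cas_files(small_doc, lenient)
    ids = _re.findall(rb'xmi:id="(\d+)"', xmi)
    non_sofa = [i for i in ids if i != b"1"]
    dup, other = non_sofa[0], non_sofa[1]
    # reuse the first structure's id on a second structure
    bad = xmi.replace(b'xmi:id="' + other + b'"', b'xmi:id="' + dup + b'"', 1)
    with pytest.raises(FormatError, match="collision"):
        read_xmi(ts, bad, strict=True)


def test_roundtrip_semantics_on_corpus(lenient):
    for doc in generate_corpus(GeneratorConfig(seed=6, n_documents=8)):
        data = from_hub(doc, "cas", lenient).data
        hub = to_hub(data, "cas", lenient)
        again = to_hub(from_hub(hub, "cas", lenient).data, "cas", lenient)
        assert semantic_key(hub) == semantic_key(again)


def test_deterministic_double_write(lenient):
    for doc in generate_corpus(GeneratorConfig(seed=2, n_documents=5)):
        assert from_hub(doc, "cas", lenient).data == from_hub(doc, "cas", lenient).data
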