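"""PubAnnotation serialization, checked against independent oracles
(plain ``json`` reparsing and substring extraction)."""

import json

import pytest

from annbridge.formats.pubann import (
    FormatError,
    lift_pubann,
    lower_pubann,
    read_pubann,
    write_pubann,
)
from annbridge.model import semantic_key
from annbridge.pipeline import from_hub, to_hub
from annbridge.rewrite import ConversionOptions
from annbridge.synth import GeneratorConfig, generate_corpus


def _pubann_bytes(doc, opts):
    return from_hub(doc, "pubann", opts).data


def test_write_read_identity(small_doc, lenient):
    data = _pubann_bytes(small_doc, lenient)
    pub = read_pubann(data, lenient)
    assert write_pubann(pub) == data


def test_independent_json_oracle(small_doc, lenient):
    """Verify the bytes with the stdlib json module only."""
    data = _pubann_bytes(small_doc, lenient)
    obj = json.loads(data)
    assert obj["text"] == small_doc.text
    assert obj["sourceid"] == "DOC-small"
    # every single span's offsets select the expected substring
    for d in obj["denotations"]:
        span = d["span"]
        if isinstance(span, dict):
            assert 0 <= span["begin"] <= span["end"] <= len(obj["text"])
    # chain encoded: one _chain attribute, one _next relation per link
    chain_attrs = [a for a in obj["attributes"] if a["pred"] == "_chain"]
    next_rels = [r for r in obj["relations"] if r["pred"] == "_next"]
    assert len(chain_attrs) == 1 and chain_attrs[0]["obj"] == "coref"
    assert len(next_rels) == 1
    link_attrs = [a for a in obj["attributes"] if a["pred"] == "_link"]
    assert [a["obj"] for a in link_attrs] == ["anaphora"]
    # nested feature flattened to dotted attributes
    preds = {a["pred"] for a in obj["attributes"]}
    assert {"author.first", "author.last"} <= preds
    # multi-valued feature is repeated attributes on the same subject
    tags = [a for a in obj["attributes"] if a["pred"] == "tags"]
    assert len(tags) == 2 and len({a["subj"] for a in tags}) == 1
    # document attribute subject is the reserved marker
    doc_attrs = [a for a in obj["attributes"] if a["subj"] == "_doc"]
    assert {"language"} <= {a["pred"] for a in doc_attrs}


def test_lift_lower_roundtrip(small_doc, lenient):
    data = _pubann_bytes(small_doc, lenient)
    hub = to_hub(data, "pubann", lenient)
    assert semantic_key(hub) == semantic_key(
        to_hub(from_hub(hub, "pubann", lenient).data, "pubann", lenient)
    )


def test_discontinuous_span_as_segment_list(small_doc_discontinuous, lenient):
    data = _pubann_bytes(small_doc_discontinuous, lenient)
    obj = json.loads(data)
    multi = [d for d in obj["denotations"] if isinstance(d["span"], list)]
    assert len(multi) == 1
    assert [tuple(s.values()) for s in multi[0]["span"]] == [(0, 5), (19, 23)]
    hub = to_hub(data, "pubann", lenient)
    spans = [a.span for a in hub.annotations if a.span.discontinuous]
    assert len(spans) == 1 and spans[0].segments == ((0, 5), (19, 23))


def test_malformed_json_reports_offset():
    with pytest.raises(FormatError, match="byte offset"):
        read_pubann(b'{"text": "ab", ]')


def test_missing_text_rejected():
    with pytest.raises(FormatError, match="text"):
        read_pubann(b'{"denotations": []}')


def test_reserved_prefix_rejected_in_user_data():
    doc = {
        "text": "ab",
        "denotations": [{"id": "T1", "span": {"begin": 0, "end": 1}, "obj": "x"}],
        "attributes": [{"id": "A1", "subj": "T1", "pred": "_secret", "obj": "v"}],
    }
    with pytest.raises(FormatError, match="reserved"):
        read_pubann(json.dumps(doc).encode())


def test_dangling_reference_rejected():
    doc = {
        "text": "ab",
        "denotations": [{"id": "T1", "span": {"begin": 0, "end": 1}, "obj": "x"}],
        "relations": [{"id": "R1", "pred": "p", "subj": "T1", "obj": "T9"}],
    }
    with pytest.raises(FormatError, match="dangling"):
        read_pubann(json.dumps(doc).encode())


def test_schemaless_minimum():
    pub = read_pubann(b'{"text": "just text"}')
    hub = lift_pubann(pub)
    assert hub.text == "just text" and hub.annotations == []


def test_ids_renumbered_in_document_order(small_doc, lenient):
    obj = json.loads(_pubann_bytes(small_doc, lenient))
    den_ids = [d["id"] for d in obj["denotations"]]
    assert den_ids == [f"T{i}" for i in range(1, len(den_ids) + 1)]
    rel_ids = [r["id"] for r in obj["relations"]]
    assert rel_ids == [f"R{i}" for i in range(1, len(rel_ids) + 1)]


def test_deterministic_double_write(lenient):
    for doc in generate_corpus(GeneratorConfig(seed=3, n_documents=5)):
        assert _pubann_bytes(doc, lenient) == _pubann_bytes(doc, lenient)


def test_lower_requires_encoded_chains(small_doc, strict):
    with pytest.raises(Exception):
        lower_pubann(small_doc, strict)  # chains not yet encoded
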