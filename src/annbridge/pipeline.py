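"""The six directed conversions, as read → lift → rewrite → lower → write.

Every conversion passes through the hub model.  ``to_hub`` fully
structures a serialized document (decoding the provenance and chain
conventions back into views and chains); ``from_hub`` applies the fixed
rewrite sequence for the target — rename, then chains, then views, then
features, then types — and serializes.  The applied sequence per
direction:

* → PubAnnotation: project onto the expressible subset (ordered lists
  become sets), encode chains as denotations + sequential ``_next``
  relations, collapse views into reserved provenance attributes,
  flatten nested features into dotted attributes, store types as
  denotation objects (URIs kept verbatim).
* → LIF: project (chain link labels drop, with loss entries), views map
  to views, chains to mention-list annotations, relations to
  endpoint-feature annotations.
* → CAS: apply the latest-view rule, drop view/producer structure, drop
  discontinuous spans (a strict-mode error), nested features, unordered
  sets, type URIs and the namespace table — every drop recorded — then
  lower onto a generated minimal type system.

A loss report accompanies every conversion; information is never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .capabilities import LossEntry, predict_loss, project
from .model import InteropDocument
from .rewrite import (
    ConversionError,
    ConversionOptions,
    apply_renamer,
    collapse_views,
    decode_chains,
    encode_chains,
    expand_views,
)
from .formats import pubann as _pubann
from .formats import lif as _lif
from .formats import xmi as _xmi

__all__ = ["FORMATS", "ConversionResult", "to_hub", "from_hub", "convert"]

FORMATS = ("pubann", "lif", "cas")


@dataclass
class ConversionResult:
    data: bytes  # for cas: typesystem + XMI packed by pack_cas
    loss: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# CAS byte packing: a conversion result is one byte stream; the CAS
# serialization is two files (typesystem + XMI), packed with a length
# prefix so convert() has a uniform signature.  cli.py splits them back
# into two files on disk.
# ---------------------------------------------------------------------------

_CAS_MAGIC = b"ANNBRIDGE-CAS\n"


def pack_cas(ts_bytes: bytes, xmi_bytes: bytes) -> bytes:
    return _CAS_MAGIC + str(len(ts_bytes)).encode() + b"\n" + ts_bytes + xmi_bytes


def unpack_cas(data: bytes) -> tuple:
    if not data.startswith(_CAS_MAGIC):
        raise ConversionError("not a packed CAS byte stream")
    rest = data[len(_CAS_MAGIC):]
    nl = rest.index(b"\n")
    n = int(rest[:nl])
    body = rest[nl + 1:]
    return body[:n], body[n:]


# ---------------------------------------------------------------------------
# to_hub / from_hub
# ---------------------------------------------------------------------------

def _check_format(fmt: str) -> None:
    if fmt not in FORMATS:
        raise ConversionError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def to_hub(
    data: bytes, fmt: str, opts: Optional[ConversionOptions] = None
) -> InteropDocument:
    """Read serialized bytes and fully structure them in the hub model:
    provenance attributes become views again, link-relation paths become
    chains, dotted attributes become nested features."""
    _check_format(fmt)
    opts = opts or ConversionOptions()
    if fmt == "pubann":
        pub = _pubann.read_pubann(data, opts)
        doc = _pubann.lift_pubann(pub, opts)
        doc = expand_views(doc, opts)
        doc = decode_chains(doc, opts)
        return doc
    if fmt == "lif":
        return _lif.lift_lif(_lif.read_lif(data), opts)
    ts_bytes, xmi_bytes = unpack_cas(data)
    return _xmi.lift_cas(_xmi.read_xmi(ts_bytes, xmi_bytes, strict=opts.strict), opts)


def from_hub(
    doc: InteropDocument, fmt: str, opts: Optional[ConversionOptions] = None
) -> ConversionResult:
    """Apply the target's rewrite sequence and serialize.  Returns the
    bytes together with the loss report.  In strict mode a
    discontinuous span targeted at the CAS model is a conversion error
    naming the construct; lenient mode drops it with a loss entry."""
    _check_format(fmt)
    opts = opts or ConversionOptions()
    if opts.renamer is not None:
        doc = apply_renamer(doc, opts.renamer)
    loss = predict_loss(doc, fmt, opts)
    if fmt == "cas" and opts.strict:
        for entry in loss:
            if entry.construct_kind == "discontinuous_span":
                raise ConversionError(
                    f"discontinuous span: {entry.construct_id} cannot be converted "
                    "to the CAS model (no provisions for discontinuous annotations); "
                    "use lenient mode to drop it with a loss record"
                )
    doc = project(doc, fmt, opts)
    if fmt == "pubann":
        doc = encode_chains(doc, opts)
        doc = collapse_views(doc, opts)
        data = _pubann.write_pubann(_pubann.lower_pubann(doc, opts))
    elif fmt == "lif":
        data = _lif.write_lif(_lif.lower_lif(doc, opts))
    else:
        ts_bytes, xmi_bytes = _xmi.write_xmi(_xmi.lower_cas(doc, opts))
        data = pack_cas(ts_bytes, xmi_bytes)
    return ConversionResult(data=data, loss=loss)


def convert(
    data: bytes,
    from_format: str,
    to_format: str,
    opts: Optional[ConversionOptions] = None,
) -> ConversionResult:
    """Convert serialized bytes between two of the three formats."""
    _check_format(from_format)
    _check_format(to_format)
    doc = to_hub(data, from_format, opts)
    result = from_hub(doc, to_format, opts)
    result.loss = [
        LossEntry(e.construct_kind, e.construct_id, (from_format, to_format), e.detail)
        for e in result.loss
    ]
    return result
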