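"""Reading and writing DAS GFF XML feature documents.

DAS GFF is the XML response format of a DAS ``features`` request and the
sole wire format of the writeback protocol, in both directions.  The
dialect implemented here is DAS 1.6: a ``DASGFF`` root holding one ``GFF``
element, which holds ``SEGMENT`` elements, which hold ``FEATURE`` elements
with ``TYPE``, ``METHOD``, ``START``, ``END``, ``SCORE``, ``ORIENTATION``,
``PHASE``, ``NOTE`` and ``LINK`` children.  Controlled-vocabulary term
identifiers travel in the ``cvId`` attribute of ``TYPE`` and ``METHOD``.

Coordinates are 1-based, fully closed amino-acid intervals: a feature
spanning residues 10..20 has ``start=10, end=20`` and includes both
endpoints.  Non-positional features (annotations of the whole protein)
are encoded with ``start = end = 0``, the DAS convention, and are exempt
from range checks.

Serialization is deterministic: the same document always yields
byte-identical UTF-8 output with an XML declaration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from lxml import etree

from .errors import SchemaError, StructuralError, ValidationError

log = logging.getLogger(__name__)

#: Score value meaning "not applicable"; serialized as the literal "-".
SCORE_NA = None

ORIENTATIONS = ("+", "-", "0")
PHASES = ("0", "1", "2", "-")


@dataclass(frozen=True)
class Feature:
    """One positional protein annotation — the unit being edited.

    ``type_id``/``method_id`` carry the human-entered term text;
    ``type_cvid``/``method_cvid`` carry the ontology term identifier
    (``cvId`` attribute) or the empty string when none was chosen.
    ``score`` is ``None`` when not applicable.  ``orientation`` and
    ``phase`` are genomic leftovers; for proteins they default to the
    not-applicable tokens ``"0"`` and ``"-"`` (see
    :func:`daswriteback.validation.apply_protein_defaults`).
    """

    feature_id: str
    label: str = ""
    type_id: str = ""
    type_cvid: str = ""
    type_category: str = ""
    method_id: str = ""
    method_cvid: str = ""
    start: int = 0
    end: int = 0
    score: float | None = SCORE_NA
    orientation: str = "0"
    phase: str = "-"
    notes: tuple[str, ...] = ()
    links: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        # tolerate lists from callers; store hashable tuples
        object.__setattr__(self, "notes", tuple(self.notes))
        object.__setattr__(self, "links", tuple(tuple(l) for l in self.links))

    @property
    def positional(self) -> bool:
        return not (self.start == 0 and self.end == 0)

    def check(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        if not self.feature_id:
            raise ValidationError("feature_id must be non-empty")
        if self.positional and not (1 <= self.start <= self.end):
            raise ValidationError(
                f"feature {self.feature_id!r}: positional features require "
                f"1 <= start <= end, got start={self.start} end={self.end}"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"feature {self.feature_id!r}: orientation {self.orientation!r} "
                f"not in {ORIENTATIONS}"
            )
        if self.phase not in PHASES:
            raise ValidationError(
                f"feature {self.feature_id!r}: phase {self.phase!r} not in {PHASES}"
            )

    def with_notes(self, notes) -> "Feature":
        return replace(self, notes=tuple(notes))


@dataclass(frozen=True)
class Segment:
    """The DAS addressing unit: a protein identified by accession.

    ``sequence_length`` is the full protein length; it equals ``stop``
    when the document covers the whole sequence (the usual case).
    """

    segment_id: str
    start: int = 1
    stop: int = 1
    version_label: str = ""
    sequence_length: int = 0  # 0 → defaults to stop

    def __post_init__(self):
        if self.sequence_length == 0:
            object.__setattr__(self, "sequence_length", self.stop)

    def check(self) -> None:
        if not self.segment_id:
            raise ValidationError("segment_id must be non-empty")
        if not (1 <= self.start <= self.stop <= self.sequence_length):
            raise ValidationError(
                f"segment {self.segment_id!r}: require 1 <= start <= stop <= "
                f"sequence_length, got {self.start}, {self.stop}, "
                f"{self.sequence_length}"
            )


@dataclass(frozen=True)
class FeatureDocument:
    """A DAS GFF document: ordered segments, each with ordered features."""

    source_href: str = ""
    segments: tuple[tuple[Segment, tuple[Feature, ...]], ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self,
            "segments",
            tuple((seg, tuple(feats)) for seg, feats in self.segments),
        )

    def check(self) -> None:
        seen = set()
        for seg, feats in self.segments:
            seg.check()
            if seg.segment_id in seen:
                raise ValidationError(f"duplicate segment id {seg.segment_id!r}")
            seen.add(seg.segment_id)
            for f in feats:
                f.check()

    def features_for(self, segment_id: str) -> tuple[Feature, ...]:
        for seg, feats in self.segments:
            if seg.segment_id == segment_id:
                return feats
        return ()


# ---------------------------------------------------------------------------
# parsing

_KNOWN_FEATURE_CHILDREN = {
    "TYPE", "METHOD", "START", "END", "SCORE", "ORIENTATION", "PHASE",
    "NOTE", "LINK",
}


def _text(el) -> str:
    return (el.text or "").strip()


def parse_document(xml_text: str | bytes,
                   strict: bool = True) -> FeatureDocument:
    """Parse a DAS GFF XML document into a :class:`FeatureDocument`.

    Unknown child elements are ignored with a logged warning.  Raises
    :class:`StructuralError` for malformed XML and :class:`SchemaError`
    when a mandatory element or attribute (root, segment id, feature id)
    is missing.  With ``strict`` (the default) every feature must satisfy
    the Feature invariants; ``strict=False`` accepts features with bad
    coordinates or enum tokens so a validator can report on them.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise StructuralError(f"malformed XML: {exc}") from exc

    if root.tag != "DASGFF":
        raise SchemaError(f"expected root element DASGFF, got {root.tag!r}")
    gff = root.find("GFF")
    if gff is None:
        raise SchemaError("missing mandatory element DASGFF/GFF")

    source_href = gff.get("href", "")
    segments = []
    for seg_el in gff.findall("SEGMENT"):
        seg_id = seg_el.get("id")
        if not seg_id:
            raise SchemaError("DASGFF/GFF/SEGMENT missing mandatory attribute id")
        stop = int(seg_el.get("stop", "1"))
        segment = Segment(
            segment_id=seg_id,
            start=int(seg_el.get("start", "1")),
            stop=stop,
            version_label=seg_el.get("version", ""),
            sequence_length=int(seg_el.get("sequence_length", stop)),
        )
        features = tuple(
            _parse_feature(f_el, seg_id, strict)
            for f_el in seg_el.findall("FEATURE")
        )
        segments.append((segment, features))
    return FeatureDocument(source_href=source_href, segments=tuple(segments))


def _parse_feature(f_el, seg_id: str, strict: bool = True) -> Feature:
    fid = f_el.get("id")
    if not fid:
        raise SchemaError(
            f"DASGFF/GFF/SEGMENT[@id={seg_id!r}]/FEATURE missing mandatory "
            "attribute id"
        )
    kw: dict = {
        "feature_id": fid,
        "label": f_el.get("label", ""),
    }
    notes: list[str] = []
    links: list[tuple[str, str]] = []
    for child in f_el:
        tag = child.tag
        if tag == "TYPE":
            kw["type_id"] = child.get("id", _text(child))
            kw["type_cvid"] = child.get("cvId", "")
            kw["type_category"] = child.get("category", "")
        elif tag == "METHOD":
            kw["method_id"] = child.get("id", _text(child))
            kw["method_cvid"] = child.get("cvId", "")
        elif tag == "START":
            kw["start"] = int(_text(child))
        elif tag == "END":
            kw["end"] = int(_text(child))
        elif tag == "SCORE":
            txt = _text(child)
            kw["score"] = None if txt in ("-", "") else float(txt)
        elif tag == "ORIENTATION":
            kw["orientation"] = _text(child) or "0"
        elif tag == "PHASE":
            kw["phase"] = _text(child) or "-"
        elif tag == "NOTE":
            notes.append(child.text or "")
        elif tag == "LINK":
            links.append((child.get("href", ""), _text(child)))
        elif isinstance(tag, str):  # skip comments/PIs silently
            log.warning("ignoring unknown element %s under FEATURE %r", tag, fid)
    kw["notes"] = tuple(notes)
    kw["links"] = tuple(links)
    feature = Feature(**kw)
    if strict:
        feature.check()
    return feature


# ---------------------------------------------------------------------------
# serialization


def serialize_document(doc: FeatureDocument) -> str:
    """Serialize to DAS 1.6 GFF XML with deterministic byte output.

    Element and attribute order is fixed, the XML declaration is always
    emitted, and the encoding is UTF-8; serializing the same document
    twice yields byte-identical strings.  Raises
    :class:`~daswriteback.errors.ValidationError` before emitting anything
    if the document violates an invariant.
    """
    doc.check()
    root = etree.Element("DASGFF")
    gff = etree.SubElement(root, "GFF")
    if doc.source_href:
        gff.set("href", doc.source_href)
    for seg, feats in doc.segments:
        seg_el = etree.SubElement(gff, "SEGMENT")
        seg_el.set("id", seg.segment_id)
        seg_el.set("start", str(seg.start))
        seg_el.set("stop", str(seg.stop))
        if seg.version_label:
            seg_el.set("version", seg.version_label)
        if seg.sequence_length != seg.stop:
            seg_el.set("sequence_length", str(seg.sequence_length))
        for f in feats:
            _serialize_feature(seg_el, f)
    body = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    return body.decode("utf-8")


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "-"
    return repr(score)


def _serialize_feature(seg_el, f: Feature) -> None:
    f_el = etree.SubElement(seg_el, "FEATURE")
    f_el.set("id", f.feature_id)
    if f.label:
        f_el.set("label", f.label)
    type_el = etree.SubElement(f_el, "TYPE")
    type_el.set("id", f.type_id)
    if f.type_cvid:
        type_el.set("cvId", f.type_cvid)
    if f.type_category:
        type_el.set("category", f.type_category)
    type_el.text = f.type_id
    method_el = etree.SubElement(f_el, "METHOD")
    method_el.set("id", f.method_id)
    if f.method_cvid:
        method_el.set("cvId", f.method_cvid)
    method_el.text = f.method_id
    etree.SubElement(f_el, "START").text = str(f.start)
    etree.SubElement(f_el, "END").text = str(f.end)
    etree.SubElement(f_el, "SCORE").text = _fmt_score(f.score)
    etree.SubElement(f_el, "ORIENTATION").text = f.orientation
    etree.SubElement(f_el, "PHASE").text = f.phase
    for note in f.notes:
        etree.SubElement(f_el, "NOTE").text = note
    for href, label in f.links:
        link_el = etree.SubElement(f_el, "LINK")
        link_el.set("href", href)
        link_el.text = label
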