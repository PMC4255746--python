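"""BioC XML interchange: data model, reader, writer, offset validation.

BioC is a lightweight XML format for biomedical text-mining data: a
collection of documents, each split into passages (title, abstract, ...)
and optionally sentences, with annotations anchored to the text by
document-relative character offsets and relations linking annotation ids.
All elements carry an open string->string "infon" map for metadata.

Offsets throughout are 0-based *character* counts from the start of the
document text (the concatenation of passage texts at their declared
offsets).  Two serialization modes are supported:

* ``standoff`` — annotations are sibling elements with explicit
  offset/length locations (the usual BioC layout);
* ``inline`` — annotations are embedded as ``<mark>`` elements wrapping
  the covered span inside the text, with infons as XML attributes.

Both modes re-parse to the same annotation set; nested/overlapping spans
in inline mode are rejected unless a longest-wins policy is requested.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

from lxml import etree

__all__ = [
    "BioCAnnotation",
    "BioCCollection",
    "BioCDocument",
    "BioCLocation",
    "BioCPassage",
    "BioCRelation",
    "BioCSentence",
    "BioCValidationError",
    "Violation",
    "read_bioc",
    "segment_passage",
    "validate_offsets",
    "write_bioc",
]

_SENTENCE_BOUNDARY = re.compile(r"(?<=[.!?])\s+")


class BioCValidationError(ValueError):
    """Structurally valid XML that violates the BioC data contract."""


@dataclass(frozen=True)
class BioCLocation:
    offset: int
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class BioCAnnotation:
    id: str
    infons: dict = field(default_factory=dict)
    locations: list = field(default_factory=list)  # list[BioCLocation]
    text: str = ""

    @property
    def offset(self) -> int:
        return self.locations[0].offset

    @property
    def length(self) -> int:
        return self.locations[0].length

    @property
    def end(self) -> int:
        return self.locations[0].end

    def span(self) -> tuple:
        return (self.offset, self.length)


@dataclass
class BioCRelation:
    id: str
    infons: dict = field(default_factory=dict)
    nodes: list = field(default_factory=list)  # list[(refid, role)]


@dataclass
class BioCSentence:
    offset: int
    text: str = ""
    infons: dict = field(default_factory=dict)
    annotations: list = field(default_factory=list)
    index: int = 0  # 0-based ordinal within the document, dense

    @property
    def end(self) -> int:
        return self.offset + len(self.text)


@dataclass
class BioCPassage:
    offset: int
    text: str = ""
    infons: dict = field(default_factory=dict)
    sentences: list = field(default_factory=list)
    annotations: list = field(default_factory=list)
    relations: list = field(default_factory=list)

    @property
    def effective_text(self) -> str:
        """Passage text, reconstructed from sentences when only they carry it."""
        if self.text:
            return self.text
        if not self.sentences:
            return ""
        end = max(s.end for s in self.sentences) - self.offset
        buf = [" "] * end
        for s in self.sentences:
            start = s.offset - self.offset
            buf[start : start + len(s.text)] = s.text
        return "".join(buf)

    @property
    def end(self) -> int:
        return self.offset + len(self.effective_text)


@dataclass
class BioCDocument:
    id: str
    infons: dict = field(default_factory=dict)
    passages: list = field(default_factory=list)

    def text(self) -> str:
        """Full document text with passage gaps padded by spaces."""
        if not self.passages:
            return ""
        end = max(p.end for p in self.passages)
        buf = [" "] * end
        for p in self.passages:
            t = p.effective_text
            buf[p.offset : p.offset + len(t)] = t
        return "".join(buf)

    def sentences(self) -> Iterator[BioCSentence]:
        for p in self.passages:
            yield from p.sentences

    def annotations(self) -> Iterator[BioCAnnotation]:
        for p in self.passages:
            yield from p.annotations
            for s in p.sentences:
                yield from s.annotations

    def relations(self) -> Iterator[BioCRelation]:
        for p in self.passages:
            yield from p.relations

    def reindex_sentences(self) -> None:
        """Assign dense 0-based sentence ordinals across passages."""
        for i, s in enumerate(self.sentences()):
            s.index = i


@dataclass
class BioCCollection:
    source: str = ""
    date: str = ""
    key: str = ""
    infons: dict = field(default_factory=dict)
    documents: list = field(default_factory=list)


@dataclass(frozen=True)
class Violation:
    kind: str  # offset-mismatch | dangling-node | duplicate-id | ...
    document_id: str
    element_id: str
    message: str


# ---------------------------------------------------------------------------
# Reading

def _infons(elem) -> dict:
    return {e.get("key"): (e.text or "") for e in elem.findall("infon")}


def _int(elem, tag: str, context: str) -> int:
    node = elem.find(tag)
    value = int(node.text) if node is not None and node.text else 0
    if value < 0:
        raise BioCValidationError(f"negative {tag} in {context}")
    return value


def _read_annotation(elem, context: str) -> BioCAnnotation:
    ann = BioCAnnotation(id=elem.get("id", ""), infons=_infons(elem))
    for loc in elem.findall("location"):
        offset = int(loc.get("offset"))
        length = int(loc.get("length"))
        if offset < 0 or length < 0:
            raise BioCValidationError(
                f"negative offset/length on annotation '{ann.id}' in {context}"
            )
        ann.locations.append(BioCLocation(offset, length))
    node = elem.find("text")
    ann.text = node.text or "" if node is not None else ""
    return ann


def _read_inline_text(elem, base_offset: int, context: str):
    """Reconstruct (plain_text, annotations) from a <text> with <mark> children."""
    parts: list = []
    annotations: list = []
    pos = base_offset

    def push(s: Optional[str]) -> None:
        nonlocal pos
        if s:
            parts.append(s)
            pos += len(s)

    push(elem.text)
    for mark in elem:
        if mark.tag != "mark":
            raise BioCValidationError(f"unexpected inline element <{mark.tag}> in {context}")
        covered = mark.text or ""
        infons = {k: v for k, v in mark.attrib.items() if k != "id"}
        annotations.append(
            BioCAnnotation(
                id=mark.get("id", ""),
                infons=infons,
                locations=[BioCLocation(pos, len(covered))],
                text=covered,
            )
        )
        push(covered)
        push(mark.tail)
    return "".join(parts), annotations


def _read_text_and_annotations(parent, base_offset: int, context: str):
    """Read <text> (plain or inline-marked) plus sibling <annotation>s."""
    text = ""
    annotations: list = []
    node = parent.find("text")
    if node is not None:
        if len(node):  # has <mark> children -> inline mode
            text, annotations = _read_inline_text(node, base_offset, context)
        else:
            text = node.text or ""
    for a in parent.findall("annotation"):
        annotations.append(_read_annotation(a, context))
    return text, annotations


def _read_relation(elem, context: str) -> BioCRelation:
    rel = BioCRelation(id=elem.get("id", ""), infons=_infons(elem))
    for node in elem.findall("node"):
        rel.nodes.append((node.get("refid", ""), node.get("role", "")))
    return rel


def read_bioc(source: Union[str, bytes, io.IOBase]) -> BioCCollection:
    """Parse a BioC XML collection from a string, bytes, stream, or path.

    Raises ``lxml.etree.XMLSyntaxError`` (with line information) on
    malformed XML and :class:`BioCValidationError` on negative offsets or
    relation nodes that do not resolve to an annotation in the same
    document.
    """
    if isinstance(source, str) and "<" in source:
        root = etree.fromstring(source.encode("utf-8"))
    elif isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(source).getroot()

    def text_of(tag: str) -> str:
        node = root.find(tag)
        return node.text or "" if node is not None else ""

    coll = BioCCollection(
        source=text_of("source"),
        date=text_of("date"),
        key=text_of("key"),
        infons=_infons(root),
    )
    seen_ids = set()
    for delem in root.findall("document"):
        doc_id_node = delem.find("id")
        doc = BioCDocument(
            id=doc_id_node.text or "" if doc_id_node is not None else "",
            infons=_infons(delem),
        )
        if doc.id in seen_ids:
            raise BioCValidationError(f"duplicate document id '{doc.id}'")
        seen_ids.add(doc.id)
        for pelem in delem.findall("passage"):
            context = f"document '{doc.id}'"
            passage = BioCPassage(offset=_int(pelem, "offset", context), infons=_infons(pelem))
            passage.text, passage.annotations = _read_text_and_annotations(
                pelem, passage.offset, context
            )
            for selem in pelem.findall("sentence"):
                sent = BioCSentence(offset=_int(selem, "offset", context), infons=_infons(selem))
                sent.text, sent.annotations = _read_text_and_annotations(
                    selem, sent.offset, context
                )
                passage.sentences.append(sent)
            for relem in pelem.findall("relation"):
                passage.relations.append(_read_relation(relem, context))
            doc.passages.append(passage)
        doc.reindex_sentences()
        known = {a.id for a in doc.annotations()}
        for rel in doc.relations():
            for refid, _role in rel.nodes:
                if refid not in known:
                    raise BioCValidationError(
                        f"relation '{rel.id}' in document '{doc.id}' references "
                        f"unknown annotation '{refid}'"
                    )
        coll.documents.append(doc)
    return coll


# ---------------------------------------------------------------------------
# Writing

def _write_infons(parent, infons: dict) -> None:
    for key in infons:
        e = etree.SubElement(parent, "infon", key=key)
        e.text = infons[key]


def _write_annotation(parent, ann: BioCAnnotation) -> None:
    e = etree.SubElement(parent, "annotation", id=ann.id)
    _write_infons(e, ann.infons)
    for loc in ann.locations:
        etree.SubElement(e, "location", offset=str(loc.offset), length=str(loc.length))
    etree.SubElement(e, "text").text = ann.text


def _write_inline_text(parent, text: str, base_offset: int, annotations: Iterable,
                       overlap_policy: str) -> None:
    anns = sorted(annotations, key=lambda a: (a.offset, -a.length, a.id))
    selected: list = []
    for a in anns:
        clash = [b for b in selected if a.offset < b.end and b.offset < a.end]
        if clash:
            if overlap_policy != "longest-wins":
                raise BioCValidationError(
                    f"overlapping annotations in inline mode: '{a.id}' vs "
                    f"'{clash[0].id}' (set overlap policy 'longest-wins')"
                )
            continue  # sort order guarantees the kept one is the longest
        selected.append(a)
    node = etree.SubElement(parent, "text")
    cursor = 0
    last = node
    for a in selected:
        start = a.offset - base_offset
        chunk = text[cursor:start]
        if last is node:
            node.text = chunk
        else:
            last.tail = chunk
        mark = etree.SubElement(node, "mark", id=a.id)
        for k, v in a.infons.items():
            mark.set(k, v)
        mark.text = a.text
        cursor = start + a.length
        last = mark
    tail = text[cursor:]
    if last is node:
        node.text = tail
    else:
        last.tail = tail


def _write_text_unit(parent, text: str, base_offset: int, annotations: list,
                     mode: str, overlap_policy: str) -> None:
    if mode == "inline":
        _write_inline_text(parent, text, base_offset, annotations, overlap_policy)
    else:
        etree.SubElement(parent, "text").text = text
        for a in annotations:
            _write_annotation(parent, a)


def write_bioc(collection: BioCCollection, mode: str = "standoff",
               overlap_policy: str = "error") -> str:
    """Serialize a collection to BioC XML text.

    ``mode='standoff'`` round-trips field-for-field through
    :func:`read_bioc`; ``mode='inline'`` embeds ``<mark>`` elements around
    covered spans (overlaps error out unless ``overlap_policy='longest-wins'``).
    """
    if mode not in ("standoff", "inline"):
        raise ValueError(f"unknown mode {mode!r}")
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = collection.source
    etree.SubElement(root, "date").text = collection.date
    etree.SubElement(root, "key").text = collection.key
    _write_infons(root, collection.infons)
    for doc in collection.documents:
        delem = etree.SubElement(root, "document")
        etree.SubElement(delem, "id").text = doc.id
        _write_infons(delem, doc.infons)
        for p in doc.passages:
            pelem = etree.SubElement(delem, "passage")
            _write_infons(pelem, p.infons)
            etree.SubElement(pelem, "offset").text = str(p.offset)
            _write_text_unit(pelem, p.text, p.offset, p.annotations, mode, overlap_policy)
            for s in p.sentences:
                selem = etree.SubElement(pelem, "sentence")
                _write_infons(selem, s.infons)
                etree.SubElement(selem, "offset").text = str(s.offset)
                _write_text_unit(selem, s.text, s.offset, s.annotations, mode, overlap_policy)
            for rel in p.relations:
                relem = etree.SubElement(pelem, "relation", id=rel.id)
                _write_infons(relem, rel.infons)
                for refid, role in rel.nodes:
                    etree.SubElement(relem, "node", refid=refid, role=role)
    return etree.tostring(root, encoding="unicode", pretty_print=True)


# ---------------------------------------------------------------------------
# Sentence segmentation

def segment_passage(passage: BioCPassage) -> None:
    """Split an unsegmented passage into sentences (in place).

    Input segmentation, when present, is always preserved; otherwise a
    simple rule (sentence-final punctuation followed by whitespace)
    applies, and text without any boundary becomes a single sentence.
    Sentence offsets stay document-relative; the passage text is kept, so
    the sentences-with-gaps reconstruction contract holds trivially.
    """
    if passage.sentences or not passage.text:
        return
    pos = 0
    for m in _SENTENCE_BOUNDARY.finditer(passage.text):
        chunk = passage.text[pos : m.start()]
        if chunk.strip():
            passage.sentences.append(
                BioCSentence(offset=passage.offset + pos, text=chunk)
            )
        pos = m.end()
    tail = passage.text[pos:]
    if tail.strip():
        passage.sentences.append(BioCSentence(offset=passage.offset + pos, text=tail))


# ---------------------------------------------------------------------------
# Validation

def validate_offsets(collection: BioCCollection) -> list:
    """Check every annotation span against the document text it claims to cover.

    Returns violation records (empty list == valid); never raises —
    violations are data, not exceptions.
    """
    violations: list = []
    for doc in collection.documents:
        text = doc.text()
        for ann in doc.annotations():
            # text is the concatenation of the (possibly discontinuous) spans
            covered = "".join(text[loc.offset : loc.end] for loc in ann.locations)
            out_of_range = any(loc.end > len(text) for loc in ann.locations)
            if covered != ann.text or out_of_range:
                violations.append(
                    Violation(
                        kind="offset-mismatch",
                        document_id=doc.id,
                        element_id=ann.id,
                        message=(
                            f"annotation '{ann.id}' claims {ann.text!r} at "
                            f"{[(l.offset, l.length) for l in ann.locations]} "
                            f"but document has {covered!r}"
                        ),
                    )
                )
        known = {a.id for a in doc.annotations()}
        for rel in doc.relations():
            for refid, _role in rel.nodes:
                if refid not in known:
                    violations.append(
                        Violation(
                            kind="dangling-node",
                            document_id=doc.id,
                            element_id=rel.id,
                            message=f"relation '{rel.id}' references missing annotation '{refid}'",
                        )
                    )
    return violations
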