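"""Reading and writing PubTator text and BioC XML.

Internal offsets are whole-document, 0-based, over ``title + "\\n" +
abstract`` — the convention PubTator files use. Composite mentions
serialize as a single annotation whose identifiers are semicolon-joined.
Species annotations round-trip through the same files with type
``Species`` and the taxid as identifier.
"""

from __future__ import annotations

import io
from lxml import etree

from .types import Document, Mention, MentionType, SpeciesTag


class FormatError(ValueError):
    pass


# ----------------------------------------------------------------- PubTator

def read_pubtator(stream) -> list[Document]:
    """Parse a PubTator file: ``PMID|t|title``, ``PMID|a|abstract``, then
    tab-separated annotation lines, documents separated by blank lines.
    Annotation text is validated against the offsets."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    docs: list[Document] = []
    doc: Document | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            if doc is not None:
                docs.append(doc)
                doc = None
            continue
        if "|t|" in line or "|a|" in line:
            pmid, kind, text = line.split("|", 2)
            if kind == "t":
                if doc is not None:
                    docs.append(doc)
                doc = Document(doc_id=pmid, title=text, abstract="")
            elif kind == "a":
                if doc is None or doc.doc_id != pmid:
                    raise FormatError(
                        f"line {lineno}: abstract for unknown document {pmid}")
                doc.abstract = text
            else:
                raise FormatError(f"line {lineno}: malformed header {line!r}")
            continue
        parts = line.split("\t")
        if doc is None or parts[0] != doc.doc_id:
            raise FormatError(f"line {lineno}: annotation outside document")
        if len(parts) not in (5, 6):
            raise FormatError(
                f"line {lineno}: expected 5 or 6 tab-separated fields")
        _, start_s, end_s, text, typ = parts[:5]
        start, end = int(start_s), int(end_s)
        slice_ = doc.text[start:end]
        if slice_ != text:
            raise FormatError(
                f"line {lineno}: annotation text {text!r} does not match "
                f"document slice {slice_!r}")
        ids = [i for i in parts[5].split(";") if i] if len(parts) == 6 else []
        if typ == "Species":
            doc.species_tags.append(SpeciesTag(
                start=start, end=end, name=text,
                taxid=ids[0] if ids else ""))
        else:
            doc.mentions.append(Mention(
                start=start, end=end, text=text, type=MentionType(typ),
                ids=ids))
            doc.doc_ids.update(ids)
    if doc is not None:
        docs.append(doc)
    return docs


def write_pubtator(docs: list[Document], stream) -> None:
    """Inverse of :func:`read_pubtator`; each document block ends with one
    blank line so write(read(x)) is byte-identical for canonical files."""
    close = False
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        stream = open(stream, "w", encoding="utf-8")
        close = True
    try:
        for doc in docs:
            stream.write(f"{doc.doc_id}|t|{doc.title}\n")
            stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            rows = [(m.start, m.end, m.text, m.type.value, ";".join(m.ids))
                    for m in doc.mentions]
            rows += [(t.start, t.end, t.name, "Species", t.taxid)
                     for t in doc.species_tags]
            for start, end, text, typ, ids in sorted(rows):
                line = f"{doc.doc_id}\t{start}\t{end}\t{text}\t{typ}"
                if ids:
                    line += f"\t{ids}"
                stream.write(line + "\n")
            stream.write("\n")
    finally:
        if close:
            stream.close()


def pubtator_dumps(docs: list[Document]) -> str:
    buf = io.StringIO()
    write_pubtator(docs, buf)
    return buf.getvalue()


# --------------------------------------------------------------------- BioC

def _passage_for(doc: Document, offset: int) -> str:
    return "title" if offset < len(doc.title) else "abstract"


def write_bioc(docs: list[Document], stream) -> None:
    """BioC XML with one passage per title and abstract; annotation offsets
    stay whole-document (each passage carries its own offset)."""
    collection = etree.Element("collection")
    etree.SubElement(collection, "source").text = "genenorm"
    etree.SubElement(collection, "date").text = ""
    etree.SubElement(collection, "key").text = ""
    ann_counter = 0
    for doc in docs:
        d = etree.SubElement(collection, "document")
        etree.SubElement(d, "id").text = doc.doc_id
        passages = {
            "title": (0, doc.title),
            "abstract": (len(doc.title) + 1, doc.abstract),
        }
        rows = [(m.start, m.end, m.text, m.type.value, m.ids)
                for m in doc.mentions]
        rows += [(t.start, t.end, t.name, "Species",
                  [t.taxid] if t.taxid else []) for t in doc.species_tags]
        for name, (p_off, p_text) in passages.items():
            if name == "abstract" and not p_text:
                continue
            p = etree.SubElement(d, "passage")
            infon = etree.SubElement(p, "infon", key="type")
            infon.text = name
            etree.SubElement(p, "offset").text = str(p_off)
            etree.SubElement(p, "text").text = p_text
            for start, end, text, typ, ids in sorted(
                    r for r in rows
                    if _passage_for(doc, r[0]) == name):
                ann_counter += 1
                a = etree.SubElement(p, "annotation", id=str(ann_counter))
                t_infon = etree.SubElement(a, "infon", key="type")
                t_infon.text = typ
                if ids:
                    id_infon = etree.SubElement(a, "infon", key="identifier")
                    id_infon.text = ";".join(ids)
                etree.SubElement(a, "location", offset=str(start),
                                 length=str(end - start))
                etree.SubElement(a, "text").text = text
    data = etree.tostring(collection, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8")
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        with open(stream, "wb") as fh:
            fh.write(data)
    else:
        stream.write(data if "b" in getattr(stream, "mode", "b")
                     else data.decode("utf-8"))


def read_bioc(stream) -> list[Document]:
    if isinstance(stream, str) and stream.lstrip().startswith("<"):
        root = etree.fromstring(stream.encode("utf-8"))
    else:
        root = etree.parse(stream).getroot()
    docs: list[Document] = []
    for d in root.findall("document"):
        doc = Document(doc_id=d.findtext("id"), title="", abstract="")
        for p in d.findall("passage"):
            ptype = None
            for infon in p.findall("infon"):
                if infon.get("key") == "type":
                    ptype = infon.text
            text = p.findtext("text") or ""
            if ptype == "title":
                doc.title = text
            elif ptype == "abstract":
                doc.abstract = text
            else:
                raise FormatError(f"unknown passage type {ptype!r}")
            for a in p.findall("annotation"):
                typ = ids = None
                for infon in a.findall("infon"):
                    if infon.get("key") == "type":
                        typ = infon.text
                    elif infon.get("key") == "identifier":
                        ids = infon.text
                loc = a.find("location")
                start = int(loc.get("offset"))
                end = start + int(loc.get("length"))
                a_text = a.findtext("text") or ""
                id_list = [i for i in (ids or "").split(";") if i]
                if typ == "Species":
                    doc.species_tags.append(SpeciesTag(
                        start=start, end=end, name=a_text,
                        taxid=id_list[0] if id_list else ""))
                else:
                    doc.mentions.append(Mention(
                        start=start, end=end, text=a_text,
                        type=MentionType(typ), ids=id_list))
                    doc.doc_ids.update(id_list)
        doc.validate()
        docs.append(doc)
    return docs


def bioc_dumps(docs: list[Document]) -> str:
    buf = io.BytesIO()
    write_bioc(docs, buf)
    return buf.getvalue().decode("utf-8")
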