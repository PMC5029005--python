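"""Corpus I/O: BioC XML and the tab-separated annotation sheet.

BioC dialect
------------
``collection -> document (id = PMID) -> passage`` with one passage per
sentence (``offset`` = document-relative sentence start, ``text`` = sentence
string).  Entity mentions are ``annotation`` nodes with infons ``type``
(``plant``/``chemical``) and ``identifier`` (``namespace:value`` pairs joined
with ``|``, or ``NA``); locations are document-relative.  Corpus units are
``relation`` nodes with infons ``type`` (``POS``/``NEG``, or ``UNLABELED``
for candidate units), ``weak_trigger`` and ``strong_trigger``, plus two node
refs with roles ``plant`` and ``chemical``.  Extra infons (annotation
bookkeeping, model predictions) round-trip through
:attr:`~plantchem.model.CorpusUnit.provenance`.  Document-level infons
round-trip through :attr:`~plantchem.model.AbstractDoc.meta`.

Writing is deterministic: documents ordered by pmid, annotations by span,
relations by (plant, chemical) span — so ``write(read(f))`` is a
canonical form and re-reading it is lossless.

Annotation sheet
----------------
UTF-8 TSV with exactly the 15 canonical columns::

    PlantName  P.ID  P.Off  P.Note  P.Check  ChemName  C.ID  C.Off  C.Note
    C.Check  Sentence  PMID  Label  WeakTrigger  StrongTrigger

Offsets are sentence-relative, 0-based half-open, serialized ``start:end``.
Empty/``NA`` trigger cells map to absent triggers; an empty Label cell is an
UNLABELED candidate unit.
"""

from __future__ import annotations

import csv
import io
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from lxml import etree

from .errors import CorpusParseError, IntegrityError, ValidationError
from .model import (
    AbstractDoc,
    CorpusUnit,
    EntityClass,
    EntityMention,
    Label,
    SentenceRecord,
)

__all__ = [
    "read_bioc",
    "write_bioc",
    "bioc_bytes",
    "export_sheet",
    "import_sheet",
    "iter_units",
    "docs_from_units",
    "SHEET_COLUMNS",
]

SHEET_COLUMNS = (
    "PlantName", "P.ID", "P.Off", "P.Note", "P.Check",
    "ChemName", "C.ID", "C.Off", "C.Note", "C.Check",
    "Sentence", "PMID", "Label", "WeakTrigger", "StrongTrigger",
)

_RESERVED_RELATION_INFONS = {"type", "weak_trigger", "strong_trigger"}


def _ids_to_str(ids: tuple[tuple[str, str], ...]) -> str:
    return "|".join(f"{ns}:{value}" for ns, value in ids) if ids else "NA"


def _ids_from_str(s: str) -> tuple[tuple[str, str], ...]:
    s = s.strip()
    if s in ("", "NA"):
        return ()
    out = []
    for chunk in s.split("|"):
        ns, sep, value = chunk.partition(":")
        if not sep:
            raise CorpusParseError(f"identifier {chunk!r} is not namespace:value")
        out.append((ns, value))
    return tuple(out)


def iter_units(docs: Iterable[AbstractDoc]) -> list[CorpusUnit]:
    """All corpus units of a document collection, in document order."""
    units: list[CorpusUnit] = []
    for doc in docs:
        for sent in doc.sentences:
            units.extend(getattr(sent, "units", []))
    return units


# ---------------------------------------------------------------------------
# BioC
# ---------------------------------------------------------------------------


def _infon(parent: etree._Element, key: str, value: str) -> None:
    el = etree.SubElement(parent, "infon", key=key)
    el.text = value


def write_bioc(docs: Sequence[AbstractDoc], target: str | Path | io.IOBase) -> None:
    """Serialize a validated document collection as BioC XML."""
    payload = bioc_bytes(docs)
    if isinstance(target, (str, Path)):
        Path(target).write_bytes(payload)
    else:
        target.write(payload)


def bioc_bytes(docs: Sequence[AbstractDoc]) -> bytes:
    for doc in docs:
        doc.validate()
        for unit in iter_units([doc]):
            unit.validate()
    collection = etree.Element("collection")
    etree.SubElement(collection, "source").text = "plantchem"
    etree.SubElement(collection, "date")
    etree.SubElement(collection, "key")
    for doc in sorted(docs, key=lambda d: d.pmid):
        doc_el = etree.SubElement(collection, "document")
        etree.SubElement(doc_el, "id").text = doc.pmid
        for key in sorted(doc.meta):
            _infon(doc_el, key, doc.meta[key])
        for sent in doc.sentences:
            pas = etree.SubElement(doc_el, "passage")
            etree.SubElement(pas, "offset").text = str(sent.doc_offset)
            etree.SubElement(pas, "text").text = sent.text
            ann_ids: dict[tuple[int, int, EntityClass], str] = {}
            mentions = sorted(
                sent.mentions, key=lambda m: (m.start, m.end, m.entity_class.value)
            )
            for n, m in enumerate(mentions, start=1):
                ann_id = f"T{n}"
                ann_ids[(m.start, m.end, m.entity_class)] = ann_id
                ann = etree.SubElement(pas, "annotation", id=ann_id)
                _infon(ann, "type", m.entity_class.value)
                _infon(ann, "identifier", _ids_to_str(m.ids))
                etree.SubElement(
                    ann,
                    "location",
                    offset=str(sent.doc_offset + m.start),
                    length=str(m.end - m.start),
                )
                etree.SubElement(ann, "text").text = m.text
            units = sorted(
                getattr(sent, "units", []),
                key=lambda u: (u.plant.span, u.chemical.span),
            )
            for n, unit in enumerate(units, start=1):
                for mention in (unit.plant, unit.chemical):
                    key = (mention.start, mention.end, mention.entity_class)
                    if key not in ann_ids:
                        raise IntegrityError(
                            f"unit mention {mention.text!r} is not among the "
                            "sentence annotations"
                        )
                rel = etree.SubElement(pas, "relation", id=f"R{n}")
                _infon(rel, "type", unit.label.value)
                _infon(
                    rel,
                    "weak_trigger",
                    " ".join(unit.weak_trigger) if unit.weak_trigger else "NA",
                )
                _infon(rel, "strong_trigger", unit.strong_trigger or "NA")
                for key in sorted(unit.provenance):
                    if unit.provenance[key]:
                        _infon(rel, key, unit.provenance[key])
                plant_key = (unit.plant.start, unit.plant.end, EntityClass.PLANT)
                chem_key = (
                    unit.chemical.start,
                    unit.chemical.end,
                    EntityClass.CHEMICAL,
                )
                etree.SubElement(
                    rel, "node", refid=ann_ids[plant_key], role="plant"
                )
                etree.SubElement(
                    rel, "node", refid=ann_ids[chem_key], role="chemical"
                )
    return etree.tostring(
        collection,
        pretty_print=True,
        xml_declaration=True,
        encoding="UTF-8",
    )


def _read_infons(el: etree._Element) -> dict[str, str]:
    return {i.get("key"): (i.text or "") for i in el.findall("infon")}


def read_bioc(source: str | Path | io.IOBase) -> list[AbstractDoc]:
    """Parse a BioC XML file into documents with corpus units attached.

    Units live on ``sentence.units`` (a list plantchem attaches to each
    :class:`SentenceRecord`); :func:`iter_units` flattens them.
    """
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"malformed BioC XML: {exc}") from exc
    docs: list[AbstractDoc] = []
    for doc_el in tree.getroot().findall("document"):
        pmid = (doc_el.findtext("id") or "").strip()
        meta = _read_infons(doc_el)
        sentences: list[SentenceRecord] = []
        for pas in doc_el.findall("passage"):
            offset = int(pas.findtext("offset") or "0")
            text = pas.findtext("text") or ""
            sent = SentenceRecord(doc_offset=offset, text=text, pmid=pmid)
            by_id: dict[str, EntityMention] = {}
            for ann in pas.findall("annotation"):
                infons = _read_infons(ann)
                loc = ann.find("location")
                if loc is None:
                    raise CorpusParseError(
                        f"annotation {ann.get('id')!r} has no location"
                    )
                start = int(loc.get("offset")) - offset
                length = int(loc.get("length"))
                mention = EntityMention(
                    entity_class=EntityClass(infons.get("type", "")),
                    start=start,
                    end=start + length,
                    text=ann.findtext("text") or text[start : start + length],
                    ids=_ids_from_str(infons.get("identifier", "NA")),
                )
                mention.validate_against(text)
                by_id[ann.get("id")] = mention
            sent.mentions = sorted(
                by_id.values(), key=lambda m: (m.start, m.end, m.entity_class.value)
            )
            units: list[CorpusUnit] = []
            for rel in pas.findall("relation"):
                infons = _read_infons(rel)
                roles = {n.get("role"): n.get("refid") for n in rel.findall("node")}
                try:
                    plant = by_id[roles["plant"]]
                    chem = by_id[roles["chemical"]]
                except KeyError as exc:
                    raise IntegrityError(
                        f"relation {rel.get('id')!r} in {pmid} references a "
                        f"missing annotation id: {exc}"
                    ) from exc
                weak = infons.get("weak_trigger", "NA")
                strong = infons.get("strong_trigger", "NA")
                unit = CorpusUnit(
                    sentence=sent,
                    plant=plant,
                    chemical=chem,
                    label=Label(infons.get("type", "UNLABELED")),
                    weak_trigger=tuple(weak.split()) if weak not in ("", "NA") else None,
                    strong_trigger=strong if strong not in ("", "NA") else None,
                    provenance={
                        k: v
                        for k, v in infons.items()
                        if k not in _RESERVED_RELATION_INFONS
                    },
                )
                unit.validate()
                units.append(unit)
            sent.units = units  # type: ignore[attr-defined]
            sentences.append(sent)
        length = max(
            (s.doc_offset + len(s.text) for s in sentences), default=0
        )
        chars = [" "] * length
        for s in sentences:
            chars[s.doc_offset : s.doc_offset + len(s.text)] = s.text
        docs.append(
            AbstractDoc(pmid=pmid, text="".join(chars), sentences=sentences, meta=meta)
        )
    return docs


def docs_from_units(units: Sequence[CorpusUnit]) -> list[AbstractDoc]:
    """Group loose units into single-sentence-per-passage documents.

    Sentences are grouped by (pmid, text); each document's text is the
    concatenation of its sentences at their offsets.
    """
    sent_map: dict[tuple[str, int, str], SentenceRecord] = {}
    order: list[tuple[str, int, str]] = []
    for unit in units:
        key = (unit.sentence.pmid, unit.sentence.doc_offset, unit.sentence.text)
        if key not in sent_map:
            sent = SentenceRecord(
                doc_offset=unit.sentence.doc_offset,
                text=unit.sentence.text,
                pmid=unit.sentence.pmid,
            )
            sent.units = []  # type: ignore[attr-defined]
            sent_map[key] = sent
            order.append(key)
        sent = sent_map[key]
        for mention in (unit.plant, unit.chemical):
            if mention not in sent.mentions:
                sent.mentions.append(mention)
        rebound = CorpusUnit(
            sentence=sent,
            plant=unit.plant,
            chemical=unit.chemical,
            label=unit.label,
            weak_trigger=unit.weak_trigger,
            strong_trigger=unit.strong_trigger,
            provenance=dict(unit.provenance),
        )
        sent.units.append(rebound)  # type: ignore[attr-defined]
    docs: dict[str, AbstractDoc] = {}
    for key in order:
        sent = sent_map[key]
        sent.mentions.sort(key=lambda m: (m.start, m.end, m.entity_class.value))
        doc = docs.setdefault(
            sent.pmid, AbstractDoc(pmid=sent.pmid, text="", sentences=[])
        )
        doc.sentences.append(sent)
    for doc in docs.values():
        doc.sentences.sort(key=lambda s: s.doc_offset)
        length = max((s.doc_offset + len(s.text) for s in doc.sentences), default=0)
        chars = [" "] * length
        for s in doc.sentences:
            chars[s.doc_offset : s.doc_offset + len(s.text)] = s.text
        doc.text = "".join(chars)
    return list(docs.values())


# ---------------------------------------------------------------------------
# Annotation sheet
# ---------------------------------------------------------------------------


def _span_to_str(m: EntityMention) -> str:
    return f"{m.start}:{m.end}"


def _span_from_str(s: str, row: int) -> tuple[int, int]:
    try:
        start, _, end = s.partition(":")
        return int(start), int(end)
    except ValueError as exc:
        raise CorpusParseError(f"row {row}: offset {s!r} is not start:end") from exc


def export_sheet(
    units: Sequence[CorpusUnit], target: str | Path | TextIO | None = None
) -> str:
    """Serialize units as the 15-column TSV annotation sheet."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(SHEET_COLUMNS)
    for unit in units:
        unit.validate()
        prov = unit.provenance
        writer.writerow(
            [
                unit.plant.text,
                _ids_to_str(unit.plant.ids),
                _span_to_str(unit.plant),
                prov.get("p_note", ""),
                prov.get("p_check", ""),
                unit.chemical.text,
                _ids_to_str(unit.chemical.ids),
                _span_to_str(unit.chemical),
                prov.get("c_note", ""),
                prov.get("c_check", ""),
                unit.sentence.text,
                unit.sentence.pmid,
                "" if unit.label is Label.UNLABELED else unit.label.value,
                " ".join(unit.weak_trigger) if unit.weak_trigger else "",
                unit.strong_trigger or "",
            ]
        )
    text = buf.getvalue()
    if target is not None:
        if isinstance(target, (str, Path)):
            Path(target).write_text(text, encoding="utf-8")
        else:
            target.write(text)
    return text


def import_sheet(source: str | Path | TextIO) -> list[CorpusUnit]:
    """Parse an annotation sheet back into corpus units.

    Rows sharing (PMID, Sentence) share one :class:`SentenceRecord`.  POS
    rows must carry both triggers; offsets must match the sentence substring.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\t" not in source and "\n" not in source
    ):
        with open(source, encoding="utf-8") as fh:
            return import_sheet(fh)
    if isinstance(source, str):
        source = io.StringIO(source)
    reader = csv.reader(source, delimiter="\t")
    try:
        header = tuple(next(reader))
    except StopIteration:
        raise CorpusParseError("sheet is empty (no header row)") from None
    if header != SHEET_COLUMNS:
        raise CorpusParseError(
            f"sheet header {header!r} does not match the canonical column list"
        )
    sentences: dict[tuple[str, str], SentenceRecord] = {}
    units: list[CorpusUnit] = []
    for row_num, row in enumerate(reader, start=2):
        if not row or all(not cell for cell in row):
            continue
        if len(row) != len(SHEET_COLUMNS):
            raise CorpusParseError(
                f"row {row_num}: expected {len(SHEET_COLUMNS)} columns, got {len(row)}"
            )
        rec = dict(zip(SHEET_COLUMNS, row))
        sent_key = (rec["PMID"], rec["Sentence"])
        sent = sentences.setdefault(
            sent_key,
            SentenceRecord(doc_offset=0, text=rec["Sentence"], pmid=rec["PMID"]),
        )

        def build_mention(
            cls: EntityClass, name_col: str, id_col: str, off_col: str
        ) -> EntityMention:
            start, end = _span_from_str(rec[off_col], row_num)
            mention = EntityMention(
                entity_class=cls,
                start=start,
                end=end,
                text=rec[name_col],
                ids=_ids_from_str(rec[id_col]),
            )
            if sent.text[start:end] != mention.text:
                raise IntegrityError(
                    f"row {row_num}: {off_col} substring "
                    f"{sent.text[start:end]!r} does not equal {name_col} "
                    f"{mention.text!r}"
                )
            if mention not in sent.mentions:
                sent.mentions.append(mention)
            return mention

        plant = build_mention(EntityClass.PLANT, "PlantName", "P.ID", "P.Off")
        chem = build_mention(EntityClass.CHEMICAL, "ChemName", "C.ID", "C.Off")
        label_cell = rec["Label"].strip()
        label = Label(label_cell) if label_cell else Label.UNLABELED
        weak_cell = rec["WeakTrigger"].strip()
        strong_cell = rec["StrongTrigger"].strip()
        unit = CorpusUnit(
            sentence=sent,
            plant=plant,
            chemical=chem,
            label=label,
            weak_trigger=tuple(weak_cell.split()) if weak_cell not in ("", "NA") else None,
            strong_trigger=strong_cell if strong_cell not in ("", "NA") else None,
            provenance={
                k: v
                for k, v in {
                    "p_note": rec["P.Note"],
                    "p_check": rec["P.Check"],
                    "c_note": rec["C.Note"],
                    "c_check": rec["C.Check"],
                }.items()
                if v
            },
        )
        try:
            unit.validate()
        except ValidationError as exc:
            raise ValidationError(f"row {row_num}: {exc}") from exc
        units.append(unit)
    for sent in sentences.values():
        sent.mentions.sort(key=lambda m: (m.start, m.end, m.entity_class.value))
    return units
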