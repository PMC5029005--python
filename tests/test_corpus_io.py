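import io

import pytest

from plantchem.corpus_io import (
    SHEET_COLUMNS,
    bioc_bytes,
    docs_from_units,
    export_sheet,
    import_sheet,
    iter_units,
    read_bioc,
    write_bioc,
)
from plantchem.errors import CorpusParseError, IntegrityError, ValidationError
from plantchem.fixtures import fixture_docs, generate
from plantchem.model import (
    CorpusUnit,
    EntityClass,
    EntityMention,
    Label,
    SentenceRecord,
)

MINIMAL_BIOC = """<?xml version="1.0" encoding="UTF-8"?>
<collection>
  <source>test</source>
  <document>
    <id>15493960</id>
    <passage>
      <offset>0</offset>
      <text>Pomegranate contains anthocyanins.</text>
      <annotation id="T1">
        <infon key="type">plant</infon>
        <infon key="identifier">Taxonomy:22663</infon>
        <location offset="0" length="11"/>
        <text>Pomegranate</text>
      </annotation>
      <annotation id="T2">
        <infon key="type">chemical</infon>
        <infon key="identifier">NA</infon>
        <location offset="21" length="12"/>
        <text>anthocyanins</text>
      </annotation>
      <relation id="R1">
        <infon key="type">POS</infon>
        <infon key="weak_trigger">contains</infon>
        <infon key="strong_trigger">contains</infon>
        <node refid="T1" role="plant"/>
        <node refid="T2" role="chemical"/>
      </relation>
    </passage>
  </document>
</collection>
"""


def sorted_units(docs_or_units):
    units = (
        iter_units(docs_or_units)
        if docs_or_units and hasattr(docs_or_units[0], "pmid")
        else list(docs_or_units)
    )
    return sorted(
        units,
        key=lambda u: (u.sentence.pmid, u.sentence.text, u.plant.span, u.chemical.span),
    )


def simple_unit(label=Label.POS, weak=("contains",), strong="contains"):
    text = "ginger contains gingerol."
    sent = SentenceRecord(0, text, pmid="77")
    plant = EntityMention(EntityClass.PLANT, 0, 6, "ginger")
    chem = EntityMention(EntityClass.CHEMICAL, 16, 24, "gingerol")
    sent.mentions = [plant, chem]
    unit = CorpusUnit(
        sentence=sent,
        plant=plant,
        chemical=chem,
        label=label,
        weak_trigger=weak,
        strong_trigger=strong,
    )
    sent.units = [unit]
    return unit


class TestBioc:
    def test_minimal_document_parses_to_one_pos_unit(self):
        docs = read_bioc(io.BytesIO(MINIMAL_BIOC.encode()))
        assert len(docs) == 1
        (unit,) = iter_units(docs)
        assert unit.sentence.pmid == "15493960"
        assert unit.label is Label.POS
        assert unit.plant.text == "Pomegranate"
        assert unit.plant.ids == (("Taxonomy", "22663"),)
        assert unit.chemical.ids == ()
        assert unit.weak_trigger == ("contains",)
        assert unit.strong_trigger == "contains"

    def test_triggers_only_on_pos_relations(self):
        fixtures = generate(40, 0.5, 0.1, seed=13)
        docs = read_bioc(io.BytesIO(bioc_bytes(fixture_docs(fixtures))))
        units = iter_units(docs)
        assert any(u.label is Label.POS for u in units)
        for u in units:
            if u.label is Label.POS:
                assert u.weak_trigger and u.strong_trigger
            else:
                assert u.weak_trigger is None and u.strong_trigger is None

    def test_empty_collection(self):
        docs = read_bioc(io.BytesIO(bioc_bytes([])))
        assert docs == []

    def test_roundtrip_is_lossless_and_canonical(self):
        docs = fixture_docs(generate(50, 0.5, 0.1, seed=21))
        payload = bioc_bytes(docs)
        docs2 = read_bioc(io.BytesIO(payload))
        assert bioc_bytes(docs2) == payload
        assert sorted_units(docs2) == sorted_units(docs)
        offsets = {d.pmid: [s.doc_offset for s in d.sentences] for d in docs}
        assert {
            d.pmid: [s.doc_offset for s in d.sentences] for d in docs2
        } == offsets

    def test_malformed_xml_names_line(self):
        with pytest.raises(CorpusParseError, match="line"):
            read_bioc(io.BytesIO(b"<collection><document></collection>"))

    def test_relation_with_missing_annotation_id(self):
        broken = MINIMAL_BIOC.replace('refid="T2"', 'refid="T9"')
        with pytest.raises(IntegrityError, match="T9"):
            read_bioc(io.BytesIO(broken.encode()))

    def test_pos_unit_without_trigger_rejected_before_writing(self):
        unit = simple_unit(weak=None, strong=None)
        with pytest.raises(ValidationError, match="weak trigger"):
            bioc_bytes(docs_from_units([unit]))


class TestSheet:
    def test_one_sentence_two_plants_shares_sentence_cell(self):
        text = (
            "Effects of nitrogen deposition on masson pine "
            "(Pinus massoniana) forests were studied."
        )
        sent = SentenceRecord(0, text, pmid="555")
        chem = EntityMention(
            EntityClass.CHEMICAL, text.find("nitrogen"), text.find("nitrogen") + 8,
            "nitrogen",
        )
        plants = [
            EntityMention(EntityClass.PLANT, text.find(s), text.find(s) + len(s), s)
            for s in ("masson pine", "Pinus massoniana")
        ]
        sent.mentions = [chem, *plants]
        units = [
            CorpusUnit(sentence=sent, plant=p, chemical=chem, label=Label.UNLABELED)
            for p in plants
        ]
        rows = export_sheet(units).splitlines()
        assert rows[0] == "\t".join(SHEET_COLUMNS)
        assert len(rows) == 3
        assert rows[1].split("\t")[10] == rows[2].split("\t")[10] == text
        assert [r.split("\t")[0] for r in rows[1:]] == [
            "masson pine",
            "Pinus massoniana",
        ]

    def test_zero_units_is_header_only(self):
        assert export_sheet([]) == "\t".join(SHEET_COLUMNS) + "\n"

    def test_neg_row_with_empty_triggers_imports_as_absent(self):
        unit = simple_unit(label=Label.NEG, weak=None, strong=None)
        (got,) = import_sheet(export_sheet([unit]))
        assert got.label is Label.NEG
        assert got.weak_trigger is None and got.strong_trigger is None

    def test_na_trigger_cells_map_to_absent(self):
        sheet = export_sheet([simple_unit(Label.NEG, None, None)])
        header, row = sheet.splitlines()
        cells = row.split("\t")
        cells[13] = cells[14] = "NA"
        (got,) = import_sheet(header + "\n" + "\t".join(cells) + "\n")
        assert got.weak_trigger is None and got.strong_trigger is None

    def test_offset_not_matching_name_is_integrity_error(self):
        sheet = export_sheet([simple_unit()])
        header, row = sheet.splitlines()
        cells = row.split("\t")
        cells[2] = "1:7"  # P.Off no longer matches PlantName
        with pytest.raises(IntegrityError, match="row 2"):
            import_sheet(header + "\n" + "\t".join(cells) + "\n")

    def test_pos_row_without_weak_trigger_reports_row(self):
        sheet = export_sheet([simple_unit()])
        header, row = sheet.splitlines()
        cells = row.split("\t")
        cells[13] = ""
        with pytest.raises(ValidationError, match="row 2"):
            import_sheet(header + "\n" + "\t".join(cells) + "\n")

    def test_wrong_header_rejected(self):
        with pytest.raises(CorpusParseError, match="canonical column"):
            import_sheet("PlantName\tP.ID\n")

    def test_check_marks_preserved_in_provenance(self):
        unit = simple_unit()
        unit.provenance = {"p_check": "O", "c_check": "X", "c_note": "bad id"}
        (got,) = import_sheet(export_sheet([unit]))
        assert got.provenance == unit.provenance
        assert got == unit

    def test_roundtrip_on_generated_units(self):
        units = [f.unit for f in generate(100, 0.5, 0.1, seed=2)]
        again = import_sheet(export_sheet(units))
        assert again == units


def test_validation_rejects_exactly_the_trigger_rule_violations():
    good_pos = simple_unit()
    good_neg = simple_unit(Label.NEG, None, None)
    bad_pos = simple_unit(weak=None, strong=None)
    bad_neg = simple_unit(Label.NEG, ("x",), "x")
    two_word_strong = simple_unit(strong="contains much")
    good_pos.validate()
    good_neg.validate()
    for bad in (bad_pos, bad_neg, two_word_strong):
        with pytest.raises(ValidationError):
            bad.validate()
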