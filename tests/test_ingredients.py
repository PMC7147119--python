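"""Ingredient parsing, canonical keys, and catalog merging."""

import random

import pytest

from netpharm.ingredients import (
    FormulaCatalog,
    RawIngredientRecord,
    canonical_key,
    merge_catalogs,
    overlap_partition,
    parse_structure_table,
)

PALMITIC_SMILES = "CCCCCCCCCCCCCCCC(=O)O"
# cross-checked with an independent chemistry toolkit (Open Babel)
PALMITIC_INCHIKEY = "IPCSVZSSVZVIGE-UHFFFAOYSA-N"

ETHANOL_MOLBLOCK = """ethanol
  test

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.2000    1.2000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
$$$$
"""

BROKEN_MOLBLOCK = """broken
  test

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 Xx  0  0  0  0  0  0  0  0  0  0  0  0
  1  9  1  0
M  END
$$$$
"""


class TestParsing:
    def test_empty_sdf_yields_no_records(self, tmp_path):
        p = tmp_path / "empty.sdf"
        p.write_text("")
        assert parse_structure_table(p, "sdf", "H1", "DB") == []

    def test_sdf_records_and_malformed_block_skipped(self, tmp_path):
        p = tmp_path / "mix.sdf"
        p.write_text(ETHANOL_MOLBLOCK + BROKEN_MOLBLOCK + ETHANOL_MOLBLOCK)
        records = parse_structure_table(p, "sdf", "H1", "DB")
        assert len(records) == 2
        assert all(r.smiles == "CCO" for r in records)
        assert records[0].name == "ethanol"

    def test_csv_blank_smiles_kept_as_absent(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("name,smiles\nginsenoside,CCO\npalmitic acid,"
                     f"{PALMITIC_SMILES}\nmystery compound,\n")
        records = parse_structure_table(p, "csv", "H1", "DB")
        assert len(records) == 3
        assert records[2].smiles is None and records[2].name == "mystery compound"

    def test_csv_column_map(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("Compound,Structure\nx,CCO\n")
        records = parse_structure_table(
            p, "csv", "H1", "DB",
            column_map={"name": "Compound", "smiles": "Structure"},
        )
        assert records[0].name == "x" and records[0].smiles == "CCO"

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_structure_table(tmp_path / "nope.sdf", "sdf", "H1", "DB")

    def test_missing_column_is_fatal(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("name,structure\nx,CCO\n")
        with pytest.raises(ValueError, match="smiles"):
            parse_structure_table(p, "csv", "H1", "DB")


class TestCanonicalKey:
    def test_name_fallback_is_normalized_and_flagged(self):
        rec = RawIngredientRecord("H1", "DB", name="  Palmitic   Acid ")
        assert canonical_key(rec) == ("NAME:palmitic acid", True)

    def test_atom_order_does_not_change_key(self):
        a = RawIngredientRecord("H1", "DB", smiles=PALMITIC_SMILES)
        b = RawIngredientRecord("H1", "DB", smiles="OC(=O)CCCCCCCCCCCCCCC")
        assert canonical_key(a) == canonical_key(b)

    def test_inchikey_matches_independent_toolkit(self):
        rec = RawIngredientRecord("H1", "DB", smiles=PALMITIC_SMILES)
        key, fallback = canonical_key(rec)
        assert key == PALMITIC_INCHIKEY and not fallback
        assert len(key) == 27

    def test_unparseable_structure_falls_back_to_name(self):
        rec = RawIngredientRecord("H1", "DB", name="junk", smiles="not-a-smiles")
        assert canonical_key(rec) == ("NAME:junk", True)

    def test_no_structure_no_name_is_an_error(self):
        with pytest.raises(ValueError):
            RawIngredientRecord("H1", "DB")


def _fixture_records():
    """6 records, 2 sharing palmitic acid across 2 herbs -> 5 compounds."""
    return [
        RawIngredientRecord("RS", "DB1", name="palmitic acid",
                            smiles=PALMITIC_SMILES),
        RawIngredientRecord("YZ", "DB2", name="Palmitic Acid",
                            smiles="OC(=O)CCCCCCCCCCCCCCC"),
        RawIngredientRecord("RS", "DB1", name="ethanol", smiles="CCO"),
        RawIngredientRecord("YZ", "DB1", name="methanol", smiles="CO"),
        RawIngredientRecord("FL", "DB2", name="benzene", smiles="c1ccccc1"),
        RawIngredientRecord("SCP", "DB1", name="no structure here"),
    ]


class TestMerge:
    def test_single_record_identity(self):
        cat = merge_catalogs([RawIngredientRecord("RS", "DB", smiles="CCO")])
        assert len(cat) == 1
        assert cat.per_herb_counts == {"RS": 1}
        assert cat.compounds[0].compound_id == "M1"

    def test_shared_structure_merges_across_herbs(self):
        cat = merge_catalogs(_fixture_records())
        assert len(cat) == 5
        shared = [c for c in cat.compounds if c.canonical_key == PALMITIC_INCHIKEY]
        assert len(shared) == 1
        assert shared[0].herbs == frozenset({"RS", "YZ"})
        assert shared[0].source_dbs == frozenset({"DB1", "DB2"})

    def test_same_compound_in_all_four_herbs(self):
        records = [
            RawIngredientRecord(h, "DB", name="palmitic acid",
                                smiles=PALMITIC_SMILES)
            for h in ("RS", "YZ", "FL", "SCP")
        ]
        cat = merge_catalogs(records)
        assert len(cat) == 1
        assert cat.compounds[0].herbs == frozenset({"RS", "YZ", "FL", "SCP"})

    def test_self_concatenation_is_idempotent(self):
        records = _fixture_records()
        a = merge_catalogs(records)
        b = merge_catalogs(records + records)
        assert [c.canonical_key for c in a.compounds] == [
            c.canonical_key for c in b.compounds
        ]
        assert a.per_herb_counts == b.per_herb_counts

    def test_shuffling_input_gives_byte_identical_export(self, tmp_path):
        records = _fixture_records()
        shuffled = records[:]
        random.Random(7).shuffle(shuffled)
        merge_catalogs(records).to_csv(tmp_path / "a.csv")
        merge_catalogs(shuffled).to_csv(tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_name_fallback_never_merges_with_structure_key(self):
        records = [
            RawIngredientRecord("RS", "DB", name="ethanol", smiles="CCO"),
            RawIngredientRecord("YZ", "DB", name="ethanol"),
        ]
        assert len(merge_catalogs(records)) == 2

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            merge_catalogs([])

    def test_csv_round_trip(self, tmp_path):
        cat = merge_catalogs(_fixture_records())
        cat.to_csv(tmp_path / "cat.csv")
        back = FormulaCatalog.from_csv(tmp_path / "cat.csv")
        assert [c.canonical_key for c in back.compounds] == [
            c.canonical_key for c in cat.compounds
        ]
        assert back.per_herb_counts == cat.per_herb_counts


class TestOverlapPartition:
    def test_disjoint_herbs_all_multiplicity_one(self):
        cat = merge_catalogs([
            RawIngredientRecord("RS", "DB", smiles="CCO"),
            RawIngredientRecord("YZ", "DB", smiles="CO"),
        ])
        histogram, _ = overlap_partition(cat)
        assert histogram == {1: 2}

    def test_one_compound_in_all_four_herbs(self):
        records = [
            RawIngredientRecord(h, "DB", name="palmitic acid",
                                smiles=PALMITIC_SMILES)
            for h in ("RS", "YZ", "FL", "SCP")
        ] + [
            RawIngredientRecord("RS", "DB", smiles="CCO"),
            RawIngredientRecord("YZ", "DB", smiles="CO"),
            RawIngredientRecord("FL", "DB", smiles="c1ccccc1"),
            RawIngredientRecord("SCP", "DB", smiles="CCCO"),
        ]
        histogram, herb_map = overlap_partition(merge_catalogs(records))
        assert histogram == {1: 4, 4: 1}
        assert sum(histogram.values()) == 5
        assert sum(m * v for m, v in histogram.items()) == sum(
            len(h) for h in herb_map.values()
        )
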