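"""Glycan mass arithmetic, database parsing and configuration counting."""

import math
from itertools import combinations_with_replacement

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycopair.glycans import (
    DEFAULT_REGISTRY,
    GlycanBox,
    GlycanComposition,
    GlycanDatabase,
    builtin_oglycan_database,
    count_configurations,
    count_unique_combined_masses,
    enumerate_boxes,
    oxonium_mz,
    parse_glycan_database,
)


class TestMasses:
    def test_residue_masses_match_formulas(self):
        # HexNAc residue = C8H13NO5
        assert DEFAULT_REGISTRY["HexNAc"].residue_mass == pytest.approx(
            203.0794, abs=1e-4
        )
        assert DEFAULT_REGISTRY["Hex"].residue_mass == pytest.approx(
            162.0528, abs=1e-4
        )

    @pytest.mark.parametrize(
        "text,water_loss,expected",
        [
            ("Hex(1)", False, 163.0601),
            ("Hex(1)", True, 145.0495),
            ("HexNAc(1)Hex(1)", False, 366.1395),
            ("HexNAc(1)", False, 204.0866),
            ("NeuAc(1)", True, 274.0921),
            ("NeuAc(1)", False, 292.1027),
            ("NeuGc(1)", False, 308.0976),
            ("NeuGc(1)", True, 290.0870),
        ],
    )
    def test_oxonium_reference_values(self, text, water_loss, expected):
        mz = oxonium_mz(GlycanComposition.parse(text), water_loss)
        assert round(mz, 4) == expected

    def test_oxonium_differences_recover_residue_masses(self):
        # oxonium(X+Y) - oxonium(Y) = residue mass of X
        hexnac_hex = oxonium_mz(GlycanComposition.parse("HexNAc(1)Hex(1)"))
        hexose = oxonium_mz(GlycanComposition.parse("Hex(1)"))
        assert hexnac_hex - hexose == pytest.approx(
            DEFAULT_REGISTRY["HexNAc"].residue_mass, abs=1e-4
        )

    def test_empty_composition_has_no_oxonium(self):
        empty = GlycanComposition.from_counts({})
        with pytest.raises(ValueError):
            oxonium_mz(empty)


class TestCompositionText:
    def test_canonical_order_is_registry_order(self):
        c = GlycanComposition.from_counts({"Hex": 1, "HexNAc": 2})
        assert str(c) == "HexNAc(2)Hex(1)"

    def test_unknown_monosaccharide_rejected(self):
        with pytest.raises(ValueError, match="unknown monosaccharide Xyz"):
            GlycanComposition.parse("HexNAc(1)Xyz(1)")

    @given(
        st.dictionaries(
            st.sampled_from(DEFAULT_REGISTRY.names),
            st.integers(min_value=1, max_value=9),
            min_size=1,
            max_size=4,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_text_round_trip(self, counts):
        c = GlycanComposition.from_counts(counts)
        assert GlycanComposition.parse(str(c)) == c


class TestDatabaseParsing:
    def test_parse_with_mass_annotation(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("# comment\nHexNAc(1) % 203.0794\n\nHexNAc(1)Hex(1)\n")
        db = parse_glycan_database(p)
        assert len(db) == 2
        assert db[0].mass == pytest.approx(203.0794, abs=1e-4)

    def test_empty_file_empty_database(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("")
        assert len(parse_glycan_database(p)) == 0

    def test_mass_disagreement_rejected(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("HexNAc(1) % 250.0\n")
        with pytest.raises(ValueError, match="disagrees"):
            parse_glycan_database(p)

    def test_duplicate_composition_rejected(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("HexNAc(1)\nHexNAc(1)\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_glycan_database(p)

    def test_unknown_code_names_line(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("HexNAc(1)\nHexNAc(1)Xyz(1)\n")
        with pytest.raises(ValueError, match=r":2:.*Xyz"):
            parse_glycan_database(p)

    def test_entries_sorted_by_mass(self, oglycan_db):
        masses = [c.mass for c in oglycan_db]
        assert masses == sorted(masses)


def _enumerate_multisets(n_items: int, max_size: int) -> int:
    total = 0
    for k in range(1, max_size + 1):
        total += sum(1 for _ in combinations_with_replacement(range(n_items), k))
    return total


class TestConfigurationCounting:
    @pytest.mark.parametrize(
        "n,sites,expected",
        [(32, 5, 435_896), (32, 8, 76_904_684), (1, 1, 1), (2, 2, 5)],
    )
    def test_closed_form(self, n, sites, expected):
        assert count_configurations(n, sites, sites) == expected

    def test_closed_form_equals_enumeration_small(self):
        for n in range(1, 7):
            for k in range(1, 7):
                assert count_configurations(n, k, k) == _enumerate_multisets(n, k)

    def test_max_glycans_caps_sites(self):
        assert count_configurations(32, 8, 5) == count_configurations(32, 5, 5)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            count_configurations(0, 1, 1)


class TestBoxes:
    def test_enumerate_two_entry_db(self):
        db = GlycanDatabase.from_compositions(
            [GlycanComposition.parse("HexNAc(1)"), GlycanComposition.parse("Hex(1)")]
        )
        boxes = enumerate_boxes(db, 2)
        assert len(boxes) == 5  # {A},{B},{AA},{AB},{BB}
        masses = [b.total_mass for b in boxes]
        assert masses == sorted(masses)

    def test_target_mass_selects_single_box(self):
        db = GlycanDatabase.from_compositions([GlycanComposition.parse("HexNAc(1)")])
        boxes = enumerate_boxes(db, 2, target_mass=406.1587, tolerance_ppm=10)
        assert len(boxes) == 1
        assert boxes[0].n_glycans == 2

    def test_negative_target_empty(self, oglycan_db):
        assert enumerate_boxes(oglycan_db, 2, target_mass=-100.0) == []

    def test_unique_masses_small_db(self):
        db = GlycanDatabase.from_compositions(
            [GlycanComposition.parse("HexNAc(1)"), GlycanComposition.parse("Hex(1)")]
        )
        assert count_unique_combined_masses(db, 2) == 5

    def test_unique_never_exceeds_configurations(self, oglycan_db):
        for max_glycans in (1, 2, 3):
            unique = count_unique_combined_masses(oglycan_db, max_glycans)
            conventional = count_configurations(
                len(oglycan_db), max_glycans, max_glycans
            )
            assert unique <= conventional

    def test_box_mass_is_sum_of_entries(self, oglycan_db):
        box = GlycanBox.from_indices(oglycan_db, [0, 0, 3])
        assert box.n_glycans == 3
        expected = 2 * oglycan_db[0].mass + oglycan_db[3].mass
        assert box.total_mass == pytest.approx(expected, abs=1e-6)
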