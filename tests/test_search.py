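"""Peptide-first search: offset index, hyperscore, pair search, oxonium filter."""

import math

import numpy as np
import pytest

from glycopair.chem import PROTON, WATER, AA_RESIDUE_MASS, mz as _mz
from glycopair.digestion import PeptideCandidate
from glycopair.glycans import GlycanBox, GlycanComposition, GlycanDatabase
from glycopair.search import (
    OxoniumRule,
    PeptideIndex,
    SearchParams,
    default_oxonium_rules,
    hyperscore,
    oxonium_filter,
    parse_oxonium_rules,
    precompute_offset_index,
    search_pair,
)
from glycopair.spectra import Spectrum, SpectrumPair


def b_ion(seq, i, q=1):
    return sum(AA_RESIDUE_MASS[a] for a in seq[:i]) / q + PROTON


def y_ion(seq, i, q=1):
    return (sum(AA_RESIDUE_MASS[a] for a in seq[-i:]) + WATER) / q + PROTON


def spectrum(peaks, precursor=500.0, charge=2, activation="HCD", scan_id=1):
    return Spectrum(
        scan_id, 2, activation, precursor, charge, 0.0,
        [p[0] for p in peaks], [p[1] for p in peaks],
    )


class TestOffsetIndex:
    def test_single_entry_db(self):
        db = GlycanDatabase.from_compositions([GlycanComposition.parse("HexNAc(1)")])
        index = precompute_offset_index(db, 2)
        assert [round(m, 4) for m in index.masses] == [203.0794, 406.1587]

    def test_window_lookup(self):
        db = GlycanDatabase.from_compositions([GlycanComposition.parse("HexNAc(1)")])
        index = precompute_offset_index(db, 2)
        target = 406.1587
        hits = index.lookup(target - 0.001, target + 0.001)
        assert len(hits) == 1 and hits[0].n_glycans == 2
        assert index.lookup(1000.0, 1001.0) == []

    def test_groups_collapse_equal_masses(self, oglycan_db):
        index = precompute_offset_index(oglycan_db, 3)
        assert len(index.masses) == len(set(index.masses))


class TestHyperscore:
    def test_complete_ladder_counts_all_ions(self):
        seq = "PEPTIDE"
        pep = PeptideCandidate(seq, ("P1",))
        peaks = [(b_ion(seq, i), 10.0) for i in range(1, 7)]
        peaks += [(y_ion(seq, i), 10.0) for i in range(1, 7)]
        score, n_b, n_y = hyperscore(spectrum(peaks), pep, 2)
        assert (n_b, n_y) == (6, 6)
        assert score > 0

    def test_no_overlap_scores_zero(self):
        pep = PeptideCandidate("PEPTIDE", ("P1",))
        score, n_b, n_y = hyperscore(spectrum([(1500.0, 5.0)]), pep, 2)
        assert score == 0.0

    def test_hand_computed_value(self):
        seq = "GASK"
        pep = PeptideCandidate(seq, ("P1",))
        peaks = [(b_ion(seq, 2), 10.0), (y_ion(seq, 1), 20.0), (y_ion(seq, 2), 30.0)]
        score, n_b, n_y = hyperscore(spectrum(peaks), pep, 2)
        assert (n_b, n_y) == (1, 2)
        expected = math.log(math.factorial(1)) + math.log(math.factorial(2)) + math.log(
            10.0 * (20.0 + 30.0)
        )
        assert score == pytest.approx(expected, abs=1e-9)

    def test_factorial_capped_at_ten(self):
        seq = "PEPTIDESPEPTIDES"
        pep = PeptideCandidate(seq, ("P1",))
        peaks = [(b_ion(seq, i), 1.0) for i in range(1, 16)]
        peaks += [(y_ion(seq, i), 1.0) for i in range(1, 16)]
        score, n_b, n_y = hyperscore(spectrum(peaks, precursor=900.0), pep, 2)
        assert n_b == n_y == 15
        assert score == pytest.approx(
            2 * math.log(math.factorial(10)) + math.log(15.0 * 15.0), abs=1e-9
        )


def make_pair(seq, box, charge=2, extra_delta=0.0):
    pep = PeptideCandidate(seq, ("P1",))
    neutral = pep.sequence_mass + (box.total_mass if box else 0.0) + extra_delta
    peaks = [(b_ion(seq, i), 10.0) for i in range(1, len(seq))]
    peaks += [(y_ion(seq, i), 10.0) for i in range(1, len(seq))]
    first = spectrum(peaks, precursor=_mz(neutral, charge), charge=charge)
    return SpectrumPair(first, None, "hcd_first")


class TestSearchPair:
    @pytest.fixture
    def index(self, tmp_path):
        fasta = tmp_path / "db.fasta"
        fasta.write_text(">P1\nMKGASTAKLEWIRAAAGK\n")
        from glycopair.digestion import DigestionSpec, digest

        cands = digest(
            fasta,
            DigestionSpec(max_missed_cleavages=1, peptide_length_range=(5, 40)),
            "reverse",
        )
        return PeptideIndex(cands)

    @pytest.fixture
    def offsets(self, oglycan_db):
        return precompute_offset_index(oglycan_db, 3)

    def test_recovers_glycopeptide(self, index, offsets, oglycan_db, hexnac_index):
        box = GlycanBox.from_indices(oglycan_db, [hexnac_index])
        pair = make_pair("GASTAK", box)
        psm = search_pair(pair, index, offsets)
        assert psm is not None
        assert psm.peptide.sequence == "GASTAK"
        assert psm.delta_mass == pytest.approx(203.0794, abs=0.01)
        assert any(
            b.glycan_counts == box.glycan_counts for b in psm.candidate_boxes
        )

    def test_non_glyco_peptide_has_empty_boxes(self, index, offsets):
        pair = make_pair("GASTAK", None)
        psm = search_pair(pair, index, offsets)
        assert psm.peptide.sequence == "GASTAK"
        assert psm.candidate_boxes == []

    def test_sitefree_peptide_rejects_glycan_delta(self, index, offsets):
        # LEWIR has no S/T: a glycan-sized delta cannot be explained
        pair = make_pair("LEWIR", None, extra_delta=203.07937)
        psm = search_pair(pair, index, offsets)
        assert psm is None or psm.peptide.sequence != "LEWIR"

    def test_unmatched_precursor_returns_none(self, index, offsets):
        pep = PeptideCandidate("GASTAK", ("P1",))
        first = spectrum([(300.0, 1.0)], precursor=3000.0, charge=2)
        pair = SpectrumPair(first, None, "hcd_first")
        assert search_pair(pair, index, offsets) is None

    def test_delta_is_within_tolerance_of_box_or_zero(
        self, index, offsets, oglycan_db
    ):
        for i in range(len(oglycan_db)):
            box = GlycanBox.from_indices(oglycan_db, [i])
            psm = search_pair(make_pair("GASTAK", box), index, offsets)
            assert psm is not None
            tol = psm.observed_neutral_mass * 30e-6
            assert psm.candidate_boxes
            for b in psm.candidate_boxes:
                assert abs(psm.delta_mass - b.total_mass) <= tol


class TestOxoniumFilter:
    def test_hexose_rule_passes_with_ion(self, oglycan_db):
        box = next(
            GlycanBox.from_indices(oglycan_db, [i])
            for i, c in enumerate(oglycan_db)
            if c.count("Hex") > 0
        )
        hex_rule = [
            r for r in default_oxonium_rules(0.05) if str(r.residues) == "Hex(1)"
        ]
        scan = spectrum([(163.0601, 40.0), (500.0, 100.0)])
        assert oxonium_filter(scan, box, hex_rule, 20.0)

    def test_neuac_rule_fails_without_ions(self, oglycan_db):
        box = next(
            GlycanBox.from_indices(oglycan_db, [i])
            for i, c in enumerate(oglycan_db)
            if c.count("NeuAc") > 0
        )
        scan = spectrum([(500.0, 100.0)])
        assert not oxonium_filter(scan, box, default_oxonium_rules(0.05), 20.0)

    def test_inapplicable_rules_pass_vacuously(self, oglycan_db, hexnac_index):
        box = GlycanBox.from_indices(oglycan_db, [hexnac_index])
        rules = [
            r
            for r in default_oxonium_rules(0.05)
            if r.residues.count("HexNAc") == 0
        ]
        scan = spectrum([(500.0, 100.0)])
        assert oxonium_filter(scan, box, rules, 20.0)

    def test_empty_rule_list_is_identity(self, oglycan_db):
        box = GlycanBox.from_indices(oglycan_db, [0])
        assert oxonium_filter(spectrum([(500.0, 1.0)]), box, [], 20.0)

    def test_summed_intensity_threshold(self, oglycan_db):
        box = next(
            GlycanBox.from_indices(oglycan_db, [i])
            for i, c in enumerate(oglycan_db)
            if c.count("Hex") > 0 and c.count("NeuAc") == 0
        )
        rules = [
            r for r in default_oxonium_rules(0.05) if str(r.residues) == "Hex(1)"
        ]
        # 163 at 3% + 145 at 3% sums to 6% >= 5%
        scan = spectrum([(163.0601, 3.0), (145.0495, 3.0), (500.0, 100.0)])
        assert oxonium_filter(scan, box, rules, 20.0)
        weak = spectrum([(163.0601, 2.0), (500.0, 100.0)])
        assert not oxonium_filter(weak, box, rules, 20.0)

    def test_rule_file_round_trip(self, tmp_path):
        p = tmp_path / "rules.tsv"
        p.write_text("Hex(1)\t163.0601,145.0495\t0.05\n# comment\n")
        rules = parse_oxonium_rules(p)
        assert len(rules) == 1
        assert rules[0].ion_mzs == (163.0601, 145.0495)
        assert rules[0].min_summed_relative_intensity == 0.05
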