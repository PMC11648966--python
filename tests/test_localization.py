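"""Localization graph, forward-backward DP, confidence levels, oracle parity."""

import numpy as np
import pytest

from glycopair.chem import NH3, PROTON, AA_RESIDUE_MASS
from glycopair.digestion import PeptideCandidate
from glycopair.glycans import GlycanBox
from glycopair.localization import (
    brute_force_localize,
    build_graph,
    localize,
    select_best_box,
)
from glycopair.search import SearchParams, default_oxonium_rules
from glycopair.spectra import Spectrum, SpectrumPair

from conftest import random_glyco_instance

HEXNAC = 203.07937251951


def c_ion(seq, i, glycan=0.0, q=1):
    return (sum(AA_RESIDUE_MASS[a] for a in seq[:i]) + NH3 + glycan) / q + PROTON


def scan_of(ions):
    return Spectrum(
        1, 2, "EThcD", 800.0, 2, 0.0, list(ions), np.ones(len(ions))
    )


class TestGraphStructure:
    def test_two_sites_two_paths(self, gastak, hexnac_box):
        graph = build_graph(gastak, hexnac_box, None)
        assert graph.n_configurations() == 2

    def test_saturated_sites_single_path(self, oglycan_db, hexnac_index, gastak):
        box = GlycanBox.from_indices(oglycan_db, [hexnac_index, hexnac_index])
        graph = build_graph(gastak, box, None)
        assert graph.n_configurations() == 1

    def test_two_distinct_glycans_three_sites(self, oglycan_db):
        pep = PeptideCandidate("GASTASK", ("P1",))
        box = GlycanBox.from_indices(oglycan_db, [0, 3])
        graph = build_graph(pep, box, None)
        # ordered injective placements of 2 distinct glycans on 3 sites
        assert graph.n_configurations() == 6

    def test_infeasible_box_rejected(self, oglycan_db, gastak):
        box = GlycanBox.from_indices(oglycan_db, [0, 0, 0])
        with pytest.raises(ValueError, match="infeasible box"):
            build_graph(gastak, box, None)


class TestLocalize:
    def test_single_determining_ion_gives_ten_to_one(self, gastak, hexnac_box):
        # evidence: naked c2, glyco-c3, glyco-c4 -> S3 explains 3 ions, T4 only 2
        scan = scan_of(
            [
                c_ion("GASTAK", 2),
                c_ion("GASTAK", 3, HEXNAC),
                c_ion("GASTAK", 4, HEXNAC),
            ]
        )
        res = localize(build_graph(gastak, hexnac_box, scan))
        assert res.level == "1"
        assert res.best_path_score == 3
        assert res.probability(3, "HexNAc(1)") == pytest.approx(10 / 11, abs=1e-9)
        assert res.probability(4, "HexNAc(1)") == pytest.approx(1 / 11, abs=1e-9)
        assert res.best_assignment == ((3, "HexNAc(1)"),)

    def test_forced_single_site_is_level_1b(self, oglycan_db, hexnac_index):
        pep = PeptideCandidate("GASAAK", ("P1",))
        box = GlycanBox.from_indices(oglycan_db, [hexnac_index])
        res = localize(build_graph(pep, box, None))
        assert res.level == "1b"
        assert res.probability(3, "HexNAc(1)") == 1.0
        assert res.n_configurations == 1

    def test_empty_scan_two_sites_is_level_3(self, gastak, hexnac_box):
        res = localize(build_graph(gastak, hexnac_box, None))
        assert res.level == "3"
        assert res.probability(3, "HexNAc(1)") == 0.5
        assert res.probability(4, "HexNAc(1)") == 0.5

    def test_partial_localization_is_level_2(self, oglycan_db):
        # two HexNAc on three sites: pin the first site with strong evidence,
        # leave the second ambiguous between T4 and S6
        pep = PeptideCandidate("GASTASK", ("P1",))
        idx = next(i for i, c in enumerate(oglycan_db) if str(c) == "HexNAc(1)")
        box = GlycanBox.from_indices(oglycan_db, [idx, idx])
        seq = "GASTASK"
        scan = scan_of([c_ion(seq, 3, HEXNAC), c_ion(seq, 3, HEXNAC, q=2)])
        res = localize(build_graph(pep, box, scan))
        assert res.level == "2"
        assert res.probability(3, "HexNAc(1)") > 0.75
        assert max(res.probability(4, "HexNAc(1)"), res.probability(6, "HexNAc(1)")) <= 0.75

    def test_probability_conservation(self, oglycan_db):
        rng = np.random.default_rng(11)
        for _ in range(30):
            pep, box = random_glyco_instance(rng, oglycan_db)
            graph = build_graph(pep, box, None)
            ions = [
                ion
                for i in range(1, len(pep.sequence))
                for c in graph.layers[i]
                if rng.random() < 0.2
                for ion in graph.node_ion_mzs(i, c)[:2]
            ]
            res = localize(build_graph(pep, box, scan_of(ions) if ions else None))
            per_name = {}
            for s, g, p in res.site_probabilities:
                per_name[g] = per_name.get(g, 0.0) + p
            for g, mult in zip(graph.glycans, graph.multiplicities):
                name = str(g)
                total_mult = sum(
                    m
                    for gg, m in zip(graph.glycans, graph.multiplicities)
                    if str(gg) == name
                )
                assert per_name[name] == pytest.approx(total_mult, abs=1e-6)
            for site in graph.candidate_sites:
                site_total = sum(
                    p for s, _, p in res.site_probabilities if s == site
                )
                assert site_total <= 1 + 1e-6

    def test_noise_peaks_do_not_move_probabilities(self, gastak, hexnac_box):
        seq = "GASTAK"
        true_ions = [c_ion(seq, 3, HEXNAC), c_ion(seq, 4, HEXNAC)]
        base = localize(build_graph(gastak, hexnac_box, scan_of(true_ions)))
        noisy = localize(
            build_graph(
                gastak, hexnac_box, scan_of(true_ions + [555.5, 666.6, 777.7])
            )
        )
        assert base.site_probabilities == noisy.site_probabilities
        assert base.level == noisy.level

    def test_added_determining_ion_never_decreases_probability(
        self, gastak, hexnac_box
    ):
        seq = "GASTAK"
        ions = [c_ion(seq, 3, HEXNAC)]
        p1 = localize(build_graph(gastak, hexnac_box, scan_of(ions))).probability(
            3, "HexNAc(1)"
        )
        ions.append(c_ion(seq, 3, HEXNAC, q=2))
        p2 = localize(build_graph(gastak, hexnac_box, scan_of(ions))).probability(
            3, "HexNAc(1)"
        )
        assert p2 >= p1


class TestOracleParity:
    def test_dp_equals_brute_force_on_random_instances(self, oglycan_db):
        rng = np.random.default_rng(23)
        for _ in range(60):
            pep, box = random_glyco_instance(rng, oglycan_db)
            graph0 = build_graph(pep, box, None)
            ions = [
                ion
                for i in range(1, len(pep.sequence))
                for c in graph0.layers[i]
                if rng.random() < 0.15
                for ion in graph0.node_ion_mzs(i, c)[: int(rng.integers(0, 5))]
            ]
            ions += list(rng.uniform(100, 2000, size=int(rng.integers(0, 15))))
            scan = scan_of(ions) if ions else None
            a = localize(build_graph(pep, box, scan))
            b = brute_force_localize(pep, box, scan)
            assert a.best_path_score == b.best_path_score
            assert a.level == b.level
            assert a.n_configurations == b.n_configurations
            assert a.best_assignment == b.best_assignment
            pa = {(s, g): p for s, g, p in a.site_probabilities}
            pb = {(s, g): p for s, g, p in b.site_probabilities}
            assert set(pa) == set(pb)
            for key in pa:
                assert pa[key] == pytest.approx(pb[key], abs=1e-9)

    def test_single_configuration_trivially_identical(self, oglycan_db, hexnac_index):
        pep = PeptideCandidate("GASAAK", ("P1",))
        box = GlycanBox.from_indices(oglycan_db, [hexnac_index])
        a = localize(build_graph(pep, box, None))
        b = brute_force_localize(pep, box, None)
        assert a == b


class TestBoxSelection:
    def test_best_supported_box_wins(self, oglycan_db, gastak):
        idx_hexnac = next(
            i for i, c in enumerate(oglycan_db) if str(c) == "HexNAc(1)"
        )
        idx_core1 = next(
            i for i, c in enumerate(oglycan_db) if str(c) == "HexNAc(1)Hex(1)"
        )
        seq = "GASTAK"
        core1_mass = oglycan_db[idx_core1].mass
        second = scan_of(
            [
                c_ion(seq, 3, core1_mass),
                c_ion(seq, 4, core1_mass),
                c_ion(seq, 5, core1_mass),
                c_ion(seq, 3, core1_mass, q=2),
            ]
        )
        first = Spectrum(
            1, 2, "HCD", 800.0, 2, 0.0,
            [163.0601, 204.0867, 366.1395, 500.0], [40.0, 40.0, 40.0, 100.0],
        )
        pair = SpectrumPair(first, second, "hcd_first")
        boxes = [
            GlycanBox.from_indices(oglycan_db, [idx_hexnac]),
            GlycanBox.from_indices(oglycan_db, [idx_core1]),
        ]
        box, result = select_best_box(
            pair, gastak, boxes, default_oxonium_rules(0.05)
        )
        assert str(box) == "HexNAc(1)Hex(1)"
        assert result.best_path_score == 4

    def test_all_boxes_filtered_reports_unassigned(self, oglycan_db, gastak):
        idx_neuac = next(
            i for i, c in enumerate(oglycan_db) if c.count("NeuAc") > 0
        )
        first = Spectrum(1, 2, "HCD", 800.0, 2, 0.0, [500.0], [100.0])
        pair = SpectrumPair(first, None, "hcd_first")
        boxes = [GlycanBox.from_indices(oglycan_db, [idx_neuac])]
        box, result = select_best_box(
            pair, gastak, boxes, default_oxonium_rules(0.05)
        )
        assert box is None
        assert result.level == "3"

    def test_single_passing_box_returned(self, oglycan_db, gastak, hexnac_box):
        first = Spectrum(1, 2, "HCD", 800.0, 2, 0.0, [204.0867], [100.0])
        pair = SpectrumPair(first, None, "hcd_first")
        box, result = select_best_box(pair, gastak, [hexnac_box], [])
        assert box is hexnac_box
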