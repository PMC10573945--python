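"""Physicochemical metrics, melting temperatures, specificity, filters."""
from __future__ import annotations

import math
import random

import pytest

from skipaso import fixtures as fx
from skipaso.evaluation import (FilterThresholds, apply_filters,
                                compute_physchem, compute_tm,
                                max_self_complementarity,
                                search_genome_matches, self_dimer_max)

NRAS_TOP = "UGCUCCUAGUACCUGUAGAGGUUAA"


class TestPhysChem:
    def test_hand_counted_reference_sequence(self):
        p = compute_physchem(NRAS_TOP)
        assert p.gc_percent == pytest.approx(44.0)
        assert p.g_percent == pytest.approx(24.0)
        assert p.max_g_run == 2

    def test_tetra_g_detected_and_failed(self):
        seq = "GGGG" + "A" * 21
        p = compute_physchem(seq)
        assert p.max_g_run == 4
        assert "g_run" in apply_filters(seq).failed_criteria

    def test_poly_a_profile(self):
        p = compute_physchem("A" * 25)
        assert p.gc_percent == 0.0
        assert p.max_self_comp_pairs == 0
        assert math.isnan(p.tm_nn)
        assert apply_filters("A" * 25).failed_criteria == ["gc_range"]

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            compute_physchem("ACTGU")  # T invalid in RNA alphabet

    def test_pure_function(self):
        assert compute_physchem(NRAS_TOP) == compute_physchem(NRAS_TOP)


class TestSelfComplementarity:
    def test_perfect_palindrome_pairs_fully(self):
        assert self_dimer_max("AAAAUUUU") == 8

    def test_hbond_mode_weights_pairs(self):
        # eight A-U pairs at 2 hydrogen bonds each
        assert self_dimer_max("AAAAUUUU", mode="hbonds") == 16
        # G-C pairs carry 3 bonds
        assert self_dimer_max("GGCC", mode="hbonds") == 12

    def test_wobble_counts_as_pair(self):
        # G pairs U via wobble: GGGG vs UUUU alignment
        assert self_dimer_max("GGUU") >= 4

    def test_no_complementarity(self):
        assert self_dimer_max("AAAA") == 0
        assert self_dimer_max("CCCC") == 0

    def test_intramolecular_bound_for_25mers(self):
        rnd = random.Random(5)
        for _ in range(20):
            seq = "".join(rnd.choice("ACGU") for _ in range(25))
            # a 25-mer hairpin cannot stack more than 12 pairs, so the
            # combined metric is dominated by the self-dimer component
            assert max_self_complementarity(seq) >= self_dimer_max(seq)


class TestMeltingTemperature:
    def test_basic_formula_hand_value(self):
        # 25-mer with 11 G+C: 64.9 + 41*(11-16.4)/25 = 56.044
        assert compute_tm(NRAS_TOP, "basic") == pytest.approx(56.044)

    def test_salt_adjusted_hand_value(self):
        # 100.5 + 41*11/25 - 820/25 + 16.6*log10(1) = 85.74
        assert compute_tm(NRAS_TOP, "salt_adjusted", na_conc=1.0) \
            == pytest.approx(85.74)

    def test_salt_term_uses_log10(self):
        t1 = compute_tm(NRAS_TOP, "salt_adjusted", na_conc=1.0)
        t01 = compute_tm(NRAS_TOP, "salt_adjusted", na_conc=0.1)
        assert t1 - t01 == pytest.approx(16.6)

    def test_nn_requires_gc(self):
        with pytest.raises(ValueError, match="at least one G or C"):
            compute_tm("A" * 25, "nearest_neighbor")

    def test_nn_tables_differ(self):
        dna = compute_tm(NRAS_TOP, "nearest_neighbor", nn_table="dna")
        rna = compute_tm(NRAS_TOP, "nearest_neighbor", nn_table="rna")
        assert dna != rna
        assert 40 < dna < 120 and 40 < rna < 120

    @pytest.mark.parametrize("method", ["basic", "salt_adjusted",
                                        "nearest_neighbor"])
    def test_monotone_in_gc_content(self, method):
        """More G+C never lowers Tm at fixed length and salt."""
        prev = None
        for k in range(1, 26):
            seq = "G" * k + "A" * (25 - k)
            t = compute_tm(seq, method)
            if prev is not None:
                assert t >= prev - 1e-9
            prev = t

    def test_basic_matches_independent_reimplementation(self):
        rnd = random.Random(11)
        for _ in range(25):
            seq = "".join(rnd.choice("ACGU") for _ in range(25))
            gc = sum(c in "GC" for c in seq)
            assert compute_tm(seq, "basic") \
                == pytest.approx(64.9 + 41 * (gc - 16.4) / 25)


def _naive_scan(genome: dict[str, str], aso: str, budget: int):
    """Independent O(n*25) Hamming-scan oracle over both strands."""
    comp = str.maketrans("ACGT", "TGCA")
    target = aso.replace("U", "T").translate(comp)[::-1]
    queries = {"+": target, "-": target.translate(comp)[::-1]}
    hits = []
    for chrom, seq in genome.items():
        for strand, q in queries.items():
            for i in range(len(seq) - len(q) + 1):
                mm = sum(a != b for a, b in zip(seq[i:i + len(q)], q))
                if mm <= budget:
                    hits.append((chrom, i, strand, mm))
    return sorted(hits)


@pytest.fixture(scope="module")
def planted():
    locus = fx.generate_locus(fx.nras_like_spec())
    # on-target: the H3D (13,-12) donor window of exon 3
    return locus, "UGCUCCUAGUACCUGUAGAGGUUAA"


class TestGenomeSearch:
    def test_single_planted_site_is_unique(self, planted):
        locus, aso = planted
        res = search_genome_matches(aso, locus.genome)
        assert res.match_count == 1 and res.unique

    @pytest.mark.parametrize("k,expected", [(0, 2), (2, 2), (3, 1)])
    def test_offtarget_within_budget_breaks_uniqueness(self, planted, k,
                                                       expected):
        locus, aso = planted
        comp = str.maketrans("ACGT", "TGCA")
        target = aso.replace("U", "T").translate(comp)[::-1]
        doped = fx.plant_offtarget(locus, target, k, seed=99)
        res = search_genome_matches(aso, doped.genome, mismatch_budget=2)
        assert res.match_count == expected
        assert res.unique == (expected == 1)

    def test_matches_naive_oracle(self, planted):
        locus, aso = planted
        doped = fx.plant_offtarget(locus, "AGTCC" * 5, 1, seed=7)
        for seq in (aso, "ACGUACGUACGUACGUACGUACGUA"):
            got = search_genome_matches(seq, doped.genome, mismatch_budget=2)
            assert got.locations == _naive_scan(doped.genome, seq, 2)

    def test_reverse_strand_hit_found(self):
        aso = NRAS_TOP
        comp = str.maketrans("ACGT", "TGCA")
        target = aso.replace("U", "T").translate(comp)[::-1]
        target_rc = target.translate(comp)[::-1]
        genome = {"c": "T" * 60 + target_rc + "T" * 60}
        res = search_genome_matches(aso, genome)
        assert res.match_count == 1
        assert res.locations[0][2] == "-"

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError, match="empty genome"):
            search_genome_matches(NRAS_TOP, {})


class TestFilters:
    def test_passing_candidate(self):
        rep = apply_filters(NRAS_TOP)
        assert rep.passed and rep.failed_criteria == []
        assert rep.specificity is None  # not evaluated without a genome

    def test_gc_bounds_inclusive(self):
        # exactly 40% GC (10 of 25) passes
        seq = "G" * 5 + "C" * 5 + "A" * 15
        rep = apply_filters(seq, FilterThresholds(max_g_run=5))
        assert "gc_range" not in rep.failed_criteria

    def test_monotone_under_tightening(self):
        rnd = random.Random(3)
        base = FilterThresholds()
        tight = FilterThresholds(gc_min=45, gc_max=55, g_max=30,
                                 max_g_run=2, max_self_comp=8)
        for _ in range(50):
            seq = "".join(rnd.choice("ACGU") for _ in range(25))
            if not apply_filters(seq, base).passed:
                assert not apply_filters(seq, tight).passed

    def test_specificity_failure_reported(self):
        aso = NRAS_TOP
        comp = str.maketrans("ACGT", "TGCA")
        target = aso.replace("U", "T").translate(comp)[::-1]
        genome = {"c": "T" * 30 + target + "T" * 30 + target + "T" * 30}
        rep = apply_filters(aso, genome=genome)
        assert "specificity" in rep.failed_criteria
        assert rep.specificity.match_count == 2
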