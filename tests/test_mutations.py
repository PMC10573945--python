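"""Mutation parsing, 20/20 classification and exon burden ranking."""
from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skipaso.intervals import GenomicInterval
from skipaso.mutations import (ExonMutationSummary, MutationRecord,
                               ONCOGENE, TUMOR_SUPPRESSOR, UNCLASSIFIED,
                               classify_gene, count_patients_per_exon,
                               normalize_mutation_class,
                               parse_mutation_table,
                               rank_exons_by_mutation,
                               select_top_fraction_genes)


def _rec(gene="G", sample="S1", mclass="substitution_missense",
         chrom="1", pos0=None):
    iv = (GenomicInterval(chrom, pos0, pos0 + 1)
          if pos0 is not None else None)
    return MutationRecord(gene=gene, sample_id=sample,
                          mutation_class=mclass, genomic_interval=iv)


def _mix(n_gof: int, n_lof: int, total: int) -> list[MutationRecord]:
    recs = [_rec(sample=f"S{i}", mclass="substitution_missense")
            for i in range(n_gof)]
    recs += [_rec(sample=f"T{i}", mclass="substitution_nonsense")
             for i in range(n_lof)]
    recs += [_rec(sample=f"U{i}", mclass="substitution_synonymous")
             for i in range(total - n_gof - n_lof)]
    return recs


class TestParsing:
    def test_three_row_table(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "Gene name\tID_sample\tMutation Description\t"
            "Mutation genome position\n"
            "BRAF\tS1\tSubstitution - Missense\t7:140753336-140753336\n"
            "BRAF\tS2\tDeletion - Frameshift\t7:140753400-140753410\n"
            "BRAF\tS3\tSomething Exotic\t7:140753500-140753500\n")
        records = parse_mutation_table(p)
        assert len(records) == 3
        assert records[0].mutation_class == "substitution_missense"
        assert records[1].mutation_class == "deletion_frameshift"
        assert records[2].mutation_class == "other"
        # 1-based inclusive on disk -> 0-based half-open internally
        iv = records[0].genomic_interval
        assert (iv.chrom, iv.start, iv.end) == ("7", 140753335, 140753336)

    def test_missing_column_is_hard_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("Gene name\tID_sample\tMutation Description\n"
                     "BRAF\tS1\tSubstitution - Missense\n")
        with pytest.raises(ValueError, match="Mutation genome position"):
            parse_mutation_table(p)

    def test_unparseable_coordinate_skipped_not_fatal(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "Gene name\tID_sample\tMutation Description\t"
            "Mutation genome position\n"
            "BRAF\tS1\tSubstitution - Missense\tnot-a-coordinate\n"
            "BRAF\tS2\tSubstitution - Missense\t7:10-10\n")
        records = parse_mutation_table(p)
        assert [r.sample_id for r in records] == ["S2"]

    @pytest.mark.parametrize("raw,expected", [
        ("Substitution - Missense", "substitution_missense"),
        ("Substitution - Nonsense", "substitution_nonsense"),
        ("Substitution - coding silent", "substitution_synonymous"),
        ("Deletion - In frame", "deletion_in_frame"),
        ("Insertion - In frame", "insertion_in_frame"),
        ("Complex - deletion inframe", "complex_deletion_in_frame"),
        ("Deletion - Frameshift", "deletion_frameshift"),
        ("Insertion - Frameshift", "insertion_frameshift"),
        ("Whole gene deletion", "other"),
    ])
    def test_vocabulary_map(self, raw, expected):
        assert normalize_mutation_class(raw) == expected


class TestClassification:
    @pytest.mark.parametrize("gof,lof,total,label", [
        (25, 3, 100, ONCOGENE),          # ONG 25 > 20, TSG 3 <= 5
        (25, 10, 100, TUMOR_SUPPRESSOR),  # ONG 25 > 20, TSG 10 > 5
        (10, 25, 100, TUMOR_SUPPRESSOR),  # ONG 10 < 20, TSG 25 > 20
        (10, 10, 100, UNCLASSIFIED),      # both < 20
        (20, 3, 100, UNCLASSIFIED),       # ONG exactly 20: no row matches
        (10, 20, 100, UNCLASSIFIED),      # TSG exactly 20 with ONG < 20
        (25, 5, 100, ONCOGENE),           # TSG exactly 5 is <= 5
    ])
    def test_decision_grid(self, gof, lof, total, label):
        scores = classify_gene(_mix(gof, lof, total))
        assert scores.x == gof and scores.y == lof
        assert scores.label == label

    def test_scores_are_percentages(self):
        s = classify_gene(_mix(25, 3, 100))
        assert s.ong_score == pytest.approx(25.0)
        assert s.tsg_score == pytest.approx(3.0)

    def test_permutation_invariant(self):
        recs = _mix(25, 10, 60)
        shuffled = recs.copy()
        random.Random(0).shuffle(shuffled)
        assert classify_gene(recs) == classify_gene(shuffled)

    def test_zero_records_rejected(self):
        with pytest.raises(ValueError, match="no mutation annotations"):
            classify_gene([])

    def test_recurrence_filter_drops_singleton_missense(self):
        # 30 missense spread over 30 positions (single sample each) plus
        # 70 synonymous: with a recurrence requirement of 2 samples per
        # position, no missense counts and the gene is unclassified.
        recs = [_rec(sample=f"S{i}", pos0=100 + i) for i in range(30)]
        recs += [_rec(sample=f"U{i}", mclass="substitution_synonymous",
                      pos0=500) for i in range(70)]
        assert classify_gene(recs).label == ONCOGENE
        filtered = classify_gene(recs, recurrence_threshold=2)
        assert filtered.x == 0
        assert filtered.label == UNCLASSIFIED

    @settings(max_examples=200, derandomize=True)
    @given(gof=st.integers(0, 40), lof=st.integers(0, 40),
           extra=st.integers(1, 40))
    def test_grid_is_total(self, gof, lof, extra):
        """Every score pair gets exactly one of the three labels."""
        label = classify_gene(_mix(gof, lof, gof + lof + extra)).label
        assert label in {ONCOGENE, TUMOR_SUPPRESSOR, UNCLASSIFIED}


class TestExonCounts:
    def test_hand_counted_example(self, nras_model):
        exon_a = nras_model.transcripts[0].exons[2]  # exon 3
        exon_b = nras_model.transcripts[0].exons[3]  # exon 4
        recs = [
            _rec(sample="P1", chrom="chrN", pos0=exon_a.interval.start + 5),
            _rec(sample="P1", chrom="chrN", pos0=exon_a.interval.start + 9),
            _rec(sample="P2", chrom="chrN", pos0=exon_a.interval.start + 5),
            _rec(sample="P3", chrom="chrN", pos0=exon_b.interval.start + 1),
        ]
        by_id = {s.exon_id: s
                 for s in count_patients_per_exon(recs, nras_model)}
        assert by_id[exon_a.id].absolute_freq == 2  # P1 counted once
        assert by_id[exon_a.id].relative_freq == pytest.approx(2 / 3)
        assert by_id[exon_b.id].absolute_freq == 1
        assert by_id[exon_b.id].relative_freq == pytest.approx(1 / 3)

    def test_first_base_of_exon_counts(self, nras_model):
        exon = nras_model.transcripts[0].exons[2]
        recs = [_rec(sample="P1", chrom="chrN", pos0=exon.interval.start)]
        by_id = {s.exon_id: s
                 for s in count_patients_per_exon(recs, nras_model)}
        assert by_id[exon.id].absolute_freq == 1
        # one base earlier falls in the intron
        recs = [_rec(sample="P1", chrom="chrN",
                     pos0=exon.interval.start - 1)]
        by_id = {s.exon_id: s
                 for s in count_patients_per_exon(recs, nras_model)}
        assert by_id[exon.id].absolute_freq == 0

    def test_non_point_mutations_ignored(self, nras_model):
        exon = nras_model.transcripts[0].exons[2]
        recs = [_rec(sample="P1", mclass="deletion_frameshift",
                     chrom="chrN", pos0=exon.interval.start + 5)]
        assert all(s.absolute_freq == 0
                   for s in count_patients_per_exon(recs, nras_model))

    def test_empty_input_gives_zero_counts(self, nras_model):
        summaries = count_patients_per_exon([], nras_model)
        assert summaries and all(s.absolute_freq == 0 for s in summaries)

    def test_exon_count_bounded_by_gene_count(self, nras_fixture,
                                              nras_model):
        recs = [r for r in parse_mutation_table(nras_fixture["mutations"])
                if r.gene == "NRASL"]
        summaries = count_patients_per_exon(recs, nras_model)
        # independent denominator: distinct samples with >= 1 point
        # mutation overlapping any exon of the gene
        exon_ivs = {e.id: e.interval for t in nras_model.transcripts
                    for e in t.exons}
        denom = len({
            r.sample_id for r in recs
            if r.mutation_class.startswith("substitution")
            and r.genomic_interval is not None
            and any(iv.overlaps(r.genomic_interval)
                    for iv in exon_ivs.values())})
        assert denom > 0
        for s in summaries:
            assert s.absolute_freq <= denom
            assert s.relative_freq == pytest.approx(s.absolute_freq / denom)


class TestRanking:
    def _summaries(self, triples):
        return [ExonMutationSummary(e, a, r) for e, a, r in triples]

    def test_top_k_with_distinct_counts(self):
        s = self._summaries([(f"E{i:02d}", i, i / 100) for i in range(12)])
        top = rank_exons_by_mutation(s, k=10)
        assert len(top) == 10
        assert top[0].exon_id == "E11" and top[0].rank == 1

    def test_fewer_exons_than_k(self):
        s = self._summaries([("A", 3, 0.5), ("B", 1, 0.2)])
        assert [x.exon_id for x in rank_exons_by_mutation(s, k=10)] \
            == ["A", "B"]

    def test_tie_break_matches_bruteforce_oracle(self):
        rnd = random.Random(42)
        s = self._summaries([(f"E{i:02d}", rnd.randint(0, 3),
                              rnd.choice([0.1, 0.2])) for i in range(20)])
        oracle = sorted(s, key=lambda x: (-x.absolute_freq,
                                          -x.relative_freq, x.exon_id))
        got = rank_exons_by_mutation(s, k=20)
        assert [x.exon_id for x in got] == [x.exon_id for x in oracle]
        # fully tied pair: lexicographically smaller id first
        pair = self._summaries([("B", 2, 0.4), ("A", 2, 0.4)])
        assert [x.exon_id for x in rank_exons_by_mutation(pair)] == ["A", "B"]


class TestTopFractionGenes:
    def _records(self, counts: dict[str, int]):
        return [_rec(gene=g, sample=f"{g}-{i}")
                for g, n in counts.items() for i in range(n)]

    def test_top_ten_percent_of_twenty_genes(self):
        counts = {f"G{i:02d}": i + 1 for i in range(20)}
        top = select_top_fraction_genes(self._records(counts), 0.10)
        assert sorted(top) == ["G18", "G19"]

    def test_fraction_one_keeps_all(self):
        counts = {"A": 3, "B": 1}
        assert sorted(select_top_fraction_genes(
            self._records(counts), 1.0)) == ["A", "B"]

    def test_tie_at_cut_includes_both(self):
        counts = {"A": 5, "B": 3, "C": 3, "D": 1}
        # ceil(0.5 * 4) = 2, but C ties with B at 3 samples
        top = select_top_fraction_genes(self._records(counts), 0.5)
        assert sorted(top) == ["A", "B", "C"]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            select_top_fraction_genes(self._records({"A": 1}), bad)
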