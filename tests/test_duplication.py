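"""Pairwise similarity and tandem/segmental classification rules."""

import pytest

from famchar.core_io import GeneLocus
from famchar.duplication import (
    DEFAULT_THRESHOLDS,
    PairAlignmentStats,
    classify_pair,
    genomic_gap,
    intervening_gene_count,
    pairwise_similarity,
    scan_duplications,
)
from famchar.family_assign import assign_groups, filter_hits


def locus(gid, chrom, start, end, in_family=False):
    return GeneLocus(gid, chrom, start, end, "+", in_family)


class TestPairwiseSimilarity:
    def test_identical_sequences(self):
        s = pairwise_similarity("MKVLAT", "MKVLAT")
        assert s.identity_pct == 100.0 and s.coverage_pct == 100.0

    def test_completely_different_same_length(self):
        s = pairwise_similarity("AAAA", "WWWW")
        assert s.identity_pct == 0.0

    def test_single_substitution_hand_alignment(self):
        # gapless is optimal: 5 identical of 6 columns
        s = pairwise_similarity("MKVLAT", "MKVLAA")
        assert s.identity_pct == pytest.approx(100 * 5 / 6, abs=1e-9)
        assert s.coverage_pct == 100.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_similarity("", "MK")


class TestGapAndIntervening:
    def test_gap_between_nearest_ends(self):
        assert genomic_gap(locus("a", "chr1", 100, 200), locus("b", "chr1", 301, 400)) == 100
        assert genomic_gap(locus("a", "chr1", 100, 200), locus("b", "chr1", 150, 400)) == 0

    def test_adjacent_genes_no_intervening(self):
        a, b = locus("a", "chr1", 100, 200, True), locus("b", "chr1", 300, 400, True)
        assert intervening_gene_count(a, b, [a, b]) == 0

    def test_family_members_not_counted(self):
        a = locus("a", "chr1", 100, 200, True)
        b = locus("b", "chr1", 10_000, 11_000, True)
        between = [
            locus("n1", "chr1", 300, 400),
            locus("n2", "chr1", 500, 600),
            locus("n3", "chr1", 700, 800),
            locus("fam", "chr1", 1_000, 1_100, in_family=True),
        ]
        assert intervening_gene_count(a, b, [a, b] + between) == 3

    def test_overlapping_loci_empty_interval(self):
        a = locus("a", "chr1", 100, 500, True)
        b = locus("b", "chr1", 300, 700, True)
        assert intervening_gene_count(a, b, [a, b, locus("n", "chr1", 350, 360)]) == 0

    def test_different_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            intervening_gene_count(
                locus("a", "chr1", 1, 10), locus("b", "chr2", 1, 10), []
            )

    def test_gap_triangle_consistency(self):
        a = locus("a", "chr1", 100, 200)
        b = locus("b", "chr1", 1_000, 2_000)
        c = locus("c", "chr1", 5_000, 6_000)
        span_b = b.length
        assert genomic_gap(a, c) <= genomic_gap(a, b) + span_b + genomic_gap(b, c)


class TestClassifyPair:
    def make_loci(self, geom):
        if geom == "tandem":  # same chromosome, 50 kb gap, 3 intervening
            pair = [locus("a", "chr1", 100_000, 101_000, True),
                    locus("b", "chr1", 151_001, 152_000, True)]
            noise = [locus(f"n{i}", "chr1", 110_000 + i * 5_000, 110_500 + i * 5_000)
                     for i in range(3)]
        elif geom == "cross":  # different chromosomes
            pair = [locus("a", "chr1", 100_000, 101_000, True),
                    locus("b", "chr5", 100_000, 101_000, True)]
            noise = []
        else:  # same chromosome but 2 Mb apart
            pair = [locus("a", "chr1", 100_000, 101_000, True),
                    locus("b", "chr1", 2_101_000, 2_102_000, True)]
            noise = []
        all_loci = pair + noise
        return {g.gene_id: g for g in pair}, all_loci

    def test_tandem_geometry(self):
        loci, all_loci = self.make_loci("tandem")
        stats = PairAlignmentStats("a", "b", identity_pct=95.0, coverage_pct=100.0)
        assert classify_pair(stats, loci, all_loci).klass == "tandem"

    def test_cross_chromosome_segmental(self):
        loci, all_loci = self.make_loci("cross")
        stats = PairAlignmentStats("a", "b", identity_pct=78.0, coverage_pct=85.0)
        call = classify_pair(stats, loci, all_loci)
        assert call.klass == "segmental" and not call.same_chromosome

    def test_distant_low_coverage_pair_uncalled(self):
        loci, all_loci = self.make_loci("far")
        stats = PairAlignmentStats("a", "b", identity_pct=78.0, coverage_pct=60.0)
        assert classify_pair(stats, loci, all_loci).klass == "none"

    def test_pure_function_of_evidence(self):
        loci, all_loci = self.make_loci("cross")
        stats = PairAlignmentStats("a", "b", identity_pct=78.0, coverage_pct=85.0)
        first = classify_pair(stats, loci, all_loci)
        second = classify_pair(stats, loci, all_loci)
        assert first == second

    def test_missing_locus_rejected(self):
        loci, all_loci = self.make_loci("cross")
        stats = PairAlignmentStats("a", "zz", identity_pct=90.0, coverage_pct=90.0)
        with pytest.raises(ValueError, match="zz"):
            classify_pair(stats, loci, all_loci)

    def test_segmental_bounds_are_strict(self):
        loci, all_loci = self.make_loci("cross")
        at_bound = PairAlignmentStats("a", "b", identity_pct=70.0, coverage_pct=80.0)
        assert classify_pair(at_bound, loci, all_loci).klass == "none"


class TestScanDuplications:
    def test_planted_pairs_recovered_with_full_precision(self, family_bundle):
        b = family_bundle
        roster = assign_groups(filter_hits(b.hits), loci=b.loci)
        calls = scan_duplications(roster, b.proteins, b.loci)
        tandem = {tuple(sorted((c.id_a, c.id_b))) for c in calls if c.klass == "tandem"}
        seg = {tuple(sorted((c.id_a, c.id_b))) for c in calls if c.klass == "segmental"}
        assert tandem == {tuple(sorted(p)) for p in b.truth.tandem_pairs}
        assert seg == {tuple(sorted(p)) for p in b.truth.segmental_pairs}

    def test_invariant_to_input_row_order(self, family_bundle):
        b = family_bundle
        roster = assign_groups(filter_hits(b.hits), loci=b.loci)
        fwd = scan_duplications(roster, b.proteins, b.loci)
        rev = scan_duplications(roster, list(reversed(b.proteins)), list(reversed(b.loci)))
        assert fwd == rev

    def test_no_candidates_gives_empty_list(self):
        from famchar.core_io import DomainHit, ProteinRecord

        hits = [DomainHit("a", "PF00257", 1e-9), DomainHit("b", "PF00257", 1e-9)]
        roster = assign_groups(hits)
        seqs = [ProteinRecord("a", "MKVLATWCDE" * 4), ProteinRecord("b", "GGHHRRNNQQ" * 4)]
        all_loci = [locus("a", "chr1", 1, 120, True), locus("b", "chr2", 1, 120, True)]
        assert scan_duplications(roster, seqs, all_loci) == []

    def test_missing_sequence_rejected(self, family_bundle):
        b = family_bundle
        roster = assign_groups(filter_hits(b.hits), loci=b.loci)
        with pytest.raises(ValueError, match="sequence missing"):
            scan_duplications(roster, b.proteins[:-1], b.loci)
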