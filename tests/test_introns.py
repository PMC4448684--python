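"""Exhaustive intron search and decoy-FDR tests."""

import numpy as np
import pytest

from splicesurvey.genome import AnnotationSet, GenomeModel, revcomp
from splicesurvey.introns import (
    CandidateIntron,
    FdrPoint,
    Region,
    build_exhaustive_db,
    classify_intron,
    collapse_redundancy,
    dinucleotide_pairs,
    enumerate_candidate_introns,
    fdr_curve,
    inefficiency_partition,
    one_annotated_site_count,
    select_threshold,
)

from conftest import make_gene, random_genome, scan_introns


def test_256_combinations():
    pairs = dinucleotide_pairs()
    assert len(pairs) == 256
    assert len(set(pairs)) == 256
    assert ("GT", "AG") in pairs


class TestEnumerate:
    def region(self, seq, strand="+", start=0):
        return Region("c", start, start + len(seq), strand, seq)

    def test_no_donor_empty(self):
        assert enumerate_candidate_introns(self.region("AAAACCCCAAAACCCC"), "GT", "AG") == []

    def test_matches_quadratic_scan(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        region = self.region(seq)
        for donor, acceptor in [("GT", "AG"), ("CA", "TT"), ("GG", "GG")]:
            got = sorted(
                (c.start, c.end)
                for c in enumerate_candidate_introns(region, donor, acceptor, 10)
            )
            assert got == scan_introns(seq, donor, acceptor, 10)

    def test_min_length_boundary(self):
        # GT at 0, AG ending at 9 (too short) and at 10 (included)
        seq = "GTCCCCCAGA"  # intron GT..AG inclusive = positions 0..9, len 9? craft:
        seq = "GTCCCCCCAG"  # GT at 0, AG at 8..10 -> intron len 10
        region = self.region(seq)
        got = enumerate_candidate_introns(region, "GT", "AG", 10)
        assert [(c.start, c.end) for c in got] == [(0, 10)]
        assert enumerate_candidate_introns(region, "GT", "AG", 11) == []

    def test_minus_strand_coordinates_and_symmetry(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        plus = Region("c", 1000, 1200, "+", seq)
        minus = Region("c", 1000, 1200, "-", seq)  # same oriented sequence
        got_plus = enumerate_candidate_introns(plus, "GT", "AG", 10)
        got_minus = enumerate_candidate_introns(minus, "GT", "AG", 10)
        # same region-coordinate hits, mirrored genomic coordinates
        assert len(got_plus) == len(got_minus)
        mirrored = sorted((2200 - c.end, 2200 - c.start) for c in got_plus)
        assert sorted((c.start, c.end) for c in got_minus) == mirrored

    def test_strand_symmetry_via_revcomp(self):
        """Searching the − strand equals the + search on the reverse
        complement (the oriented region sequence already encodes this)."""
        rng = np.random.default_rng(7)
        fwd = "".join(rng.choice(list("ACGT"), size=150))
        a = enumerate_candidate_introns(Region("c", 0, 150, "+", revcomp(fwd)), "GT", "AG")
        b = enumerate_candidate_introns(Region("c", 0, 150, "-", revcomp(fwd)), "GT", "AG")
        assert [(c.end - c.start) for c in a] == [(c.end - c.start) for c in b]
        assert sorted((c.start, c.end) for c in b) == sorted(
            (150 - e, 150 - s) for s, e in ((c.start, c.end) for c in a)
        )


class TestExhaustiveDb:
    @pytest.fixture
    def world(self):
        rng = np.random.default_rng(17)
        genome = random_genome(rng, {"c": 900})
        genes = [
            make_gene("g1", "c", "+", [(100, 160), (200, 260)]),
            make_gene("g2", "c", "-", [(400, 470), (520, 580)]),
        ]
        return genome, AnnotationSet(genes)

    def test_flank_truncation_at_region_edge(self, world):
        genome, ann = world
        db = build_exhaustive_db(ann, genome, gene_flank=10, junction_flank=57,
                                 combos=[("GT", "AG")])
        for j in db.junctions:
            assert j.left_flank_len <= 57 and j.right_flank_len <= 57
        assert any(j.left_flank_len < 57 for j in db.junctions)

    def test_overlapping_regions_collapse(self, world):
        genome, ann = world
        # two annotations of the same gene -> overlapping identical regions
        twin = AnnotationSet([ann.genes[0],
                              make_gene("g1b", "c", "+", ann.genes[0].exons)])
        db1 = build_exhaustive_db(
            AnnotationSet([ann.genes[0]]), genome, 50, 30, combos=[("GT", "AG")]
        )
        db2 = build_exhaustive_db(twin, genome, 50, 30, combos=[("GT", "AG")])
        assert {j.junction_id for j in db1.junctions} == {
            j.junction_id for j in db2.junctions
        }

    def test_min_intron_respected(self, world):
        genome, ann = world
        db = build_exhaustive_db(ann, genome, 20, 30, min_intron_len=10,
                                 combos=[("GT", "AG")])
        for j in db.junctions:
            _, _, _, span = j.junction_id.split(":")
            lo, hi = (int(x) for x in span.split("-"))
            assert hi - lo >= 10


class TestFdr:
    def _cand(self, n, canonical, support):
        return CandidateIntron(
            chromosome="c", strand="+", start=n * 100, end=n * 100 + 50,
            donor_dinuc="GT" if canonical else "CA",
            acceptor_dinuc="AG" if canonical else "TT",
            left_flank_len=57, right_flank_len=57,
            unique_start_count=support, unique_sequence_count=support,
        )

    def test_formula_and_zero_cases(self):
        cands = [self._cand(i, True, 20) for i in range(95)] + [
            self._cand(100 + i, False, 20) for i in range(5)
        ]
        curve = fdr_curve(cands, thresholds=[1])
        assert curve[0].canonical_count == 95
        assert curve[0].random_count == 5
        assert curve[0].fdr == pytest.approx(0.05)
        only_canonical = [self._cand(i, True, 5) for i in range(10)]
        assert all(p.fdr == 0.0 for p in fdr_curve(only_canonical, [1, 2, 3]))

    def test_counts_non_increasing_in_threshold(self):
        rng = np.random.default_rng(12)
        cands = [
            self._cand(i, bool(rng.integers(0, 2)), int(rng.integers(1, 40)))
            for i in range(60)
        ]
        curve = fdr_curve(cands)
        cs = [p.canonical_count for p in curve]
        rs = [p.random_count for p in curve]
        assert cs == sorted(cs, reverse=True)
        assert rs == sorted(rs, reverse=True)

    def test_select_threshold(self):
        curve = [
            FdrPoint(10, 100, 20, 20 / 120),
            FdrPoint(13, 95, 4, 4 / 99),
            FdrPoint(14, 90, 2, 2 / 92),
        ]
        assert select_threshold(curve, alpha=0.05) == 13
        zero = [FdrPoint(1, 10, 0, 0.0), FdrPoint(2, 8, 0, 0.0)]
        assert select_threshold(zero, 0.05) == 1
        bad = [FdrPoint(1, 5, 5, 0.5), FdrPoint(2, 3, 3, 0.5)]
        with pytest.warns(UserWarning, match="no threshold"):
            assert select_threshold(bad, 0.05) == 2

    def test_pooling_invariant_to_sample_relabeling(self):
        """FDR depends only on pooled supports, not on how reads are split
        across samples (supports here are already pooled quantities)."""
        cands = [self._cand(i, i % 3 > 0, 5 + i) for i in range(20)]
        curve1 = fdr_curve(cands)
        np.random.default_rng(1).shuffle(cands)
        curve2 = fdr_curve(cands)
        assert curve1 == curve2


class TestClassify:
    @pytest.fixture
    def annotated(self):
        # gene with one intron [160, 200) on +
        genes = [make_gene("g", "c", "+", [(100, 160), (200, 260)],
                           biotype="protein_coding"),
                 make_gene("nc", "c", "+", [(400, 500)], biotype="ncRNA")]
        return AnnotationSet(genes)

    def _cand(self, start, end):
        return CandidateIntron(
            chromosome="c", strand="+", start=start, end=end,
            donor_dinuc="GT", acceptor_dinuc="AG",
            left_flank_len=57, right_flank_len=57,
        )

    def test_known(self, annotated):
        c = classify_intron(self._cand(160, 200), annotated)
        assert c.status == "known"
        assert c.location_class == "protein_coding"

    def test_one_annotated_site(self, annotated):
        c = classify_intron(self._cand(160, 230), annotated)
        assert c.status == "one_annotated_donor"
        c2 = classify_intron(self._cand(140, 200), annotated)
        assert c2.status == "one_annotated_acceptor"

    def test_both_novel_and_location(self, annotated):
        c = classify_intron(self._cand(120, 150), annotated)
        assert c.status == "both_novel" and c.location_class == "protein_coding"
        c2 = classify_intron(self._cand(420, 460), annotated)
        assert c2.location_class == "ncRNA"
        c3 = classify_intron(self._cand(700, 750), annotated)
        assert c3.location_class == "intergenic"

    def test_inclusion_exclusion_worked_example(self):
        assert one_annotated_site_count(1155, 1007, 252) == 1910


class TestPartitionAndCollapse:
    def _cand(self, start, support):
        return CandidateIntron(
            chromosome="c", strand="+", start=start, end=start + 30,
            donor_dinuc="GT", acceptor_dinuc="AG",
            left_flank_len=57, right_flank_len=57,
            unique_sequence_count=support, unique_start_count=support,
            read_count=support,
        )

    def test_boundary_70_71(self):
        cryptic, novel = inefficiency_partition(
            [self._cand(0, 70), self._cand(100, 71)], cutoff=70
        )
        assert [c.start for c in cryptic] == [0]
        assert [c.start for c in novel] == [100]
        assert inefficiency_partition([], 70) == ([], [])

    def test_collapse_same_intron(self):
        a, b = self._cand(0, 10), self._cand(0, 7)
        b.per_sample = {"s2": {"read_count": 7}}
        a.per_sample = {"s1": {"read_count": 10}}
        merged = collapse_redundancy([a, b])
        assert len(merged) == 1
        assert merged[0].unique_start_count == 10
        assert set(merged[0].per_sample) == {"s1", "s2"}
        distinct = collapse_redundancy([self._cand(0, 1), self._cand(50, 1)])
        assert len(distinct) == 2
        assert collapse_redundancy([]) == []
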