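"""Read-mapping tests: uniqueness, overhang, staged protocol, oracle."""

import numpy as np
import pytest

from splicesurvey.genome import AnnotationSet, GenomeModel, revcomp, spliced_sequence
from splicesurvey.junctions import assemble_database
from splicesurvey.mapping import (
    JunctionCountTable,
    ReadAlignment,
    ReadMapper,
    map_read,
    overhang_ok,
    run_staged_mapping,
    summarize_counts,
)

from conftest import make_gene, random_genome, scan_classify


@pytest.fixture(scope="module")
def world():
    """A small genome with two genes and a normal+skipping database."""
    rng = np.random.default_rng(42)
    genome = random_genome(rng, {"chr": 3000})
    genes = [
        make_gene("g1", "chr", "+", [(100, 200), (250, 350), (400, 500)]),
        make_gene("g2", "chr", "-", [(700, 790), (850, 950), (1000, 1100)]),
    ]
    ann = AnnotationSet(genes)
    db = assemble_database(genes, genome, 57, kinds={"normal", "skipping"})
    return genome, ann, db


def mutate(seq: str, positions: list[int]) -> str:
    rotate = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = rotate[out[p]]
    return "".join(out)


class TestMapRead:
    def test_junction_read_unique_zero_mismatch(self, world):
        genome, ann, db = world
        jx = next(j for j in db.junctions if j.junction_id == "g1:normal:1-2")
        read = jx.sequence[30:87]
        res = map_read(read, genome, db, 3)
        assert res.status == "unique"
        assert res.alignment.target_id == "g1:normal:1-2"
        assert res.alignment.mismatches == 0
        assert res.alignment.offset == 30

    def test_mismatched_read_counts_mismatches(self, world):
        genome, ann, db = world
        jx = next(j for j in db.junctions if j.junction_id == "g1:normal:2-3")
        read = mutate(jx.sequence[20:77], [5, 30])
        res = map_read(read, genome, db, 3)
        assert res.status == "unique"
        assert res.alignment.mismatches == 2

    def test_four_mismatches_unmapped(self, world):
        genome, ann, db = world
        jx = db.junctions[0]
        read = mutate(jx.sequence[10:67], [3, 17, 31, 45])
        # also mutate relative to any genome hit: junction reads cross introns
        assert map_read(read, genome, db, 3).status == "unmapped"

    def test_ambiguous_between_two_junctions(self, world):
        genome, ann, db = world
        # craft two junctions sharing the identical sequence via a duplicated db
        from splicesurvey.junctions import Junction, JunctionDatabase

        jx = db.junctions[0]
        twin = Junction(
            junction_id="twin", kind=jx.kind, gene_id="gX",
            donor_exon=1, acceptor_exon=2, sequence=jx.sequence,
            left_flank_len=jx.left_flank_len, right_flank_len=jx.right_flank_len,
        )
        db2 = JunctionDatabase(read_len=57, junctions=[*db.junctions, twin])
        read = jx.sequence[25:82]
        assert map_read(read, genome, db2, 3).status == "ambiguous"

    def test_exonic_read_genome_unique(self, world):
        genome, ann, db = world
        read = genome.fetch("chr", 120, 177)  # inside g1 exon 1
        res = map_read(read, genome, db, 3)
        assert res.status == "unique"
        assert res.alignment.target_kind == "genome"
        assert res.alignment.offset == 120

    def test_reverse_strand_read_maps(self, world):
        genome, ann, db = world
        read = revcomp(genome.fetch("chr", 1500, 1557))
        res = map_read(read, genome, db, 0)
        assert res.status == "unique"
        assert res.alignment.strand == "-"
        assert res.alignment.offset == 1500

    def test_read_with_n_never_matches_reference(self, world):
        genome, ann, db = world
        read = genome.fetch("chr", 1500, 1557)
        read_n = read[:10] + "N" + read[11:]
        res = map_read(read_n, genome, db, 0)
        assert res.status == "unmapped"
        res3 = map_read(read_n, genome, db, 3)
        assert res3.status == "unique" and res3.alignment.mismatches == 1

    def test_invalid_characters_rejected(self, world):
        genome, ann, db = world
        assert map_read("ACGTX" + "A" * 52, genome, db, 3).status == "rejected"

    def test_short_read_raises(self, world):
        genome, ann, db = world
        with pytest.raises(ValueError):
            map_read("ACGTACGTACGT", genome, db, 3)


class TestOverhang:
    @pytest.mark.parametrize(
        "left,right", [(5, 52), (6, 51), (28, 29)], ids=["5-52", "6-51", "28-29"]
    )
    def test_boundaries(self, left, right):
        aln = ReadAlignment(
            target_kind="junction", target_id="j", offset=0, strand="+",
            mismatches=0, read_len=left + right,
            overhang_left=left, overhang_right=right,
        )
        assert overhang_ok(aln) is (left >= 6 and right >= 6)

    def test_genome_alignment_rejected(self):
        aln = ReadAlignment(
            target_kind="genome", target_id="chr", offset=0, strand="+",
            mismatches=0, read_len=57,
        )
        with pytest.raises(ValueError):
            overhang_ok(aln)


def test_full_length_reads_always_pass_overhang(world):
    """With flanks of X-6 nt, any full-length alignment inside a
    normal/skipping junction overlaps the breakpoint by >= 6 nt per side."""
    genome, ann, db = world
    mapper = ReadMapper(genome, db, 0)
    for jx in db.junctions:
        for off in range(len(jx.sequence) - 57 + 1):
            res = mapper.map(jx.sequence[off : off + 57])
            if res.status == "unique" and res.alignment.target_kind == "junction":
                assert overhang_ok(res.alignment), (jx.junction_id, off)


class TestStagedMapping:
    def test_skip_read_traced_once(self, world):
        genome, ann, db = world
        g1 = ann.genes[0]
        circ_db = assemble_database(ann.genes, genome, 63, kinds={"circular"})
        skip_iso = spliced_sequence(g1, genome, [1, 3])
        read = skip_iso[100 - 28 : 100 - 28 + 57]  # spans the exon1|exon3 joint
        read = mutate(read, [10])
        table, report = run_staged_mapping(
            {read: 1}, genome, db, circ_db=circ_db, sample_id="s"
        )
        assert table.read_count("s", "g1:skip:1-3") == 1
        assert report.tallies["stage1"]["junction_unique"] == 1
        assert "stage2" not in report.tallies  # nothing left unmapped

    def test_exonic_read_never_a_junction_count(self, world):
        genome, ann, db = world
        read = genome.fetch("chr", 260, 317)  # inside g1 exon 2
        table, report = run_staged_mapping({read: 1}, genome, db, sample_id="s")
        assert report.tallies["stage1"]["genome_unique"] == 1
        assert table.junctions("s") == []

    def test_backsplice_read_found_in_stage2(self, world):
        genome, ann, db = world
        g1 = ann.genes[0]
        circ_db = assemble_database(ann.genes, genome, 63, kinds={"circular"})
        exon2 = g1.exon_seq(genome, 2)
        circle_read = (exon2 + exon2)[100 - 20 : 100 - 20 + 57]  # tail->head joint
        table, report = run_staged_mapping(
            {circle_read: 2}, genome, db, circ_db=circ_db, sample_id="s"
        )
        assert report.tallies["stage1"]["unmapped"] == 2
        assert report.tallies["stage2"]["junction_unique"] == 2
        assert table.read_count("s", "g1:circ:2-2") == 2

    def test_conservation_of_reads(self, world):
        genome, ann, db = world
        rng = np.random.default_rng(3)
        reads = {}
        for _ in range(60):
            pos = int(rng.integers(0, 2943))
            reads[genome.fetch("chr", pos, pos + 57)] = int(rng.integers(1, 4))
        reads["".join(rng.choice(list("ACGT"), size=57))] = 2
        table, report = run_staged_mapping(reads, genome, db, sample_id="s")
        assert sum(report.tallies["stage1"].values()) == sum(reads.values())
        assert report.n_reads == sum(reads.values())


class TestSummarize:
    def test_distinct_offsets_and_sequences(self):
        table = summarize_counts(
            [("j1", 0, "AAA", 1), ("j1", 0, "AAA", 1), ("j1", 4, "CCC", 1)], "s"
        )
        assert table.read_count("s", "j1") == 3
        assert table.unique_start_count("s", "j1") == 2
        assert table.unique_sequence_count("s", "j1") == 2

    def test_duplicate_reads_one_sequence(self):
        table = summarize_counts([("j1", 7, "AAA", 5)], "s")
        assert table.read_count("s", "j1") == 5
        assert table.unique_sequence_count("s", "j1") == 1

    def test_empty(self):
        table = summarize_counts([], "s")
        assert table.junctions() == []

    def test_merge_and_pooling(self):
        t1 = summarize_counts([("j1", 0, "AAA", 2)], "s1")
        t2 = summarize_counts([("j1", 5, "CCC", 1)], "s2")
        t1.merge(t2)
        assert t1.pooled_read_count("j1") == 3
        assert t1.pooled_unique_start_count("j1") == 2
        assert t1.pooled_unique_sequence_count("j1") == 2


def test_mapper_agrees_with_bruteforce_scanner(world):
    """Pigeonhole search vs position-by-position scanner on 250 reads of
    mixed provenance (clean, mutated, random, N-containing)."""
    genome, ann, db = world
    mapper = ReadMapper(genome, db, 3)
    targets = [("genome", "chr", genome.chromosomes["chr"])] + [
        ("junction", j.junction_id, j.sequence) for j in db.junctions
    ]
    rng = np.random.default_rng(99)
    reads = []
    for _ in range(60):
        pos = int(rng.integers(0, 2943))
        read = genome.fetch("chr", pos, pos + 57)
        reads.append(read)
        reads.append(mutate(read, list(rng.choice(57, size=3, replace=False))))
        reads.append(revcomp(read))
    for j in db.junctions:
        if len(j.sequence) >= 57:
            off = int(rng.integers(0, len(j.sequence) - 56))
            reads.append(mutate(j.sequence[off : off + 57], [int(rng.integers(57))]))
    for _ in range(30):
        reads.append("".join(rng.choice(list("ACGT"), size=57)))
    reads.append(reads[0][:20] + "N" + reads[0][21:])

    for read in reads:
        res = mapper.map(read)
        status, best = scan_classify(read, targets, 3)
        assert res.status == status, read
        if status == "unique":
            kind, tid, off, strand, mm = best[0]
            assert (res.alignment.target_kind, res.alignment.target_id) == (kind, tid)
            assert res.alignment.mismatches == mm
            assert res.alignment.strand == strand
            assert res.alignment.offset == off
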