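"""Exhaustive donor-acceptor intron search with decoy-based FDR.

Every gene region (gene span plus a flank, default 300 nt, to cover UTRs and
nearby intergenic sequence) is scanned for all 4^2 x 4^2 = 256 splice donor x
acceptor dinucleotide combinations.  Each (donor occurrence, acceptor
occurrence) pair whose intron — the segment from the donor dinucleotide to
the acceptor dinucleotide inclusive — is at least 10 nt long becomes a
candidate, and a diagnostic junction sequence of up to 57 nt of flank on
either side is emitted for 0-mismatch read mapping.

The canonical splice signal is GT..AG on the transcribed strand (GU..AG in
the RNA).  All 255 other combinations are treated as decoys: reads cannot
arise from spliceosomal splicing at those signals, so the decoy match count
estimates the false-positive rate of the canonical list,

    FDR(t) = R(t) / (C(t) + R(t)),

where C(t) and R(t) count canonical and decoy junctions supported by more
than ``t`` unique read start positions (pooled over samples).  The reported
threshold is the smallest t with FDR <= alpha.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .genome import AnnotationSet, GenomeModel, revcomp
from .junctions import Junction, JunctionDatabase
from .mapping import JunctionCountTable

logger = logging.getLogger(__name__)

CANONICAL_DONOR = "GT"
CANONICAL_ACCEPTOR = "AG"
DEFAULT_MIN_INTRON = 10
DEFAULT_GENE_FLANK = 300
DEFAULT_JUNCTION_FLANK = 57


def dinucleotide_pairs() -> list[tuple[str, str]]:
    """All donor x acceptor dinucleotide combinations (4^2 x 4^2 = 256)."""
    dinucs = ["".join(p) for p in product("ACGT", repeat=2)]
    return [(d, a) for d in dinucs for a in dinucs]


@dataclass(frozen=True)
class Region:
    """A strand-oriented search region: ``seq`` is the transcribed-strand
    sequence of genomic interval [start, end) on ``chromosome``."""

    chromosome: str
    start: int
    end: int
    strand: str
    seq: str
    gene_id: str = ""

    def genomic_interval(self, region_start: int, region_end: int) -> tuple[int, int]:
        """Map a half-open interval in region coordinates to genomic
        (ascending) coordinates."""
        if self.strand == "+":
            return self.start + region_start, self.start + region_end
        return self.end - region_end, self.end - region_start


@dataclass
class CandidateIntron:
    """A candidate intron found by the exhaustive search.

    ``start``/``end`` delimit the intron as a genomic half-open interval;
    the donor site sits at ``start`` on + and at ``end`` on −.
    """

    chromosome: str
    strand: str
    start: int
    end: int
    donor_dinuc: str
    acceptor_dinuc: str
    left_flank_len: int
    right_flank_len: int
    gene_id: str = ""
    read_count: int = 0
    unique_start_count: int = 0
    unique_sequence_count: int = 0
    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)
    donor_annotated: bool = False
    acceptor_annotated: bool = False
    status: str = ""  # known | one_annotated_donor | one_annotated_acceptor | both_novel
    location_class: str = ""  # protein_coding | ncRNA | intergenic

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def canonical(self) -> bool:
        return (
            self.donor_dinuc == CANONICAL_DONOR
            and self.acceptor_dinuc == CANONICAL_ACCEPTOR
        )

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chromosome, self.strand, self.start, self.end)

    @property
    def junction_id(self) -> str:
        return f"novel:{self.chromosome}:{self.strand}:{self.start}-{self.end}"


@dataclass(frozen=True)
class FdrPoint:
    threshold: int
    canonical_count: int
    random_count: int
    fdr: float | None  # None when no junction survives the threshold


def _dinuc_positions(seq: str) -> dict[str, list[int]]:
    positions: dict[str, list[int]] = {}
    for i in range(len(seq) - 1):
        positions.setdefault(seq[i : i + 2], []).append(i)
    return positions


def enumerate_candidate_introns(
    region: Region,
    donor_dinuc: str,
    acceptor_dinuc: str,
    min_len: int = DEFAULT_MIN_INTRON,
    junction_flank: int = DEFAULT_JUNCTION_FLANK,
    _dinuc_index: dict[str, list[int]] | None = None,
) -> list[CandidateIntron]:
    """All introns starting with ``donor_dinuc`` and ending with
    ``acceptor_dinuc`` (inclusive) of length >= ``min_len`` in the region."""
    index = _dinuc_index if _dinuc_index is not None else _dinuc_positions(region.seq)
    donors = index.get(donor_dinuc, [])
    acceptors = index.get(acceptor_dinuc, [])
    out = []
    for d in donors:
        # intron = seq[d : a+2]; need a+2-d >= min_len, i.e. a >= d+min_len-2
        lo = bisect_left(acceptors, d + min_len - 2)
        for a in acceptors[lo:]:
            a2 = a + 2
            left = region.seq[max(0, d - junction_flank) : d]
            right = region.seq[a2 : a2 + junction_flank]
            g_start, g_end = region.genomic_interval(d, a2)
            out.append(
                CandidateIntron(
                    chromosome=region.chromosome,
                    strand=region.strand,
                    start=g_start,
                    end=g_end,
                    donor_dinuc=donor_dinuc,
                    acceptor_dinuc=acceptor_dinuc,
                    left_flank_len=len(left),
                    right_flank_len=len(right),
                    gene_id=region.gene_id,
                )
            )
    return out


def gene_regions(
    annotation: AnnotationSet, genome: GenomeModel, gene_flank: int = DEFAULT_GENE_FLANK
) -> list[Region]:
    regions = []
    for g in annotation.genes:
        start = max(0, g.start - gene_flank)
        end = min(genome.length(g.chromosome), g.end + gene_flank)
        seq = genome.fetch(g.chromosome, start, end)
        if g.strand == "-":
            seq = revcomp(seq)
        regions.append(
            Region(
                chromosome=g.chromosome, start=start, end=end,
                strand=g.strand, seq=seq, gene_id=g.gene_id,
            )
        )
    return regions


def build_exhaustive_db(
    annotation: AnnotationSet,
    genome: GenomeModel,
    gene_flank: int = DEFAULT_GENE_FLANK,
    junction_flank: int = DEFAULT_JUNCTION_FLANK,
    min_intron_len: int = DEFAULT_MIN_INTRON,
    combos: list[tuple[str, str]] | None = None,
) -> JunctionDatabase:
    """Candidate-intron junction database over all gene regions and all 256
    dinucleotide combinations (or a restricted ``combos`` list).

    Identical genomic introns reachable from overlapping gene regions are
    collapsed at build time (the record with the longer flanks is kept), so
    no read can be counted twice through region redundancy.
    """
    if combos is None:
        combos = dinucleotide_pairs()
    best: dict[str, Junction] = {}
    n_dropped_n = 0
    for region in gene_regions(annotation, genome, gene_flank):
        index = _dinuc_positions(region.seq)
        for donor, acceptor in combos:
            for cand in enumerate_candidate_introns(
                region, donor, acceptor, min_intron_len, junction_flank,
                _dinuc_index=index,
            ):
                # rebuild the junction sequence from the region
                if region.strand == "+":
                    d = cand.start - region.start
                    a2 = cand.end - region.start
                else:
                    d = region.end - cand.end
                    a2 = region.end - cand.start
                seq = (
                    region.seq[max(0, d - junction_flank) : d]
                    + region.seq[a2 : a2 + junction_flank]
                )
                if "N" in seq:
                    n_dropped_n += 1
                    continue
                jid = cand.junction_id
                prev = best.get(jid)
                if prev is None or len(seq) > len(prev.sequence):
                    best[jid] = Junction(
                        junction_id=jid,
                        kind="exhaustive",
                        gene_id=region.gene_id,
                        donor_exon=cand.start,
                        acceptor_exon=cand.end,
                        sequence=seq,
                        left_flank_len=cand.left_flank_len,
                        right_flank_len=len(seq) - cand.left_flank_len,
                    )
    if n_dropped_n:
        logger.info("build_exhaustive_db: dropped %d junctions containing N", n_dropped_n)
    junctions = [best[jid] for jid in sorted(best)]
    return JunctionDatabase(read_len=junction_flank, junctions=junctions)


def collect_candidates(
    db: JunctionDatabase,
    table: JunctionCountTable,
    genome: GenomeModel,
    min_reads: int = 1,
) -> list[CandidateIntron]:
    """Candidate introns with read support from a stage-3 count table."""
    out = []
    for j in db.junctions:
        if j.kind != "exhaustive":
            continue
        pooled_reads = table.pooled_read_count(j.junction_id)
        if pooled_reads < min_reads:
            continue
        _, chrom, strand, span = j.junction_id.split(":")
        start, end = (int(x) for x in span.split("-"))
        if strand == "+":
            donor = genome.fetch(chrom, start, start + 2)
            acceptor = genome.fetch(chrom, end - 2, end)
        else:
            donor = revcomp(genome.fetch(chrom, end - 2, end))
            acceptor = revcomp(genome.fetch(chrom, start, start + 2))
        per_sample = {
            s: {
                "read_count": table.read_count(s, j.junction_id),
                "unique_start_count": table.unique_start_count(s, j.junction_id),
                "unique_sequence_count": table.unique_sequence_count(s, j.junction_id),
            }
            for s in table.samples
            if table.read_count(s, j.junction_id) > 0
        }
        out.append(
            CandidateIntron(
                chromosome=chrom,
                strand=strand,
                start=start,
                end=end,
                donor_dinuc=donor,
                acceptor_dinuc=acceptor,
                left_flank_len=j.left_flank_len,
                right_flank_len=j.right_flank_len,
                gene_id=j.gene_id,
                read_count=pooled_reads,
                unique_start_count=table.pooled_unique_start_count(j.junction_id),
                unique_sequence_count=table.pooled_unique_sequence_count(j.junction_id),
                per_sample=per_sample,
            )
        )
    return out


def collapse_redundancy(candidates: list[CandidateIntron]) -> list[CandidateIntron]:
    """Merge candidates identical in (chromosome, strand, start, end).

    Duplicates arise when overlapping gene regions emit the same genomic
    intron; a given read is never counted twice, so merged supports take the
    maximum over duplicates."""
    merged: dict[tuple, CandidateIntron] = {}
    for cand in candidates:
        prev = merged.get(cand.key)
        if prev is None:
            merged[cand.key] = cand
            continue
        prev.read_count = max(prev.read_count, cand.read_count)
        prev.unique_start_count = max(prev.unique_start_count, cand.unique_start_count)
        prev.unique_sequence_count = max(
            prev.unique_sequence_count, cand.unique_sequence_count
        )
        for s, rec in cand.per_sample.items():
            if s not in prev.per_sample:
                prev.per_sample[s] = rec
    return [merged[k] for k in sorted(merged)]


def fdr_curve(
    candidates: list[CandidateIntron],
    thresholds: list[int] | None = None,
) -> list[FdrPoint]:
    """Decoy FDR as a function of the unique-start support cutoff: at each
    threshold t, junctions with support > t are counted by class and
    FDR = R / (C + R)."""
    supports_c = sorted(c.unique_start_count for c in candidates if c.canonical)
    supports_r = sorted(c.unique_start_count for c in candidates if not c.canonical)
    if thresholds is None:
        max_support = max(
            [s for s in supports_c + supports_r] or [1]
        )
        thresholds = list(range(1, max_support + 1))
    points = []
    for t in thresholds:
        c = len(supports_c) - bisect_left(supports_c, t + 1)
        r = len(supports_r) - bisect_left(supports_r, t + 1)
        fdr = r / (c + r) if (c + r) > 0 else None
        points.append(FdrPoint(threshold=t, canonical_count=c, random_count=r, fdr=fdr))
    return points


def select_threshold(curve: list[FdrPoint], alpha: float = 0.05) -> int:
    """Smallest threshold with FDR <= alpha; falls back to the largest
    threshold (with a warning) when none qualifies."""
    if not curve:
        raise ValueError("empty FDR curve")
    for point in sorted(curve, key=lambda p: p.threshold):
        if point.fdr is not None and point.fdr <= alpha:
            return point.threshold
    import warnings

    t_max = max(p.threshold for p in curve)
    warnings.warn(
        f"no threshold reaches FDR <= {alpha}; reporting the maximum ({t_max})",
        stacklevel=2,
    )
    return t_max


def classify_intron(
    candidate: CandidateIntron, annotation: AnnotationSet
) -> CandidateIntron:
    """Annotate a candidate with its relation to the annotated intron set
    and its genomic location class (protein_coding > ncRNA > intergenic)."""
    donor_sites = annotation.donor_sites()
    acceptor_sites = annotation.acceptor_sites()
    c, st = candidate.chromosome, candidate.strand
    donor_coord = candidate.start if st == "+" else candidate.end
    acceptor_coord = candidate.end if st == "+" else candidate.start
    candidate.donor_annotated = (c, st, donor_coord) in donor_sites
    candidate.acceptor_annotated = (c, st, acceptor_coord) in acceptor_sites
    if candidate.key in {(g, s, lo, hi) for g, s, lo, hi in annotation.intron_index}:
        candidate.status = "known"
    elif candidate.donor_annotated and not candidate.acceptor_annotated:
        candidate.status = "one_annotated_donor"
    elif candidate.acceptor_annotated and not candidate.donor_annotated:
        candidate.status = "one_annotated_acceptor"
    elif candidate.donor_annotated and candidate.acceptor_annotated:
        # both sites annotated but not as a pair: an exon-skipping-like or
        # recombined intron; still one step from full novelty
        candidate.status = "both_annotated_sites"
    else:
        candidate.status = "both_novel"

    location = "intergenic"
    overlapping = [
        g
        for g in annotation.genes
        if g.chromosome == c and g.start < candidate.end and candidate.start < g.end
    ]
    if any(g.biotype == "protein_coding" for g in overlapping):
        location = "protein_coding"
    elif any(g.biotype == "ncRNA" for g in overlapping):
        location = "ncRNA"
    candidate.location_class = location
    return candidate


def one_annotated_site_count(
    n_annotated_donor: int, n_annotated_acceptor: int, n_both: int
) -> int:
    """Inclusion-exclusion count of introns using exactly one annotated
    splice site: donor-annotated + acceptor-annotated − counted-twice."""
    return n_annotated_donor + n_annotated_acceptor - n_both


def inefficiency_partition(
    candidates: list[CandidateIntron], cutoff: int = 70
) -> tuple[list[CandidateIntron], list[CandidateIntron]]:
    """Split candidates into (cryptic, putative_novel) at the unique-read-
    sequence cutoff: <= cutoff unique sequences across the junction is
    cryptic (inefficiently spliced), > cutoff is putatively novel."""
    cryptic = [c for c in candidates if c.unique_sequence_count <= cutoff]
    novel = [c for c in candidates if c.unique_sequence_count > cutoff]
    return cryptic, novel


def candidate_report(candidates: list[CandidateIntron]) -> pd.DataFrame:
    """Report TSV frame; coordinates are 1-based inclusive."""
    rows = []
    for c in sorted(candidates, key=lambda x: x.key):
        rows.append(
            {
                "chromosome": c.chromosome,
                "strand": c.strand,
                "intron_start": c.start + 1,
                "intron_end": c.end,
                "length": c.length,
                "donor_dinuc": c.donor_dinuc,
                "acceptor_dinuc": c.acceptor_dinuc,
                "canonical": c.canonical,
                "status": c.status,
                "location_class": c.location_class,
                "gene_id": c.gene_id,
                "read_count": c.read_count,
                "unique_start_count": c.unique_start_count,
                "unique_sequence_count": c.unique_sequence_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "strand", "intron_start", "intron_end", "length",
            "donor_dinuc", "acceptor_dinuc", "canonical", "status",
            "location_class", "gene_id", "read_count",
            "unique_start_count", "unique_sequence_count",
        ],
    )


def fdr_report(curve: list[FdrPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "threshold": p.threshold,
                "canonical_count": p.canonical_count,
                "random_count": p.random_count,
                "fdr": p.fdr,
            }
            for p in curve
        ],
        columns=["threshold", "canonical_count", "random_count", "fdr"],
    )
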