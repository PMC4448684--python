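"""Unique read assignment to genome and junction databases.

The matcher emulates the contract of a short-read aligner run in
"best-stratum, unique-only" mode: every alignment of the read (both
orientations, genome and junction targets) with at most ``max_mismatch``
substitutions is considered; among the hits attaining the minimal mismatch
count the read is kept only if that hit is unique.  Reads hitting two or
more targets equally well are discarded as ambiguous, reads with no hit
within the budget are unmapped.

Search strategy: exact occurrences are found with C-speed substring search
over concatenated target sequences; mismatch-tolerant search uses the
pigeonhole principle (a read with <= m mismatches has an error-free segment
when split into m+1 pieces), seeding on exact segment hits and verifying
candidates.  This is exact — no alignment within the budget can be missed —
and is validated against a brute-force position-by-position scanner in the
test suite.

``N`` never matches anything (reads are mapped conservatively): read-side N
is rewritten to a private letter so it mismatches every reference base,
including reference N.

Staged protocol (``run_staged_mapping``):

1. genome + normal/skipping junction database, up to 3 mismatches, unique
   hits only, overhang >= 6 nt on both sides of a junction breakpoint;
2. stage-1 unmapped reads against the circular (backsplice) database,
   0 mismatches, unique, overhang >= 6;
3. the same stage-1 unmapped reads against the exhaustive candidate-intron
   database, 0 mismatches, unique, overhang >= 6.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .genome import GenomeModel, revcomp
from .junctions import Junction, JunctionDatabase

READ_ALPHABET = frozenset("ACGTN")
MIN_READ_LEN = 13
DEFAULT_MIN_OVERHANG = 6

# read-side stand-in for N: never equal to any reference character
_READ_N = "n"


@dataclass(frozen=True)
class ReadAlignment:
    """A single best alignment of a read.

    ``offset`` is the leftmost covered position on the forward orientation
    of the target (chromosome or junction sequence); ``strand`` is the
    orientation of the read relative to that target.
    """

    target_kind: str  # "genome" | "junction"
    target_id: str    # chromosome name or junction_id
    offset: int
    strand: str
    mismatches: int
    read_len: int
    overhang_left: int | None = None
    overhang_right: int | None = None


@dataclass(frozen=True)
class MapResult:
    status: str  # "unique" | "ambiguous" | "unmapped" | "rejected"
    alignment: ReadAlignment | None = None
    n_best: int = 0
    best_mismatches: int | None = None


def overhang_ok(alignment: ReadAlignment, min_overhang: int = DEFAULT_MIN_OVERHANG) -> bool:
    """True iff a junction alignment overlaps the breakpoint by at least
    ``min_overhang`` nt on both sides."""
    if alignment.target_kind != "junction":
        raise ValueError("overhang_ok applies to junction alignments only")
    return (
        alignment.overhang_left is not None
        and alignment.overhang_left >= min_overhang
        and alignment.overhang_right >= min_overhang
    )


class _TargetIndex:
    """Concatenated searchable view over a list of target sequences."""

    def __init__(self, units: list[tuple[str, str, str]]):
        # units: (kind, target_id, sequence)
        self.units = units
        self.seqs = [u[2] for u in units]
        self.rcseqs = [revcomp(s) for s in self.seqs]
        self.fwd = "#".join(self.seqs)
        self.rc = "#".join(self.rcseqs)
        self.lens = [len(s) for s in self.seqs]
        starts, pos = [], 0
        for L in self.lens:
            starts.append(pos)
            pos += L + 1  # one separator char
        self.starts = starts

    def locate(self, pos: int) -> tuple[int, int]:
        idx = bisect_right(self.starts, pos) - 1
        return idx, pos - self.starts[idx]

    def _occurrences(self, pattern: str, hay: str) -> Iterator[int]:
        p = hay.find(pattern)
        while p != -1:
            yield p
            p = hay.find(pattern, p + 1)


class ReadMapper:
    """Maps reads against a genome plus (optionally) a junction database.

    Either component may be omitted: stage 2/3 mappers are junction-only.
    """

    def __init__(
        self,
        genome: GenomeModel | None,
        db: JunctionDatabase | None,
        max_mismatch: int = 3,
    ):
        if not 0 <= max_mismatch <= 3:
            raise ValueError("max_mismatch must be in 0..3")
        self.max_mismatch = max_mismatch
        units: list[tuple[str, str, str]] = []
        self._junction: dict[str, Junction] = {}
        if genome is not None:
            units.extend(("genome", name, seq) for name, seq in genome.chromosomes.items())
        if db is not None:
            for j in db.junctions:
                units.append(("junction", j.junction_id, j.sequence))
                self._junction[j.junction_id] = j
        if not units:
            raise ValueError("mapper needs a genome and/or a junction database")
        self.index = _TargetIndex(units)

    # -- hit enumeration ---------------------------------------------------

    def _exact_hits(self, read: str) -> set[tuple[int, int, str]]:
        """(unit_idx, forward_offset, strand) for 0-mismatch alignments."""
        idx = self.index
        rl = len(read)
        hits: set[tuple[int, int, str]] = set()
        for hay, strand in ((idx.fwd, "+"), (idx.rc, "-")):
            for p in idx._occurrences(read, hay):
                u, within = idx.locate(p)
                if within + rl <= idx.lens[u]:
                    off = within if strand == "+" else idx.lens[u] - within - rl
                    hits.add((u, off, strand))
        return hits

    def _mismatch_hits(self, read: str) -> list[tuple[int, int, str, int]]:
        """All alignments with 1..max_mismatch mismatches via pigeonhole
        seeding (exact hits, if any, are found too)."""
        idx = self.index
        rl = len(read)
        k = self.max_mismatch + 1
        bounds = [round(i * rl / k) for i in range(k + 1)]
        candidates: set[tuple[int, str]] = set()
        for s, e in zip(bounds, bounds[1:]):
            seg = read[s:e]
            if _READ_N in seg:
                continue  # a segment containing N can never be error-free
            for hay, strand in ((idx.fwd, "+"), (idx.rc, "-")):
                for p in idx._occurrences(seg, hay):
                    candidates.add((p - s, strand))
        hits = []
        for start, strand in candidates:
            if start < 0:
                continue
            u, within = idx.locate(start)
            if within < 0 or within + rl > idx.lens[u]:
                continue
            target = (idx.seqs if strand == "+" else idx.rcseqs)[u]
            mm = 0
            for a, b in zip(read, target[within : within + rl]):
                if a != b:
                    mm += 1
                    if mm > self.max_mismatch:
                        break
            if mm <= self.max_mismatch:
                off = within if strand == "+" else idx.lens[u] - within - rl
                hits.append((u, off, strand, mm))
        return hits

    # -- public API --------------------------------------------------------

    def map(self, read: str) -> MapResult:
        read = read.upper()
        if len(read) < MIN_READ_LEN:
            raise ValueError(f"read shorter than {MIN_READ_LEN} nt")
        if set(read) - READ_ALPHABET:
            return MapResult(status="rejected")
        read = read.replace("N", _READ_N)

        exact = self._exact_hits(read)
        if exact:
            best = [(u, off, strand, 0) for u, off, strand in exact]
        else:
            if self.max_mismatch == 0:
                return MapResult(status="unmapped")
            hits = self._mismatch_hits(read)
            if not hits:
                return MapResult(status="unmapped")
            m_star = min(h[3] for h in hits)
            best = [h for h in hits if h[3] == m_star]

        if len(best) > 1:
            return MapResult(
                status="ambiguous", n_best=len(best), best_mismatches=best[0][3]
            )
        u, off, strand, mm = best[0]
        kind, target_id, _ = self.index.units[u]
        rl = len(read)
        if kind == "junction":
            jx = self._junction[target_id]
            left = min(rl, max(0, jx.left_flank_len - off))
            aln = ReadAlignment(
                target_kind=kind, target_id=target_id, offset=off, strand=strand,
                mismatches=mm, read_len=rl,
                overhang_left=left, overhang_right=rl - left,
            )
        else:
            aln = ReadAlignment(
                target_kind=kind, target_id=target_id, offset=off, strand=strand,
                mismatches=mm, read_len=rl,
            )
        return MapResult(status="unique", alignment=aln, n_best=1, best_mismatches=mm)


def map_read(
    read: str,
    genome: GenomeModel | None,
    db: JunctionDatabase | None,
    max_mismatch: int = 3,
) -> MapResult:
    """One-shot convenience wrapper; pipelines should hold a ReadMapper."""
    return ReadMapper(genome, db, max_mismatch).map(read)


# -- count tables ----------------------------------------------------------


class JunctionCountTable:
    """Per-sample, per-junction evidence: read counts, distinct alignment
    start offsets and distinct read sequences."""

    def __init__(self) -> None:
        self._data: dict[str, dict[str, dict]] = {}

    def add(self, sample: str, junction_id: str, offset: int, seq: str, n: int = 1) -> None:
        if n < 0:
            raise ValueError("negative count")
        rec = (
            self._data.setdefault(sample, {})
            .setdefault(junction_id, {"read_count": 0, "starts": set(), "seqs": set()})
        )
        rec["read_count"] += n
        rec["starts"].add(offset)
        rec["seqs"].add(seq)

    @property
    def samples(self) -> list[str]:
        return sorted(self._data)

    def junctions(self, sample: str | None = None) -> list[str]:
        if sample is not None:
            return sorted(self._data.get(sample, {}))
        out: set[str] = set()
        for recs in self._data.values():
            out.update(recs)
        return sorted(out)

    def read_count(self, sample: str, junction_id: str) -> int:
        return self._data.get(sample, {}).get(junction_id, {}).get("read_count", 0)

    def unique_start_count(self, sample: str, junction_id: str) -> int:
        return len(self._data.get(sample, {}).get(junction_id, {}).get("starts", ()))

    def unique_sequence_count(self, sample: str, junction_id: str) -> int:
        return len(self._data.get(sample, {}).get(junction_id, {}).get("seqs", ()))

    def pooled_unique_start_count(self, junction_id: str) -> int:
        """Distinct alignment start offsets pooled over all samples (the
        varying cutoff of the decoy-FDR analysis)."""
        starts: set[int] = set()
        for recs in self._data.values():
            rec = recs.get(junction_id)
            if rec:
                starts.update(rec["starts"])
        return len(starts)

    def pooled_unique_sequence_count(self, junction_id: str) -> int:
        seqs: set[str] = set()
        for recs in self._data.values():
            rec = recs.get(junction_id)
            if rec:
                seqs.update(rec["seqs"])
        return len(seqs)

    def pooled_read_count(self, junction_id: str) -> int:
        return sum(
            recs.get(junction_id, {}).get("read_count", 0)
            for recs in self._data.values()
        )

    def merge(self, other: "JunctionCountTable") -> None:
        for sample, recs in other._data.items():
            for jid, rec in recs.items():
                dst = (
                    self._data.setdefault(sample, {})
                    .setdefault(jid, {"read_count": 0, "starts": set(), "seqs": set()})
                )
                dst["read_count"] += rec["read_count"]
                dst["starts"] |= rec["starts"]
                dst["seqs"] |= rec["seqs"]

    def to_frame(self, kind_of=None) -> pd.DataFrame:
        rows = []
        for sample in self.samples:
            for jid in sorted(self._data[sample]):
                rec = self._data[sample][jid]
                row = {
                    "sample_id": sample,
                    "junction_id": jid,
                    "read_count": rec["read_count"],
                    "unique_start_count": len(rec["starts"]),
                    "unique_sequence_count": len(rec["seqs"]),
                }
                if kind_of is not None:
                    row["kind"] = kind_of(jid)
                rows.append(row)
        cols = ["sample_id", "junction_id", "read_count",
                "unique_start_count", "unique_sequence_count"]
        if kind_of is not None:
            cols.insert(2, "kind")
        return pd.DataFrame(rows, columns=cols)


@dataclass
class StageReport:
    """Classification tallies per stage; stage-1 categories partition the
    input reads, stages 2-3 re-examine the stage-1 unmapped subset."""

    sample_id: str
    n_reads: int = 0
    tallies: dict[str, Counter] = field(default_factory=dict)

    def bump(self, stage: str, category: str, n: int = 1) -> None:
        self.tallies.setdefault(stage, Counter())[category] += n


def _as_seq_counts(reads) -> dict[str, int]:
    if isinstance(reads, Mapping):
        return dict(reads)
    counts: dict[str, int] = {}
    for r in reads:
        seq = r[1] if isinstance(r, tuple) else r
        counts[seq] = counts.get(seq, 0) + 1
    return counts


def summarize_counts(
    alignments: Iterable[tuple[str, int, str, int]], sample: str
) -> JunctionCountTable:
    """Aggregate (junction_id, offset, read_seq, n) alignment records."""
    table = JunctionCountTable()
    for junction_id, offset, seq, n in alignments:
        table.add(sample, junction_id, offset, seq, n)
    return table


def run_staged_mapping(
    reads,
    genome: GenomeModel,
    normal_skip_db: JunctionDatabase,
    circ_db: JunctionDatabase | None = None,
    exhaustive_db: JunctionDatabase | None = None,
    sample_id: str = "sample",
    max_mismatch: int = 3,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    table: JunctionCountTable | None = None,
) -> tuple[JunctionCountTable, StageReport]:
    """Run the staged mapping protocol for one sample.

    ``reads`` may be an iterable of sequences, of ``(read_id, seq)`` tuples,
    or a ``{sequence: multiplicity}`` mapping (identical reads are mapped
    once and counted with their multiplicity).
    """
    counts = _as_seq_counts(reads)
    if table is None:
        table = JunctionCountTable()
    report = StageReport(sample_id=sample_id, n_reads=sum(counts.values()))

    stage1 = ReadMapper(genome, normal_skip_db, max_mismatch)
    unmapped: dict[str, int] = {}
    for seq, n in counts.items():
        if len(seq) < MIN_READ_LEN:
            report.bump("stage1", "too_short", n)
            continue
        res = stage1.map(seq)
        if res.status == "rejected":
            report.bump("stage1", "rejected", n)
        elif res.status == "ambiguous":
            report.bump("stage1", "ambiguous", n)
        elif res.status == "unmapped":
            report.bump("stage1", "unmapped", n)
            unmapped[seq] = n
        else:
            aln = res.alignment
            if aln.target_kind == "genome":
                report.bump("stage1", "genome_unique", n)
            elif overhang_ok(aln, min_overhang):
                report.bump("stage1", "junction_unique", n)
                table.add(sample_id, aln.target_id, aln.offset, seq, n)
            else:
                report.bump("stage1", "junction_low_overhang", n)

    for stage, db in (("stage2", circ_db), ("stage3", exhaustive_db)):
        if db is None or not db.junctions or not unmapped:
            continue
        mapper = ReadMapper(None, db, max_mismatch=0)
        for seq, n in unmapped.items():
            res = mapper.map(seq)
            if res.status == "unique":
                aln = res.alignment
                if overhang_ok(aln, min_overhang):
                    report.bump(stage, "junction_unique", n)
                    table.add(sample_id, aln.target_id, aln.offset, seq, n)
                else:
                    report.bump(stage, "junction_low_overhang", n)
            else:
                report.bump(stage, res.status, n)

    return table, report


def read_fastq_sequences(path) -> dict[str, int]:
    """Sequence -> multiplicity from a FASTQ file (plain or gzipped)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    counts: dict[str, int] = {}
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip().upper()
            fh.readline()
            fh.readline()
            if not seq:
                raise ValueError(f"truncated FASTQ record in {path}")
            counts[seq] = counts.get(seq, 0) + 1
    return counts
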