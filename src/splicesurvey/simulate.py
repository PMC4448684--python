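"""Synthetic annotated genomes and RNA-seq reads with planted ground truth.

The generator emulates the statistical world the analysis assumes: random
intergenic/exonic sequence; multi-exon genes on both strands whose annotated
introns start GT and end AG; reads drawn from normal isoforms plus rare
exon-skipping isoforms (per-event rate ``skip_rate``), circular molecules
(per-gene rate ``circ_rate``, depleted in poly(A)-enriched libraries),
cryptically spliced isoforms (planted GT..AG introns inside exons, used at
``cryptic_usage_rate``) and chimeric artifact reads that join two random
positions of a gene region (the decoy-FDR null).  Skipping, cryptic splicing
and their surveillance are error semantics: aberrant molecules replace
normal molecules (competition) and survive nuclear degradation with
probability ``retention``.

Every draw flows from ``seed``; rerunning with the same spec is
byte-identical.  Defaults follow the measured scale of the biology being
emulated: a wild-type splicing-error rate by exon skipping of ~0.24% per
event, backsplice molecules rarer than skips, and ~10x circle depletion
under poly(A) selection.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field, fields

import numpy as np

from .genome import AnnotationSet, GeneModel, GenomeModel, revcomp, spliced_sequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationSpec:
    seed: int = 0
    n_genes: int = 10
    exon_count: tuple[int, int] = (1, 8)       # uniform inclusive, support 1..15
    exon_len: tuple[int, int] = (30, 150)      # nt, uniform inclusive
    intron_len: tuple[int, int] = (20, 100)    # nt, uniform inclusive
    intergenic_len: int = 100
    read_len: int = 57                         # X, 49..76 in the emulated data
    n_molecules: int = 300                     # normal molecules per gene
    depth: float = 1.0                         # expected reads per molecule
    skip_rate: float = 0.0024                  # per-event rate epsilon
    circ_rate: float = 0.0                     # per-gene circle rate rho
    polyA_depletion: float = 10.0              # circle depletion d in polyA mode
    library_type: str = "total"                # polyA | total | ribodepleted
    n_cryptic_introns: int = 0
    cryptic_usage_rate: float = 0.05
    cryptic_intron_len: tuple[int, int] = (10, 20)
    chimera_rate: float = 0.0                  # chimeric artifact reads per molecule
    gene_flank: int = 300                      # region used for chimera placement
    error_rate: float = 0.0                    # per-base substitution rate
    retention: float = 1.0                     # surveillance retention r

    def __post_init__(self) -> None:
        for name in ("skip_rate", "circ_rate", "cryptic_usage_rate",
                     "error_rate", "retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_len < 13:
            raise ValueError("read_len must be >= 13")
        for name in ("exon_count", "exon_len", "intron_len", "cryptic_intron_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must have positive support, got ({lo}, {hi})")
        if self.library_type not in ("polyA", "total", "ribodepleted"):
            raise ValueError(f"unknown library_type {self.library_type!r}")
        if self.polyA_depletion < 1:
            raise ValueError("polyA_depletion must be >= 1")


@dataclass
class CrypticIntron:
    gene_id: str
    exon_index: int          # 1-based transcript exon hosting the intron
    offset_in_exon: int      # transcript-orientation offset of the intron
    length: int
    start: int = 0           # genomic half-open interval, filled at placement
    end: int = 0
    strand: str = "+"
    chromosome: str = ""

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chromosome, self.strand, self.start, self.end)


@dataclass
class GroundTruth:
    """Planted molecule and read counts, filled in by ``simulate_reads``."""

    spec: SimulationSpec
    cryptic_introns: list[CrypticIntron] = field(default_factory=list)
    molecules: dict[str, dict[str, int]] = field(default_factory=dict)  # gene -> isoform -> n
    reads: dict[str, dict[str, int]] = field(default_factory=dict)
    skip_events: dict[str, dict] = field(default_factory=dict)  # event id -> info
    total_reads: int = 0


class ReadSet(Mapping):
    """Deduplicated reads: sequence -> multiplicity."""

    def __init__(self, counts: dict[str, int] | None = None):
        self.counts: dict[str, int] = counts or {}

    def add(self, seq: str, n: int = 1) -> None:
        if n:
            self.counts[seq] = self.counts.get(seq, 0) + n

    def __getitem__(self, seq):  # Mapping interface
        return self.counts[seq]

    def __iter__(self):
        return iter(self.counts)

    def __len__(self):
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            i = 0
            for seq in sorted(self.counts):
                for _ in range(self.counts[seq]):
                    fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                    i += 1


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _splice_signals(locus: np.ndarray, introns: list[tuple[int, int]]) -> None:
    """Force GT..AG at each (start, end) half-open intron of a transcript-
    strand locus array (in place)."""
    for s, e in introns:
        locus[s : s + 2] = np.frombuffer(b"GT", dtype=np.uint8)
        locus[e - 2 : e] = np.frombuffer(b"AG", dtype=np.uint8)


def simulate_genome(
    spec: SimulationSpec,
) -> tuple[GenomeModel, AnnotationSet, GroundTruth]:
    """One random chromosome with ``n_genes`` non-overlapping genes.

    Gene loci are laid out left to right with ``intergenic_len`` spacers;
    strands alternate deterministically with the rng.  Annotated introns are
    forced to the canonical GT..AG; requested cryptic introns are planted
    inside randomly chosen exons (also GT..AG) and recorded in the truth
    skeleton."""
    rng = np.random.default_rng([spec.seed, 0])
    parts: list[np.ndarray] = []
    genes: list[GeneModel] = []
    truth = GroundTruth(spec=spec)
    cursor = 0
    chrom = "sim_1"

    cryptic_per_gene: dict[int, int] = {}
    for k in range(spec.n_cryptic_introns):
        cryptic_per_gene[k % spec.n_genes] = cryptic_per_gene.get(k % spec.n_genes, 0) + 1

    for g in range(spec.n_genes):
        gap = _random_dna(rng, spec.intergenic_len)
        parts.append(gap)
        cursor += len(gap)

        n_exons = int(rng.integers(spec.exon_count[0], spec.exon_count[1] + 1))
        exon_lens = rng.integers(spec.exon_len[0], spec.exon_len[1] + 1, size=n_exons)
        intron_lens = rng.integers(
            spec.intron_len[0], spec.intron_len[1] + 1, size=max(0, n_exons - 1)
        )
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        gene_id = f"gene{g + 1:03d}"

        # build the locus on the transcript strand
        locus_len = int(exon_lens.sum() + intron_lens.sum())
        locus = _random_dna(rng, locus_len)
        exons_local: list[tuple[int, int]] = []
        introns_local: list[tuple[int, int]] = []
        pos = 0
        for k in range(n_exons):
            exons_local.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                introns_local.append((pos, pos + int(intron_lens[k])))
                pos += int(intron_lens[k])
        _splice_signals(locus, introns_local)

        # plant cryptic introns inside exons, clear of the exon edges
        for _ in range(cryptic_per_gene.get(g, 0)):
            candidates = [
                (idx, s, e) for idx, (s, e) in enumerate(exons_local, start=1)
                if (e - s) >= spec.cryptic_intron_len[0] + 8
            ]
            if not candidates:
                continue
            idx, s, e = candidates[int(rng.integers(0, len(candidates)))]
            max_len = min(spec.cryptic_intron_len[1], (e - s) - 8)
            clen = int(rng.integers(spec.cryptic_intron_len[0], max_len + 1))
            off = int(rng.integers(4, (e - s) - clen - 4 + 1))
            cstart = s + off
            _splice_signals(locus, [(cstart, cstart + clen)])
            truth.cryptic_introns.append(
                CrypticIntron(
                    gene_id=gene_id, exon_index=idx, offset_in_exon=off,
                    length=clen, strand=strand, chromosome=chrom,
                )
            )

        # write the locus into the genome (revcomp for minus-strand genes)
        if strand == "+":
            parts.append(locus)
            to_genomic = lambda s, e: (cursor + s, cursor + e)  # noqa: E731
        else:
            parts.append(
                np.frombuffer(
                    revcomp(locus.tobytes().decode()).encode(), dtype=np.uint8
                ).copy()
            )
            to_genomic = lambda s, e: (  # noqa: E731
                cursor + locus_len - e, cursor + locus_len - s
            )
        exons_genomic = [to_genomic(s, e) for s, e in exons_local]
        genes.append(
            GeneModel(
                gene_id=gene_id, chromosome=chrom, strand=strand,
                exons=exons_genomic, biotype="protein_coding",
            )
        )
        for ci in truth.cryptic_introns:
            if ci.gene_id == gene_id and ci.end == 0:
                s_local = exons_local[ci.exon_index - 1][0] + ci.offset_in_exon
                ci.start, ci.end = to_genomic(s_local, s_local + ci.length)
        cursor += locus_len

    parts.append(_random_dna(rng, spec.intergenic_len))
    sequence = np.concatenate(parts).tobytes().decode()
    genome = GenomeModel({chrom: sequence})
    annotation = AnnotationSet(genes)
    return genome, annotation, truth


def _sample_reads_from_iso(
    rng: np.random.Generator, iso: str, n_reads: int, X: int, circular: bool = False
) -> dict[int, int]:
    """start offset -> read count, uniform over the molecule (wrapping
    starts for circular molecules)."""
    span = len(iso) if circular else len(iso) - X + 1
    if span <= 0 or n_reads <= 0:
        return {}
    starts = rng.integers(0, span, size=n_reads)
    counts = np.bincount(starts, minlength=span)
    return {int(i): int(c) for i, c in enumerate(counts) if c}


def _apply_errors(
    rng: np.random.Generator, reads: ReadSet, error_rate: float
) -> ReadSet:
    """Binomial thinning: each read independently acquires substitution
    errors at ``error_rate`` per base (errors never produce N)."""
    if error_rate == 0:
        return reads
    out = ReadSet()
    for seq in sorted(reads.counts):
        n = reads.counts[seq]
        p_any = 1.0 - (1.0 - error_rate) ** len(seq)
        k = int(rng.binomial(n, p_any))
        out.add(seq, n - k)
        for _ in range(k):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            n_err = 0
            while n_err == 0:  # conditioned on >= 1 error
                mask = rng.random(len(arr)) < error_rate
                n_err = int(mask.sum())
            for pos in np.flatnonzero(mask):
                choices = _BASES[_BASES != arr[pos]]
                arr[pos] = choices[int(rng.integers(0, 3))]
            out.add(arr.tobytes().decode(), 1)
    return out


def _cryptic_isoform(
    gene: GeneModel, genome: GenomeModel, ci: CrypticIntron
) -> str:
    full = spliced_sequence(gene, genome, list(range(1, gene.n_exons + 1)))
    offset = sum(gene.exon_length(k) for k in range(1, ci.exon_index)) + ci.offset_in_exon
    return full[:offset] + full[offset + ci.length :]


def simulate_reads(
    genome: GenomeModel,
    annotation: AnnotationSet,
    truth: GroundTruth,
    spec: SimulationSpec,
) -> tuple[ReadSet, GroundTruth]:
    """Draw molecules and reads per gene; returns deduplicated reads and the
    completed ground truth (exact molecule and read counts per isoform)."""
    rng = np.random.default_rng([spec.seed, 1])
    X = spec.read_len
    reads = ReadSet()
    cryptic_by_gene: dict[str, list[CrypticIntron]] = {}
    for ci in truth.cryptic_introns:
        cryptic_by_gene.setdefault(ci.gene_id, []).append(ci)

    for gene in annotation.genes:
        n = gene.n_exons
        normal_iso = spliced_sequence(gene, genome, list(range(1, n + 1)))
        mol: dict[str, int] = {}
        iso_seq: dict[str, str] = {}
        normal_pool = spec.n_molecules

        for i in range(1, n + 1):
            for j in range(i + 2, n + 1):
                drawn = int(rng.binomial(spec.n_molecules, spec.skip_rate))
                kept = int(rng.binomial(drawn, spec.retention)) if drawn else 0
                normal_pool -= drawn
                label = f"skip:{i}-{j}"
                mol[label] = kept
                kept_exons = list(range(1, i + 1)) + list(range(j, n + 1))
                iso_seq[label] = spliced_sequence(gene, genome, kept_exons)
                truth.skip_events[f"{gene.gene_id}:skip:{i}-{j}"] = {
                    "gene_id": gene.gene_id, "donor": i, "acceptor": j,
                    "true_rate": spec.skip_rate, "molecules_drawn": drawn,
                    "molecules_kept": kept,
                }

        for ci in cryptic_by_gene.get(gene.gene_id, []):
            drawn = int(rng.binomial(spec.n_molecules, spec.cryptic_usage_rate))
            kept = int(rng.binomial(drawn, spec.retention)) if drawn else 0
            normal_pool -= drawn
            label = f"cryptic:{ci.start}-{ci.end}"
            mol[label] = kept
            iso_seq[label] = _cryptic_isoform(gene, genome, ci)

        n_circ = int(rng.binomial(spec.n_molecules, spec.circ_rate))
        if spec.library_type == "polyA" and n_circ:
            n_circ = int(rng.binomial(n_circ, 1.0 / spec.polyA_depletion))
        if n_circ:
            pairs = [(i, j) for i in range(1, n + 1) for j in range(i, n + 1)]
            picks = rng.integers(0, len(pairs), size=n_circ)
            for p in range(len(pairs)):
                cnt = int((picks == p).sum())
                if not cnt:
                    continue
                i, j = pairs[p]
                label = f"circ:{j}-{i}"
                mol[label] = mol.get(label, 0) + cnt
                iso_seq[label] = spliced_sequence(gene, genome, list(range(i, j + 1)))

        mol["normal"] = max(0, normal_pool)
        iso_seq["normal"] = normal_iso

        truth.molecules[gene.gene_id] = dict(mol)
        truth.reads[gene.gene_id] = {}
        # fragmentation yields reads in proportion to molecule length:
        # ``depth`` is the expected reads per normal-isoform molecule and
        # other isoforms scale by their read-window count, so every window
        # of every molecule is sampled at the same intensity
        norm_windows = max(1, len(normal_iso) - X + 1)
        for label in sorted(mol):
            seq = iso_seq[label]
            circular = label.startswith("circ:")
            windows = len(seq) if circular else max(0, len(seq) - X + 1)
            n_reads = int(round(spec.depth * mol[label] * windows / norm_windows))
            if not circular and len(seq) < X:
                if mol[label]:
                    import warnings

                    warnings.warn(
                        f"{gene.gene_id}/{label}: transcript shorter than read "
                        f"length; skipped", stacklevel=2,
                    )
                truth.reads[gene.gene_id][label] = 0
                continue
            if circular and len(seq) < X:
                truth.reads[gene.gene_id][label] = 0
                continue
            doubled = seq + seq if circular else seq
            emitted = 0
            for start, cnt in _sample_reads_from_iso(rng, seq, n_reads, X, circular).items():
                reads.add(doubled[start : start + X], cnt)
                emitted += cnt
            truth.reads[gene.gene_id][label] = emitted

        # chimeric artifact reads over the gene region (decoy-FDR null)
        n_chim = int(rng.poisson(spec.chimera_rate * spec.depth * spec.n_molecules))
        if n_chim:
            start = max(0, gene.start - spec.gene_flank)
            end = min(genome.length(gene.chromosome), gene.end + spec.gene_flank)
            region = genome.fetch(gene.chromosome, start, end)
            if gene.strand == "-":
                region = revcomp(region)
            emitted = 0
            for _ in range(n_chim):
                for _attempt in range(20):
                    k = int(rng.integers(6, X - 6 + 1))
                    d_hi = len(region) - (X - k) - 10 + 1
                    if d_hi <= k:
                        continue
                    d = int(rng.integers(k, d_hi))
                    gap = int(rng.integers(10, min(60, len(region) - d - (X - k)) + 1))
                    a2 = d + gap
                    if a2 + (X - k) <= len(region):
                        reads.add(region[d - k : d] + region[a2 : a2 + (X - k)], 1)
                        emitted += 1
                        break
            truth.reads.setdefault(gene.gene_id, {})["chimera"] = emitted

    reads = _apply_errors(np.random.default_rng([spec.seed, 2]), reads, spec.error_rate)
    truth.total_reads = reads.total
    return reads, truth


def junction_window_count(
    left_flank_len: int,
    right_flank_len: int,
    boundary: int,
    iso_len: int,
    read_len: int,
) -> int:
    """Closed-form count of read start positions in an isoform of length
    ``iso_len`` whose window matches a junction with the given flanks around
    ``boundary`` (the exhaustive-tiling oracle; overhang >= 6 is implied by
    the flank rule for full-length reads)."""
    lo = max(0, boundary - left_flank_len, boundary + 6 - read_len)
    hi = min(iso_len - read_len, boundary - 6, boundary + right_flank_len - read_len)
    return max(0, hi - lo + 1)


def tile_reads(iso_seq: str, read_len: int) -> ReadSet:
    """Every start position exactly once (exhaustive tiling)."""
    rs = ReadSet()
    for p in range(len(iso_seq) - read_len + 1):
        rs.add(iso_seq[p : p + read_len], 1)
    return rs


# -- plain key-value config files -----------------------------------------

_TUPLE_FIELDS = {"exon_count", "exon_len", "intron_len", "cryptic_intron_len"}


def write_spec(spec: SimulationSpec, path) -> None:
    with open(path, "w") as fh:
        for f in fields(spec):
            v = getattr(spec, f.name)
            if f.name in _TUPLE_FIELDS:
                v = f"{v[0]},{v[1]}"
            fh.write(f"{f.name} = {v}\n")


def read_spec(path) -> SimulationSpec:
    kwargs: dict = {}
    types = {f.name: f.type for f in fields(SimulationSpec)}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown simulation parameter {key!r}")
            if key in _TUPLE_FIELDS:
                lo, hi = value.split(",")
                kwargs[key] = (int(lo), int(hi))
            elif key == "library_type":
                kwargs[key] = value
            elif key in ("depth", "skip_rate", "circ_rate", "polyA_depletion",
                         "cryptic_usage_rate", "chimera_rate", "error_rate",
                         "retention"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = int(value)
    return SimulationSpec(**kwargs)
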