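"""Genome sequences and strand-aware gene/exon models.

Internal coordinates are 0-based half-open throughout; file interfaces
(FASTA, GFF3, report TSVs) follow their own conventions (GFF3 and TSVs are
1-based inclusive).  Exons of a gene are stored in transcript order, i.e.
genomic-ascending on the + strand and genomic-descending on the − strand,
so that downstream junction builders can reason in mRNA 5'→3' space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeModelError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass
class GenomeModel:
    """Chromosome name -> uppercase DNA sequence (A, C, G, T, N)."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise GenomeModelError(f"empty chromosome: {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeModelError(
                    f"illegal characters in chromosome {name!r}: {sorted(bad)}"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def fetch(self, name: str, start: int, end: int) -> str:
        """Slice [start, end) of a chromosome; out-of-bounds lookups are rejected."""
        seq = self.chromosomes[name]
        if not (0 <= start <= end <= len(seq)):
            raise GenomeModelError(
                f"slice [{start}, {end}) outside chromosome {name!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]


@dataclass
class GeneModel:
    """One gene with a single annotated exon chain.

    ``exons`` are genomic ``(start, end)`` half-open intervals in transcript
    order.  Intron k lies between transcript exons k and k+1.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: gene without exons")
        for s, e in self.exons:
            if e - s < 1:
                raise AnnotationError(f"{self.gene_id}: empty exon ({s}, {e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"{self.gene_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )
        expected = genomic if self.strand == "+" else genomic[::-1]
        if self.exons != expected:
            raise AnnotationError(
                f"{self.gene_id}: exons not in transcript order for strand "
                f"{self.strand}"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def exon_length(self, index: int) -> int:
        """Length of transcript exon ``index`` (1-based)."""
        s, e = self.exons[index - 1]
        return e - s

    def exon_seq(self, genome: GenomeModel, index: int) -> str:
        """Transcript-orientation sequence of exon ``index`` (1-based)."""
        s, e = self.exons[index - 1]
        seq = genome.fetch(self.chromosome, s, e)
        return revcomp(seq) if self.strand == "-" else seq

    def introns(self) -> list[tuple[int, int]]:
        """Genomic half-open intron intervals, in transcript order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            lo, hi = (e1, s2) if self.strand == "+" else (e2, s1)
            if hi - lo < 1:
                raise AnnotationError(
                    f"{self.gene_id}: zero-length intron between exons"
                )
            out.append((lo, hi))
        return out


# an intron key is (chromosome, strand, genomic_start, genomic_end), half-open
IntronKey = tuple[str, str, int, int]


@dataclass
class AnnotationSet:
    genes: list[GeneModel]
    intron_index: set[IntronKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.intron_index:
            self.intron_index = self.build_intron_index()

    def build_intron_index(self) -> set[IntronKey]:
        index: set[IntronKey] = set()
        for g in self.genes:
            for lo, hi in g.introns():
                index.add((g.chromosome, g.strand, lo, hi))
        return index

    def donor_sites(self) -> set[tuple[str, str, int]]:
        """Annotated donor (intron 5') coordinates on the transcribed strand."""
        return {
            (c, st, lo if st == "+" else hi)
            for c, st, lo, hi in self.intron_index
        }

    def acceptor_sites(self) -> set[tuple[str, str, int]]:
        return {
            (c, st, hi if st == "+" else lo)
            for c, st, lo, hi in self.intron_index
        }


def read_fasta(path) -> GenomeModel:
    """Read a (multi-)FASTA into a GenomeModel; sequences are uppercased."""
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chroms:
            raise GenomeModelError(f"duplicate chromosome {record.id!r}")
        chroms[record.id] = str(record.seq).upper()
    if not chroms:
        raise GenomeModelError(f"no FASTA records in {path}")
    return GenomeModel(chroms)


def write_fasta(genome: GenomeModel, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _exons_from_gff_gene(db, gene) -> tuple[list, bool]:
    """Exon features of a gene, using the first transcript when several exist."""
    direct = list(db.children(gene, featuretype="exon", level=1))
    if direct:
        return direct, False
    transcripts = list(db.children(gene, level=1))
    transcripts = [t for t in transcripts if list(db.children(t, featuretype="exon"))]
    if not transcripts:
        return [], False
    transcripts.sort(key=lambda t: (t.start, t.id))
    exons = list(db.children(transcripts[0], featuretype="exon"))
    return exons, len(transcripts) > 1


def read_gff(path, genome: GenomeModel) -> AnnotationSet:
    """Read gene/exon features from GFF3 into an AnnotationSet.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Genes on chromosomes absent from ``genome`` and exons outside chromosome
    bounds are rejected.  Genes with several transcripts use the first
    transcript's exon chain with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.seqid not in genome:
            raise AnnotationError(
                f"gene {gene.id} on unknown chromosome {gene.seqid!r}"
            )
        exon_feats, multi = _exons_from_gff_gene(db, gene)
        if multi:
            warnings.warn(
                f"gene {gene.id}: multiple transcripts; using the first exon chain",
                stacklevel=2,
            )
        if not exon_feats:
            continue
        chrom_len = genome.length(gene.seqid)
        intervals = []
        for ex in exon_feats:
            start, end = ex.start - 1, ex.end  # GFF3 1-based inclusive
            if not (0 <= start < end <= chrom_len):
                raise AnnotationError(
                    f"gene {gene.id}: exon ({ex.start}, {ex.end}) outside "
                    f"chromosome {gene.seqid!r} of length {chrom_len}"
                )
            intervals.append((start, end))
        intervals.sort()
        if gene.strand == "-":
            intervals.reverse()
        biotype = gene.attributes.get(
            "biotype", gene.attributes.get("gene_biotype", ["protein_coding"])
        )[0]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                exons=intervals,
                biotype=biotype,
            )
        )
    return AnnotationSet(genes)


def write_gff(annotation: AnnotationSet, path) -> None:
    """Write gene + exon features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        "splicesurvey",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id};biotype={g.biotype}",
                    ]
                )
                + "\n"
            )
            for k, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    "\t".join(
                        [
                            g.chromosome,
                            "splicesurvey",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            g.strand,
                            ".",
                            f"ID={g.gene_id}.exon{k};Parent={g.gene_id}",
                        ]
                    )
                    + "\n"
                )


def spliced_sequence(
    gene: GeneModel, genome: GenomeModel, kept_exons: list[int]
) -> str:
    """mRNA sequence of the isoform keeping exons ``kept_exons`` (1-based,
    strictly increasing, in transcript order)."""
    if not kept_exons:
        raise AnnotationError("kept_exons is empty")
    if any(k < 1 or k > gene.n_exons for k in kept_exons):
        raise AnnotationError(
            f"{gene.gene_id}: exon index out of range 1..{gene.n_exons}"
        )
    if any(b <= a for a, b in zip(kept_exons, kept_exons[1:])):
        raise AnnotationError("kept_exons must be strictly increasing")
    return "".join(gene.exon_seq(genome, k) for k in kept_exons)


def eligible_genes(annotation: AnnotationSet, min_exons: int = 3) -> list[GeneModel]:
    """Genes with at least ``min_exons`` annotated exons (skip-capable genes
    require 3)."""
    if min_exons < 1:
        raise ValueError("min_exons must be >= 1")
    out = [g for g in annotation.genes if g.n_exons >= min_exons]
    logger.info("eligible_genes: %d/%d genes with >= %d exons",
                len(out), len(annotation.genes), min_exons)
    return out


def reverse_complement_genome(genome: GenomeModel) -> GenomeModel:
    """Mirror genome (each chromosome reverse-complemented); test utility."""
    return GenomeModel({n: revcomp(s) for n, s in genome.chromosomes.items()})


def mirror_annotation(annotation: AnnotationSet, genome: GenomeModel) -> AnnotationSet:
    """Annotation mapped onto the reverse-complemented genome (strands flip,
    coordinates reflect); test utility for strand-invariance checks."""
    genes = []
    for g in annotation.genes:
        L = genome.length(g.chromosome)
        exons = [(L - e, L - s) for s, e in g.exons]
        genes.append(
            GeneModel(
                gene_id=g.gene_id,
                chromosome=g.chromosome,
                strand="-" if g.strand == "+" else "+",
                exons=exons,
                biotype=g.biotype,
            )
        )
    return AnnotationSet(genes)
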