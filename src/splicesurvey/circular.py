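"""Circular-RNA (backsplice) junction statistics.

Backsplice diagnostic reads are rare, so the emphasis is on honest
denominators and negative controls: the global ratio divides circular reads
by all linear junction reads (normal + skipping), the local ratio compares a
circle against the mean normal-junction coverage of its host gene, and
single-exon junctions of intronless genes — which cannot arise from
spliceosomal circularization — serve as a baseline-noise estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome import GeneModel
from .junctions import JunctionDatabase
from .mapping import JunctionCountTable


@dataclass
class CircRecord:
    """One backsplice junction (donor exon j -> acceptor exon i, j >= i)."""

    gene_id: str
    acceptor_exon: int  # i
    donor_exon: int     # j
    reads: dict[str, int] = field(default_factory=dict)  # sample -> circ reads
    from_intronless_gene: bool = False

    def __post_init__(self) -> None:
        if self.donor_exon < self.acceptor_exon:
            raise ValueError("backsplice requires donor exon >= acceptor exon")

    @property
    def introns_between(self) -> int:
        return self.donor_exon - self.acceptor_exon

    @property
    def single_exon(self) -> bool:
        return self.introns_between == 0

    @property
    def junction_id(self) -> str:
        return f"{self.gene_id}:circ:{self.donor_exon}-{self.acceptor_exon}"

    @property
    def total_reads(self) -> int:
        return sum(self.reads.values())


def circ_records(
    circ_db: JunctionDatabase,
    table: JunctionCountTable,
    genes: list[GeneModel],
    keep_zero: bool = False,
) -> list[CircRecord]:
    """One record per circular junction with its per-sample read counts;
    junctions with no reads are dropped unless ``keep_zero``."""
    n_exons = {g.gene_id: g.n_exons for g in genes}
    out = []
    for j in circ_db.junctions:
        if j.kind != "circular":
            continue
        reads = {
            s: table.read_count(s, j.junction_id)
            for s in table.samples
            if table.read_count(s, j.junction_id) > 0
        }
        if not reads and not keep_zero:
            continue
        out.append(
            CircRecord(
                gene_id=j.gene_id,
                acceptor_exon=j.acceptor_exon,
                donor_exon=j.donor_exon,
                reads=reads,
                from_intronless_gene=n_exons.get(j.gene_id, 0) == 1,
            )
        )
    return out


def global_circ_ratio(
    table: JunctionCountTable, db: JunctionDatabase, sample: str
) -> float | None:
    """Circular reads / (normal + skipping junction reads); None when the
    sample has no linear junction reads."""
    circ = linear = 0
    for jid in table.junctions(sample):
        kind = db.kind_of(jid)
        if kind == "circular":
            circ += table.read_count(sample, jid)
        elif kind in ("normal", "skipping"):
            linear += table.read_count(sample, jid)
    if linear == 0:
        return None
    return circ / (circ + linear)


def local_circ_ratio(
    record: CircRecord,
    table: JunctionCountTable,
    db: JunctionDatabase,
    sample: str,
    genes: list[GeneModel],
) -> tuple[float | None, bool]:
    """(ratio, suspect) — circ reads / (circ reads + mean normal-junction
    reads of the gene), excluding skipping reads.  ``suspect`` marks loci
    with no normal-junction coverage (e.g. intronless genes), where the
    ratio degenerates to 1 for any read."""
    gene = next(g for g in genes if g.gene_id == record.gene_id)
    circ = record.reads.get(sample, 0)
    normals = [
        table.read_count(sample, f"{gene.gene_id}:normal:{k}-{k + 1}")
        for k in range(1, gene.n_exons)
    ]
    mean_normal = sum(normals) / len(normals) if normals else 0.0
    denom = circ + mean_normal
    if denom == 0:
        return None, mean_normal == 0
    return circ / denom, mean_normal == 0


def replicate_consistency_filter(
    records: list[CircRecord],
    replicate_groups: dict[str, list[str]],
    min_reads: int = 1,
    min_replicates: int = 2,
) -> list[CircRecord]:
    """Keep records seen with >= min_reads in >= min_replicates replicates
    of at least one condition group."""
    out = []
    for rec in records:
        for samples in replicate_groups.values():
            n_supported = sum(
                1 for s in samples if rec.reads.get(s, 0) >= min_reads
            )
            if n_supported >= min_replicates:
                out.append(rec)
                break
    return out


def circ_structure_summary(records: list[CircRecord]) -> dict:
    """Reads binned by the number of introns between the joint exons, plus
    the single-exon and intronless-gene read shares."""
    by_introns: dict[int, int] = {}
    intronless_reads = 0
    total_reads = 0
    for rec in records:
        n = rec.total_reads
        total_reads += n
        by_introns[rec.introns_between] = by_introns.get(rec.introns_between, 0) + n
        if rec.from_intronless_gene:
            intronless_reads += n
    single = by_introns.get(0, 0)
    return {
        "reads_by_introns_between": dict(sorted(by_introns.items())),
        "total_reads": total_reads,
        "single_exon_reads": single,
        "single_exon_read_share": single / total_reads if total_reads else float("nan"),
        "intronless_gene_reads": intronless_reads,
        "intronless_gene_read_share": (
            intronless_reads / total_reads if total_reads else float("nan")
        ),
    }


def circ_report(
    records: list[CircRecord],
    table: JunctionCountTable,
    db: JunctionDatabase,
    genes: list[GeneModel],
) -> pd.DataFrame:
    rows = []
    for rec in sorted(records, key=lambda r: r.junction_id):
        for sample in table.samples:
            circ = rec.reads.get(sample, 0)
            ratio, suspect = local_circ_ratio(rec, table, db, sample, genes)
            rows.append(
                {
                    "junction_id": rec.junction_id,
                    "gene_id": rec.gene_id,
                    "donor_exon": rec.donor_exon,
                    "acceptor_exon": rec.acceptor_exon,
                    "introns_between": rec.introns_between,
                    "single_exon": rec.single_exon,
                    "from_intronless_gene": rec.from_intronless_gene,
                    "sample_id": sample,
                    "circ_reads": circ,
                    "local_circ_ratio": ratio,
                    "suspect_no_normal": suspect,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "junction_id", "gene_id", "donor_exon", "acceptor_exon",
            "introns_between", "single_exon", "from_intronless_gene",
            "sample_id", "circ_reads", "local_circ_ratio", "suspect_no_normal",
        ],
    )
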