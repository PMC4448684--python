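"""Diagnostic splice-junction sequence databases.

Three families of junctions are enumerated per gene:

* ``normal``   — consecutive exon pairs (i, i+1); the annotated splice forms.
* ``skipping`` — non-consecutive pairs (i, j), j >= i+2, diagnostic for
  exon-skipping isoforms (the skipped exons are i+1 .. j-1).
* ``circular`` — backsplice pairs (donor exon j -> acceptor exon i) with
  j >= i, joining the 3' end of a downstream-or-same exon to the 5' start of
  an upstream-or-same exon; j == i is a single-exon circle, and single-exon
  genes contribute one such junction (a useful negative control, since an
  intronless gene is not expected to circularize via splicing).

Flank rule: for a read length X, a normal/skipping junction carries the last
X-6 nt of the donor exon and the first X-6 nt of the acceptor exon (the whole
exon when shorter), so a full-length read aligned inside the junction
necessarily overlaps the breakpoint by >= 6 nt on both sides.  Circular
junctions use a fixed flank (default 57 nt) so that one database serves reads
of mixed lengths.

For an n-exon gene the family sizes are n-1, (n-1)(n-2)/2 and n(n+1)/2.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .genome import GeneModel, GenomeModel

logger = logging.getLogger(__name__)

KINDS = ("normal", "skipping", "circular", "exhaustive")


@dataclass(frozen=True)
class Junction:
    """One diagnostic junction sequence.

    ``donor_exon``/``acceptor_exon`` are 1-based transcript exon indices for
    the gene-derived kinds; exhaustive-search junctions store genomic intron
    coordinates instead (see :mod:`splicesurvey.introns`).
    """

    junction_id: str
    kind: str
    gene_id: str
    donor_exon: int
    acceptor_exon: int
    sequence: str
    left_flank_len: int
    right_flank_len: int
    skipped_exon_count: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown junction kind {self.kind!r}")
        if len(self.sequence) != self.left_flank_len + self.right_flank_len:
            raise ValueError(
                f"{self.junction_id}: sequence length {len(self.sequence)} != "
                f"{self.left_flank_len} + {self.right_flank_len}"
            )


@dataclass
class JunctionDatabase:
    read_len: int
    junctions: list[Junction]
    by_sequence: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [j.junction_id for j in self.junctions]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate junction ids: {dup[:5]}")
        if not self.by_sequence:
            for j in self.junctions:
                self.by_sequence.setdefault(j.sequence, []).append(j.junction_id)

    def __len__(self) -> int:
        return len(self.junctions)

    def __getitem__(self, junction_id: str) -> Junction:
        return self._index()[junction_id]

    def _index(self) -> dict[str, Junction]:
        if not hasattr(self, "_id_index"):
            self._id_index = {j.junction_id: j for j in self.junctions}
        return self._id_index

    def kind_of(self, junction_id: str) -> str:
        return self._index()[junction_id].kind

    def duplicate_sequence_report(self) -> dict[str, list[str]]:
        """Sequences shared by several junctions (resolved at mapping time
        by the uniqueness filter)."""
        return {s: ids for s, ids in self.by_sequence.items() if len(ids) > 1}


def _flank_pair(
    gene: GeneModel, genome: GenomeModel, donor: int, acceptor: int, flank: int
) -> tuple[str, str]:
    """(left, right) flank sequences: up to ``flank`` nt from the 3' end of
    transcript exon ``donor`` and the 5' start of exon ``acceptor``."""
    left = gene.exon_seq(genome, donor)[-flank:]
    right = gene.exon_seq(genome, acceptor)[:flank]
    return left, right


def _make(gene, genome, kind, donor, acceptor, flank, tag) -> Junction | None:
    left, right = _flank_pair(gene, genome, donor, acceptor, flank)
    seq = left + right
    if "N" in seq:
        return None
    skipped = acceptor - donor - 1 if kind == "skipping" else 0
    return Junction(
        junction_id=f"{gene.gene_id}:{tag}:{donor}-{acceptor}",
        kind=kind,
        gene_id=gene.gene_id,
        donor_exon=donor,
        acceptor_exon=acceptor,
        sequence=seq,
        left_flank_len=len(left),
        right_flank_len=len(right),
        skipped_exon_count=skipped,
    )


def build_normal_junctions(
    gene: GeneModel, genome: GenomeModel, read_len: int
) -> list[Junction]:
    """One junction per consecutive exon pair; flanks of min(exon, X-6) nt."""
    if read_len < 13:
        raise ValueError("read_len must be >= 13 (so that X-6 >= 7)")
    flank = read_len - 6
    out = []
    for i in range(1, gene.n_exons):
        j = _make(gene, genome, "normal", i, i + 1, flank, "normal")
        if j is not None:
            out.append(j)
    return out


def build_skipping_junctions(
    gene: GeneModel, genome: GenomeModel, read_len: int
) -> list[Junction]:
    """One junction per exon pair (i, j) with j >= i+2; same flank rule."""
    if read_len < 13:
        raise ValueError("read_len must be >= 13 (so that X-6 >= 7)")
    flank = read_len - 6
    out = []
    for i in range(1, gene.n_exons + 1):
        for j in range(i + 2, gene.n_exons + 1):
            jx = _make(gene, genome, "skipping", i, j, flank, "skip")
            if jx is not None:
                out.append(jx)
    return out


def build_circular_junctions(
    gene: GeneModel, genome: GenomeModel, flank: int = 57
) -> list[Junction]:
    """Backsplice junctions: 3' end of exon j joined to 5' start of exon i,
    for every ordered pair j >= i (n(n+1)/2 junctions for n exons)."""
    if flank < 7:
        raise ValueError("flank must be >= 7")
    out = []
    for i in range(1, gene.n_exons + 1):
        for j in range(i, gene.n_exons + 1):
            left, right = _flank_pair(gene, genome, j, i, flank)
            seq = left + right
            if "N" in seq:
                continue
            out.append(
                Junction(
                    junction_id=f"{gene.gene_id}:circ:{j}-{i}",
                    kind="circular",
                    gene_id=gene.gene_id,
                    donor_exon=j,
                    acceptor_exon=i,
                    sequence=seq,
                    left_flank_len=len(left),
                    right_flank_len=len(right),
                )
            )
    return out


_BUILDERS = {
    "normal": build_normal_junctions,
    "skipping": build_skipping_junctions,
}


def assemble_database(
    genes: list[GeneModel],
    genome: GenomeModel,
    read_len: int,
    kinds: set[str] = frozenset({"normal", "skipping"}),
    circ_flank: int = 57,
) -> JunctionDatabase:
    """Concatenate the requested junction families over all genes."""
    unknown = set(kinds) - {"normal", "skipping", "circular"}
    if unknown:
        raise ValueError(f"unknown kinds: {sorted(unknown)}")
    junctions: list[Junction] = []
    for kind in ("normal", "skipping", "circular"):
        if kind not in kinds:
            continue
        for gene in genes:
            if kind == "circular":
                junctions.extend(build_circular_junctions(gene, genome, circ_flank))
            else:
                junctions.extend(_BUILDERS[kind](gene, genome, read_len))
    db = JunctionDatabase(read_len=read_len, junctions=junctions)
    dup = db.duplicate_sequence_report()
    if dup:
        logger.info(
            "assemble_database: %d junction sequences shared by >1 junction "
            "(left to the mapping-time uniqueness filter)", len(dup)
        )
    return db


def junction_table(db: JunctionDatabase) -> pd.DataFrame:
    rows = [
        {
            "junction_id": j.junction_id,
            "kind": j.kind,
            "gene_id": j.gene_id,
            "donor": j.donor_exon,
            "acceptor": j.acceptor_exon,
            "left_flank_len": j.left_flank_len,
            "right_flank_len": j.right_flank_len,
            "skipped_exon_count": j.skipped_exon_count,
        }
        for j in db.junctions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "junction_id", "kind", "gene_id", "donor", "acceptor",
            "left_flank_len", "right_flank_len", "skipped_exon_count",
        ],
    )


def write_database(db: JunctionDatabase, fasta_path, tsv_path) -> None:
    """Export as FASTA (id = junction_id) plus a TSV sidecar."""
    with open(fasta_path, "w") as fh:
        for j in db.junctions:
            fh.write(f">{j.junction_id}\n{j.sequence}\n")
    junction_table(db).to_csv(tsv_path, sep="\t", index=False)
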