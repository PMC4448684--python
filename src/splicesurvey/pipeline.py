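"""End-to-end orchestration over many samples.

``run_all`` builds the junction databases once per distinct read length,
maps every sample through the staged protocol, and writes the report
tables.  All outputs are deterministically ordered (junction_id, then
sample_id) so a rerun with identical inputs is byte-identical; the thread
count never influences results.
"""

from __future__ import annotations

import dataclasses
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import circular as circ_stats
from . import introns as novel
from . import skipping as skip_stats
from .genome import AnnotationSet, GenomeModel, read_fasta, read_gff
from .junctions import JunctionDatabase, assemble_database
from .mapping import JunctionCountTable, read_fastq_sequences, run_staged_mapping

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class StatParams:
    """Statistical parameters; defaults are the surveyed pipeline's values."""

    high_confidence_cutoff: int = 8   # skip reads, strictly greater-than
    esr_threshold: float = 0.1
    fdr_alpha: float = 0.05
    inefficiency_cutoff: int = 70     # unique sequences, <= is cryptic
    min_intron_len: int = 10
    junction_flank: int = 57          # circular + exhaustive junction flanks
    gene_flank: int = 300             # region flank for the exhaustive search
    min_overhang: int = 6
    max_mismatch: int = 3

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclass
class RunConfig:
    genome_path: str
    annotation_path: str
    sample_sheet_path: str
    out_dir: str
    run_skip: bool = True
    run_circ: bool = True
    run_novel: bool = True
    params: StatParams = field(default_factory=StatParams)
    transcript_copies_path: str | None = None
    threads: int = 1  # accepted for interface symmetry; results never depend on it


@dataclass
class RunResult:
    out_dir: Path
    tables: dict[str, Path]
    sample_status: dict[str, str]
    stage_tallies: dict[str, dict]

    @property
    def n_failures(self) -> int:
        return sum(1 for s in self.sample_status.values() if s != "ok")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "fastq", "read_len"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    for optional, default in (
        ("condition", "none"), ("replicate", "1"), ("library_type", "total"),
    ):
        if optional not in sheet.columns:
            sheet[optional] = default
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return sheet


def read_transcript_copies(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("transcript copies table needs gene_id and copies columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def detected_skip_events(genes, table: JunctionCountTable):
    """Skip events with at least one diagnostic read in any sample."""
    events = []
    for gene in genes:
        for i in range(1, gene.n_exons + 1):
            for j in range(i + 2, gene.n_exons + 1):
                jid = f"{gene.gene_id}:skip:{i}-{j}"
                if table.pooled_read_count(jid) > 0:
                    events.append(skip_stats.skip_event_from_gene(gene, i, j))
    return events


def run_all(
    config: RunConfig,
    genome: GenomeModel | None = None,
    annotation: AnnotationSet | None = None,
) -> RunResult:
    p = config.params
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if genome is None:
        genome = read_fasta(config.genome_path)
    if annotation is None:
        annotation = read_gff(config.annotation_path, genome)
    sheet = read_sample_sheet(config.sample_sheet_path)
    genes = annotation.genes

    # databases: one normal+skipping db per distinct read length
    linear_dbs: dict[int, JunctionDatabase] = {}
    for read_len in sorted(set(int(x) for x in sheet["read_len"])):
        linear_dbs[read_len] = assemble_database(
            genes, genome, read_len, kinds={"normal", "skipping"}
        )
    circ_db = (
        assemble_database(genes, genome, p.junction_flank + 6,
                          kinds={"circular"}, circ_flank=p.junction_flank)
        if config.run_circ else None
    )
    exhaustive_db = (
        novel.build_exhaustive_db(
            annotation, genome,
            gene_flank=p.gene_flank, junction_flank=p.junction_flank,
            min_intron_len=p.min_intron_len,
        )
        if config.run_novel else None
    )

    kind_of = {}
    for db in [*linear_dbs.values(), circ_db, exhaustive_db]:
        if db is not None:
            for j in db.junctions:
                kind_of[j.junction_id] = j.kind

    table = JunctionCountTable()
    sample_status: dict[str, str] = {}
    stage_tallies: dict[str, dict] = {}
    for _, row in sheet.iterrows():
        sample = str(row["sample_id"])
        try:
            reads = read_fastq_sequences(row["fastq"])
            _, report = run_staged_mapping(
                reads, genome, linear_dbs[int(row["read_len"])],
                circ_db=circ_db, exhaustive_db=exhaustive_db,
                sample_id=sample, max_mismatch=p.max_mismatch,
                min_overhang=p.min_overhang, table=table,
            )
            stage_tallies[sample] = {
                stage: dict(sorted(counter.items()))
                for stage, counter in sorted(report.tallies.items())
            }
            sample_status[sample] = "ok"
        except Exception as exc:  # keep going; summarize at the end
            logger.error("sample %s failed: %s", sample, exc)
            sample_status[sample] = f"failed: {exc}"
            stage_tallies[sample] = {"error": traceback.format_exc(limit=1)}

    tables: dict[str, Path] = {}
    any_db = next(iter(linear_dbs.values()))
    combined_kinds = _CombinedKinds(kind_of)
    tables["counts"] = _write(
        table.to_frame(kind_of=lambda jid: kind_of.get(jid, "?")),
        out / "counts.tsv",
    )

    if config.run_skip:
        events = detected_skip_events(genes, table)
        records = skip_stats.esr_matrix(events, table, any_db)
        esr_rows = [
            {
                "event_id": r.event.event_id,
                "gene_id": r.event.gene_id,
                "donor_exon": r.event.donor_exon,
                "acceptor_exon": r.event.acceptor_exon,
                "skipped_nt": r.event.skipped_nt,
                "frame_preserving": r.event.frame_preserving,
                "sample_id": r.sample_id,
                "skip_reads": r.skip_reads,
                "mean_normal_reads": r.normal_reads,
                "local_esr": r.local_esr,
            }
            for r in sorted(records, key=lambda r: (r.event.event_id, r.sample_id))
        ]
        tables["esr_matrix"] = _write(
            pd.DataFrame(esr_rows, columns=[
                "event_id", "gene_id", "donor_exon", "acceptor_exon",
                "skipped_nt", "frame_preserving", "sample_id", "skip_reads",
                "mean_normal_reads", "local_esr",
            ]),
            out / "esr_matrix.tsv",
        )
        summary_rows = [
            skip_stats.sample_summary(table, combined_kinds, records, s)
            for s in table.samples
        ]
        tables["sample_summary"] = _write(
            pd.DataFrame(summary_rows, columns=[
                "sample_id", "total_junction_reads", "total_skip_reads",
                "global_esr", "mean_error_rate", "n_events_detected",
            ]),
            out / "sample_summary.tsv",
        )
        hc = skip_stats.high_confidence_filter(records, p.high_confidence_cutoff)
        tables["high_confidence"] = _write(
            pd.DataFrame(
                [
                    {
                        "event_id": e.event_id,
                        "gene_id": e.gene_id,
                        "donor_exon": e.donor_exon,
                        "acceptor_exon": e.acceptor_exon,
                        "skipped_nt": e.skipped_nt,
                        "frame_preserving": e.frame_preserving,
                    }
                    for e in sorted(hc, key=lambda e: e.event_id)
                ],
                columns=["event_id", "gene_id", "donor_exon", "acceptor_exon",
                         "skipped_nt", "frame_preserving"],
            ),
            out / "high_confidence.tsv",
        )
        if config.transcript_copies_path:
            copies = read_transcript_copies(config.transcript_copies_path)
            tables["copies_per_cell"] = _write(
                skip_stats.copies_per_cell_table(records, copies),
                out / "copies_per_cell.tsv",
            )

    if config.run_circ and circ_db is not None:
        records = circ_stats.circ_records(circ_db, table, genes)
        tables["circ_report"] = _write(
            circ_stats.circ_report(records, table, circ_db, genes),
            out / "circ_report.tsv",
        )
        ratio_rows = []
        for s in table.samples:
            # global denominator spans linear junction reads from the skip arm
            ratio = circ_stats.global_circ_ratio(table, combined_kinds, s)
            ratio_rows.append({"sample_id": s, "global_circ_ratio": ratio})
        tables["circ_ratios"] = _write(
            pd.DataFrame(ratio_rows, columns=["sample_id", "global_circ_ratio"]),
            out / "circ_ratios.tsv",
        )

    if config.run_novel and exhaustive_db is not None:
        candidates = novel.collect_candidates(exhaustive_db, table, genome)
        candidates = novel.collapse_redundancy(candidates)
        for c in candidates:
            novel.classify_intron(c, annotation)
        curve = novel.fdr_curve(candidates)
        threshold = novel.select_threshold(curve, p.fdr_alpha) if curve else 1
        reported = [
            c for c in candidates
            if c.canonical and c.unique_start_count > threshold
        ]
        cryptic, putative_novel = novel.inefficiency_partition(
            reported, p.inefficiency_cutoff
        )
        cryptic_keys = {c.key for c in cryptic}
        novel_keys = {c.key for c in putative_novel}
        ordered = sorted(candidates, key=lambda x: x.key)
        df = novel.candidate_report(candidates)
        df["reported"] = [
            c.canonical and c.unique_start_count > threshold for c in ordered
        ]
        df["partition"] = [
            ("cryptic" if c.key in cryptic_keys
             else "putative_novel" if c.key in novel_keys else "")
            for c in ordered
        ]
        tables["novel_introns"] = _write(df, out / "novel_introns.tsv")
        tables["fdr_curve"] = _write(novel.fdr_report(curve), out / "fdr_curve.tsv")

    _write_run_log(out / "run_log.txt", config, sample_status, stage_tallies)
    tables["run_log"] = out / "run_log.txt"
    return RunResult(
        out_dir=out, tables=tables,
        sample_status=sample_status, stage_tallies=stage_tallies,
    )


class _CombinedKinds:
    """kind_of adapter over the union of all databases."""

    def __init__(self, kind_map: dict[str, str]):
        self._map = kind_map

    def kind_of(self, junction_id: str) -> str:
        return self._map.get(junction_id, "?")


def _write_run_log(path: Path, config: RunConfig, status, tallies) -> None:
    with open(path, "w") as fh:
        fh.write("splicesurvey run log\n")
        fh.write("parameters:\n")
        for f in dataclasses.fields(config.params):
            fh.write(f"  {f.name} = {getattr(config.params, f.name)}\n")
        fh.write(f"  stages: skip={config.run_skip} circ={config.run_circ} "
                 f"novel={config.run_novel}\n")
        fh.write("samples:\n")
        for sample in sorted(status):
            fh.write(f"  {sample}: {status[sample]}\n")
            for stage, counter in sorted(tallies.get(sample, {}).items()):
                fh.write(f"    {stage}: {counter}\n")
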