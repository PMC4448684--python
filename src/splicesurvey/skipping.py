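"""Exon-skipping statistics.

The central quantities are the exon-skipping ratios (ESR):

* global ESR — the proportion of exon-skipping diagnostic reads among all
  exon-exon junction reads of a sample (skip / (normal + skip));
* local ESR — per skip event (i, j), skip reads divided by (skip reads +
  the arithmetic mean of the read counts of the consecutive junctions
  (i, i+1) .. (j-1, j) that the skip replaces).  The mean (rather than the
  sum) avoids double-counting multi-junction spans and reduces to
  skip/(skip+normal) for single-exon skips; the locus definition of the
  denominator is a package design choice.

When skipping is read as a splicing error, the mean of the local ESRs over
the detected event set is the per-sample splicing-error rate by exon
skipping, and local ESR x transcript copies/cell estimates the absolute
abundance of the aberrant isoform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2

from .genome import GeneModel
from .junctions import JunctionDatabase
from .mapping import JunctionCountTable


@dataclass(frozen=True)
class SkipEvent:
    """An (i, j) exon-skipping event, j >= i+2; 1-based transcript indices."""

    gene_id: str
    donor_exon: int
    acceptor_exon: int
    skipped_nt: int

    def __post_init__(self) -> None:
        if self.acceptor_exon < self.donor_exon + 2:
            raise ValueError("skip event needs acceptor >= donor + 2")

    @property
    def skipped_exon_indices(self) -> list[int]:
        return list(range(self.donor_exon + 1, self.acceptor_exon))

    @property
    def frame_preserving(self) -> bool:
        return self.skipped_nt % 3 == 0

    @property
    def event_id(self) -> str:
        return f"{self.gene_id}:skip:{self.donor_exon}-{self.acceptor_exon}"


def skip_event_from_gene(gene: GeneModel, donor: int, acceptor: int) -> SkipEvent:
    skipped_nt = sum(gene.exon_length(k) for k in range(donor + 1, acceptor))
    return SkipEvent(gene.gene_id, donor, acceptor, skipped_nt)


def events_from_database(db: JunctionDatabase, genes: list[GeneModel]) -> list[SkipEvent]:
    by_id = {g.gene_id: g for g in genes}
    return [
        skip_event_from_gene(by_id[j.gene_id], j.donor_exon, j.acceptor_exon)
        for j in db.junctions
        if j.kind == "skipping" and j.gene_id in by_id
    ]


@dataclass
class EsrRecord:
    event: SkipEvent
    sample_id: str
    skip_reads: int
    normal_reads: float  # mean over the replaced consecutive junctions
    local_esr: float | None  # None when skip + normal == 0 ("undetected")

    @property
    def detected(self) -> bool:
        return self.local_esr is not None


def global_esr(table: JunctionCountTable, db: JunctionDatabase, sample: str) -> float | None:
    """Skip reads / (normal + skip reads) for one sample; None if the sample
    has no junction reads."""
    skip = normal = 0
    for jid in table.junctions(sample):
        kind = db.kind_of(jid)
        if kind == "skipping":
            skip += table.read_count(sample, jid)
        elif kind == "normal":
            normal += table.read_count(sample, jid)
    total = skip + normal
    if total == 0:
        return None
    return skip / total


def local_esr(
    event: SkipEvent, table: JunctionCountTable, db: JunctionDatabase, sample: str
) -> EsrRecord:
    skip_id = event.event_id
    if skip_id not in {j.junction_id for j in db.junctions}:
        raise KeyError(f"skip junction {skip_id} not in database")
    skip = table.read_count(sample, skip_id)
    consecutive = [
        table.read_count(sample, f"{event.gene_id}:normal:{k}-{k + 1}")
        for k in range(event.donor_exon, event.acceptor_exon)
    ]
    normal = sum(consecutive) / len(consecutive)
    denom = skip + normal
    esr = skip / denom if denom > 0 else None
    return EsrRecord(event, sample, skip, normal, esr)


def esr_matrix(
    events: list[SkipEvent],
    table: JunctionCountTable,
    db: JunctionDatabase,
    samples: list[str] | None = None,
) -> list[EsrRecord]:
    if samples is None:
        samples = table.samples
    skip_ids = {j.junction_id for j in db.junctions if j.kind == "skipping"}
    records = []
    for event in events:
        if event.event_id not in skip_ids:
            raise KeyError(f"skip junction {event.event_id} not in database")
        for sample in samples:
            skip = table.read_count(sample, event.event_id)
            consecutive = [
                table.read_count(sample, f"{event.gene_id}:normal:{k}-{k + 1}")
                for k in range(event.donor_exon, event.acceptor_exon)
            ]
            normal = sum(consecutive) / len(consecutive)
            denom = skip + normal
            records.append(
                EsrRecord(event, sample, skip, normal,
                          skip / denom if denom > 0 else None)
            )
    return records


def mean_error_rate(records: list[EsrRecord], sample: str) -> float | None:
    """Mean local ESR over events detected (defined denominator) in this
    sample — the sample's splicing-error rate by exon skipping."""
    vals = [r.local_esr for r in records if r.sample_id == sample and r.detected]
    if not vals:
        return None
    return sum(vals) / len(vals)


def copies_per_cell(record: EsrRecord, transcript_copies: float) -> float:
    """Aberrant-isoform copies/cell = local ESR x transcript copies/cell.

    Records with ESR 0 are excluded from log-scale reports by callers."""
    if transcript_copies < 0:
        raise ValueError("transcript_copies must be >= 0")
    if record.local_esr is None:
        raise ValueError("undetected event has no copies-per-cell estimate")
    return record.local_esr * transcript_copies


def copies_per_cell_table(
    records: list[EsrRecord], transcript_copies: dict[str, float]
) -> pd.DataFrame:
    """Copies/cell for all detected events with a known copy number; events
    with ESR 0 or a missing copy-number entry are skipped."""
    rows = []
    for r in records:
        if not r.detected or r.local_esr == 0:
            continue
        copies = transcript_copies.get(r.event.gene_id)
        if copies is None:
            continue
        cpc = copies_per_cell(r, copies)
        rows.append(
            {
                "event_id": r.event.event_id,
                "sample_id": r.sample_id,
                "local_esr": r.local_esr,
                "transcript_copies": copies,
                "copies_per_cell": cpc,
                "log2_copies_per_cell": math.log2(cpc) if cpc > 0 else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "sample_id", "local_esr", "transcript_copies",
                 "copies_per_cell", "log2_copies_per_cell"],
    )


def high_confidence_filter(
    records: list[EsrRecord], min_reads: int = 8
) -> list[SkipEvent]:
    """Events supported by more than ``min_reads`` skip reads in at least
    one sample (strictly greater: max 8 is excluded, 9 is included)."""
    best: dict[str, tuple[int, SkipEvent]] = {}
    for r in records:
        cur = best.get(r.event.event_id)
        if cur is None or r.skip_reads > cur[0]:
            best[r.event.event_id] = (r.skip_reads, r.event)
    return [ev for eid, (mx, ev) in sorted(best.items()) if mx > min_reads]


def rank_by_reproducibility(
    records: list[EsrRecord],
    esr_threshold: float = 0.1,
    sample_subset: list[str] | None = None,
) -> list[tuple[SkipEvent, int]]:
    """Rank events by the number of samples (within ``sample_subset``) whose
    local ESR meets the threshold; ties broken by total skip reads, then
    event id."""
    n_meeting: dict[str, int] = {}
    total_skip: dict[str, int] = {}
    event_by_id: dict[str, SkipEvent] = {}
    for r in records:
        if sample_subset is not None and r.sample_id not in sample_subset:
            continue
        eid = r.event.event_id
        event_by_id[eid] = r.event
        n_meeting.setdefault(eid, 0)
        total_skip[eid] = total_skip.get(eid, 0) + r.skip_reads
        if r.detected and r.local_esr >= esr_threshold:
            n_meeting[eid] += 1
    ranked = sorted(
        event_by_id,
        key=lambda eid: (-n_meeting[eid], -total_skip[eid], eid),
    )
    return [(event_by_id[eid], n_meeting[eid]) for eid in ranked if n_meeting[eid] > 0]


def frame_preservation_summary(events: list[SkipEvent]) -> dict:
    """How many events excise a nucleotide count divisible by three (the sum
    over all skipped exons for multi-exon skips)."""
    n_total = len(events)
    n_preserving = sum(1 for e in events if e.frame_preserving)
    return {
        "n_preserving": n_preserving,
        "n_total": n_total,
        "fraction": n_preserving / n_total if n_total else float("nan"),
    }


def cmh_enrichment_test(strata: list, n_comparisons: int = 1) -> dict:
    """Cochran-Mantel-Haenszel chi-square test (1 df) across 2x2 strata.

    Each stratum is ``[[a, b], [c, d]]`` with rows (test sample, reference)
    and columns (skip reads, normal reads); replicates are strata.  The
    statistic uses the hypergeometric mean/variance form without continuity
    correction.  Bonferroni multiplies the p-value by the number of
    sample-vs-reference comparisons in the run, capped at 1.
    """
    if not strata:
        raise ValueError("need at least one stratum")
    sum_a = sum_e = sum_v = 0.0
    used = 0
    for tab in strata:
        (a, b), (c, d) = tab
        n = a + b + c + d
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        if min(r1, r2, c1, c2) == 0 or n < 2:
            import warnings

            warnings.warn(f"dropping degenerate stratum {tab}", stacklevel=2)
            continue
        used += 1
        sum_a += a
        sum_e += r1 * c1 / n
        sum_v += r1 * r2 * c1 * c2 / (n * n * (n - 1))
    if used == 0 or sum_v == 0:
        return {"statistic": 0.0, "p_value": 1.0, "p_bonferroni": 1.0, "n_strata": used}
    stat = (sum_a - sum_e) ** 2 / sum_v
    p = float(chi2.sf(stat, df=1))
    return {
        "statistic": float(stat),
        "p_value": p,
        "p_bonferroni": min(1.0, p * n_comparisons),
        "n_strata": used,
    }


def sample_summary(
    table: JunctionCountTable,
    db: JunctionDatabase,
    records: list[EsrRecord],
    sample: str,
) -> dict:
    skip = normal = 0
    for jid in table.junctions(sample):
        kind = db.kind_of(jid)
        if kind == "skipping":
            skip += table.read_count(sample, jid)
        elif kind == "normal":
            normal += table.read_count(sample, jid)
    total = skip + normal
    n_detected = sum(
        1 for r in records if r.sample_id == sample and r.detected and r.skip_reads > 0
    )
    return {
        "sample_id": sample,
        "total_junction_reads": total,
        "total_skip_reads": skip,
        "global_esr": skip / total if total else float("nan"),
        "mean_error_rate": mean_error_rate(records, sample),
        "n_events_detected": n_detected,
    }
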