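"""Shared fixtures and independent oracles.

The oracles here re-derive expected results by brute force, independently
of the package's search strategies: a quadratic position-by-position
mismatch scanner for read mapping, a double scan for candidate introns and
a pair enumerator for junction family sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

from splicesurvey.genome import AnnotationSet, GeneModel, GenomeModel, revcomp

# ---------------------------------------------------------------------------
# toy data builders


def random_genome(rng: np.random.Generator, lengths: dict[str, int]) -> GenomeModel:
    return GenomeModel(
        {
            name: "".join(rng.choice(list("ACGT"), size=n))
            for name, n in lengths.items()
        }
    )


def make_gene(
    gene_id: str,
    chromosome: str,
    strand: str,
    exons_genomic_ascending: list[tuple[int, int]],
    biotype: str = "protein_coding",
) -> GeneModel:
    exons = sorted(exons_genomic_ascending)
    if strand == "-":
        exons = exons[::-1]
    return GeneModel(gene_id, chromosome, strand, exons, biotype)


@pytest.fixture
def toy_rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_genome(toy_rng):
    return random_genome(toy_rng, {"chrI": 600, "chrII": 400})


@pytest.fixture
def toy_annotation(toy_genome):
    genes = [
        make_gene("gA", "chrI", "+", [(10, 60), (100, 160), (200, 260), (300, 360)]),
        make_gene("gB", "chrI", "-", [(400, 430), (460, 520)]),
        make_gene("gC", "chrII", "+", [(50, 150)]),
    ]
    return AnnotationSet(genes)


# ---------------------------------------------------------------------------
# independent mapping oracle


def scan_hits(read: str, targets: list[tuple[str, str, str]], max_mm: int):
    """All alignments of ``read`` with <= max_mm mismatches by brute force.

    Targets are (kind, id, sequence).  A hit is (kind, id, forward_offset,
    strand, mismatches); strand "-" means the reverse complement of the read
    matches the forward target there.  N on the read side never matches.
    """
    hits = []
    variants = [(read, "+"), (revcomp(read), "-")]
    for kind, tid, seq in targets:
        for probe, strand in variants:
            for off in range(len(seq) - len(probe) + 1):
                mm = 0
                for a, b in zip(probe, seq[off : off + len(probe)]):
                    if a != b or a == "N":
                        mm += 1
                        if mm > max_mm:
                            break
                if mm <= max_mm:
                    hits.append((kind, tid, off, strand, mm))
    return hits


def scan_classify(read: str, targets, max_mm: int):
    """(status, best_hits) under the minimal-mismatch uniqueness rule."""
    hits = scan_hits(read, targets, max_mm)
    if not hits:
        return "unmapped", []
    m_star = min(h[4] for h in hits)
    best = [h for h in hits if h[4] == m_star]
    return ("unique" if len(best) == 1 else "ambiguous"), best


# ---------------------------------------------------------------------------
# independent candidate-intron oracle


def scan_introns(seq: str, donor: str, acceptor: str, min_len: int):
    """Quadratic double scan: all (d, a2) with seq[d:d+2] == donor,
    seq[a2-2:a2] == acceptor and a2 - d >= min_len; returns region
    half-open intron intervals."""
    out = []
    for d in range(len(seq) - 1):
        if seq[d : d + 2] != donor:
            continue
        for a in range(len(seq) - 1):
            if seq[a : a + 2] != acceptor:
                continue
            a2 = a + 2
            if a2 - d >= min_len:
                out.append((d, a2))
    return sorted(out)


# ---------------------------------------------------------------------------
# independent junction family-size oracle


def pair_counts(n_exons: int) -> dict[str, int]:
    """Family sizes by enumerating all ordered exon pairs."""
    normal = skipping = circular = 0
    for i in range(1, n_exons + 1):
        for j in range(1, n_exons + 1):
            if j == i + 1:
                normal += 1
            if j >= i + 2:
                skipping += 1
            if j >= i:
                circular += 1
    return {"normal": normal, "skipping": skipping, "circular": circular}
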