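# Methods

`splicesurvey` reimplements a brute-force junction-database strategy for
surveying low-frequency splicing events — exon skipping, backsplicing
(circRNA) and cryptic/novel intron usage — in a compact, intron-rich genome
such as fission yeast. This note records the model, the parameter choices
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## The junction-database model

All detection is by **diagnostic reads**: a read that spans a splice joint
matches a sequence that exists only in the corresponding isoform, never in
the genome. For each gene (one annotated exon chain per gene; multi-
transcript annotations collapse to the first chain with a warning) we
enumerate:

- **normal** junctions — consecutive exon pairs (i, i+1);
- **skipping** junctions — all pairs (i, j) with j ≥ i+2; the skipped exons
  are i+1 … j−1;
- **circular** junctions — backsplice pairs: the 3′ end of exon j joined to
  the 5′ start of exon i for all j ≥ i. j = i is a single-exon circle;
  single-exon genes also get one, deliberately: a gene without introns
  cannot circularize spliceosomally, so reads on those junctions estimate
  baseline noise. Forward shuffles j < i are already covered by the
  normal/skipping families and are not duplicated here.

For an n-exon gene the family sizes are n−1, (n−1)(n−2)/2 and n(n+1)/2.

**Flank rule.** For read length X, normal/skipping junctions carry the last
X−6 nt of the donor exon and the first X−6 nt of the acceptor exon (the
whole exon when shorter). Consequently any full-length read that fits
inside a junction overlaps the breakpoint by ≥ 6 nt on both sides — the
minimum-overhang filter is built into the geometry, and this implication is
asserted as a test. Circular and exhaustive-search junctions use a fixed
57 nt flank so one database serves libraries of mixed read lengths
(49–76 nt); there the ≥ 6 nt overhang filter is applied explicitly.

## Read assignment

The matcher emulates a short-read aligner in best-stratum unique-only mode.
Every alignment of the read — both orientations, genome and junctions, up
to `max_mismatch` substitutions — is enumerated; the read is kept only if a
single alignment attains the minimal mismatch count. Staged protocol:

1. genome + normal/skipping database, ≤ 3 mismatches, unique, overhang ≥ 6;
2. stage-1 unmapped reads vs the circular database, 0 mismatches, unique,
   overhang ≥ 6;
3. the same stage-1 unmapped reads vs the exhaustive candidate-intron
   database, 0 mismatches, unique, overhang ≥ 6.

Mismatch-tolerant search uses pigeonhole seeding (split a read into m+1
segments; one must be error-free) with exact verification, so it is
provably exhaustive within the budget; the test suite checks agreement with
a position-by-position scanner over a 10 kb world, including ambiguous and
unmapped classes. `N` never matches anything, on either side. Both genome
strands are searched, and junction databases are searched with the read in
both orientations, because library strandedness varies across samples.
The overhang filter is applied after uniqueness resolution (a unique but
short-overhang junction hit is discarded and tallied, not re-assigned).
Identical read sequences are deduplicated before mapping and counted with
their multiplicity; this changes nothing statistically and makes deep
error-free simulations cheap.

Per junction and sample we track read count, distinct alignment start
offsets (`unique_start_count`) and distinct read sequences
(`unique_sequence_count`). Distinct starts, pooled over samples, are the
support variable of the decoy FDR; distinct sequences are the variable of
the cryptic/novel partition. Both are emitted since either reading of
"unique sequence reads starting at different locations" is defensible.

## Exon-skipping statistics

- **Global ESR** per sample: skip reads / (normal + skip reads).
- **Local ESR** per event (i, j): skip / (skip + mean of the consecutive
  junction counts (i,i+1) … (j−1,j)). The source method does not pin down
  the denominator at a locus; the mean of the junctions the skip replaces
  avoids double-counting multi-junction spans and reduces to
  skip/(skip+normal) for single-exon skips. A zero denominator flags the
  event "undetected" in that sample and excludes it from averages.
- **Splicing-error rate** per sample: mean local ESR over events with a
  defined denominator (the detected-in-any-sample event set is held fixed
  across samples; undetected events are excluded rather than zero-filled).
- **Copies per cell**: local ESR × the gene's transcript copies/cell;
  ESR-zero events are excluded from log-scale reports.
- Filters: high-confidence events need > 8 skip reads in ≥ 1 sample;
  reproducibility ranking counts samples with local ESR ≥ 0.1 (ties broken
  by total skip reads, then event id); frame preservation sums the skipped
  exon lengths and tests divisibility by 3.
- **Enrichment** between a sample group and a reference uses the
  Cochran–Mantel–Haenszel chi-square (1 df, hypergeometric mean/variance,
  no continuity correction) with replicates as strata, Bonferroni-corrected
  by the number of sample-vs-reference comparisons. For a single stratum
  CMH equals Pearson's X² times (n−1)/n; tests assert both this relation
  and agreement with an independent implementation.

## Circular-RNA statistics

Global ratio: circular reads / (circular + normal + skipping reads). Local
ratio per circle: circ / (circ + mean normal-junction count of the gene),
skipping reads excluded. Loci with no normal coverage (intronless genes)
degenerate to ratio 1 for any read and are flagged suspect rather than
dropped. The replicate filter keeps circles seen with ≥ 1 read in ≥ 2
replicates of one condition group. Structure summaries bin reads by the
number of introns between the joint exons and report the intronless-gene
read share as the noise floor.

## Exhaustive intron search and decoy FDR

Each gene region (gene span ± 300 nt, clipped to the chromosome) is scanned
on the gene's strand for all 256 donor×acceptor dinucleotide combinations;
every pair whose intron (donor dinucleotide through acceptor dinucleotide,
inclusive) is ≥ 10 nt becomes a candidate with up to 57 nt flanks.
Identical genomic introns reachable from overlapping regions are collapsed
at build time (longest flanks win), so no read is ever counted through two
region copies. Only GT..AG (GU..AG in RNA) is spliceosomally meaningful;
the other 255 combinations are decoys, giving

    FDR(t) = R(t) / (C(t) + R(t))

over junctions with more than t pooled distinct start positions. The
reported threshold is the smallest t with FDR ≤ α (default 0.05); the
reported list is canonical junctions above it. Candidates are classified
against the annotated intron set (known / one annotated site / both novel)
and located by gene overlap with priority protein_coding > ncRNA >
intergenic. Candidates with ≤ 70 pooled unique sequences are partitioned as
cryptic (inefficiently spliced), the rest as putative novel introns.

Note an intrinsic resolution limit of 0-mismatch junction matching: when
the genomic base after a donor equals the base at the donor (or mirror case
at the acceptor), a junction read also matches the ±1-shifted candidate and
is discarded as ambiguous. Support counts are therefore conservative; the
effect is shared by any aligner run in unique-only mode on this database.

## The synthetic world

`simulate_genome` builds one uniform-random chromosome with non-overlapping
genes on random strands; annotated introns are forced to GT..AG; requested
cryptic introns (GT..AG, ≥ 10 nt) are planted inside exon interiors and
recorded as ground truth. `simulate_reads` draws, per gene, a molecule pool
in which skip isoforms (per-event rate ε) and cryptically spliced isoforms
(usage rate) *replace* normal molecules — error semantics, not
co-expression — and survive nuclear surveillance with probability r;
circles arise at per-gene rate ρ (thinned ~10× in poly(A) libraries) in
addition to the pool. Reads of length X start uniformly along each
molecule, in numbers proportional to the molecule's window count
(`depth` = expected reads per normal molecule), which is what makes the
local ESR an unbiased estimator of ε under fragmentation; circular
molecules are sampled with wrap-around. Substitution errors are applied by
exact binomial thinning; errors never produce N. Chimeric artifact reads —
two random genomic positions of a gene region joined with ≥ 6 nt on each
side — emulate the template-switching artifacts that the decoy FDR exists
to control; their intron-boundary dinucleotides are random, so ~1/256 are
canonical-looking false positives.

Not emulated: quality scores, indels, fragment-size or GC bias, expression
heterogeneity between genes, paired ends, intron retention. A green test
therefore establishes correctness of the counting and statistics under the
stated generative model, not robustness to alignment artifacts absent from
that model.

Default rates are the measured scale of the emulated biology: ε = 0.0024
(the wild-type splicing-error rate by exon skipping of ~0.24%), retention
r = 1 (observed rates are post-surveillance), sequencing error 10⁻³ per
base, read length 57 nt (the mixed-length compromise used for the fixed-
flank databases), circles off unless requested.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GFF3 and report TSVs are
  1-based inclusive. Junction ids (`gene:kind:donor-acceptor`,
  `novel:chrom:strand:start-end`) are stable join keys across samples.
- Junctions containing N are dropped with a logged count (exact matching
  against N is undefined).
- The FDR threshold grid is the integers 1 … max support; when no point
  reaches α the maximum threshold is reported with a warning. FDR is 0 when
  R = 0 with survivors, undefined (skipped) when nothing survives.
- Degenerate CMH strata (a zero margin) are dropped with a warning.
- All outputs are sorted (junction id, then sample id) and floats are
  formatted with a fixed `%.10g`, so reruns are byte-identical; the CLI's
  `--threads` flag never influences results.
- Acceptance-scale simulations are scaled down to desk size (10-gene
  recovery worlds, 2-gene FDR worlds with read length 33 and 25–27 nt
  flanks) purely for runtime; rates, cutoffs and interval levels are the
  stated ones.

## Known limitations

- One exon chain per gene; no trans-splicing, no overlapping-gene
  resolution, no UTR inference.
- The exhaustive search scans each gene region on the annotated gene's
  strand only; antisense introns in the ± 300 nt flanks are not discovered.
- No quality-aware alignment and no indels; mapping is exact-match with a
  substitution budget.
- The exhaustive database grows quadratically with region length; genome-
  scale runs need the batching the CLI does not provide (regions are
  independent, so external sharding is trivial and results are unaffected).
- Local ESR/circ denominators are package definitions (see above); other
  reasonable locus definitions would shift local ratios by a bounded,
  monotone amount.
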