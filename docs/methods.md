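# Methods

## The simulation model

`ss3reads` models a Smart-seq3 library as a two-class mixture of read
pairs per cDNA molecule. Each molecule is a transcript copy carrying the
protocol's 5′ decoration — the tag `ATTGCGCAATG`, a random UMI, and the
`GGG` left by template switching. UMI-containing read pairs originate at
the decorated 5′ end and preserve the transcript's strand; internal read
pairs come from elsewhere in the molecule, carry no UMI, and lose strand
information (modeled as a fair reverse-complement coin flip). All
quantitative behaviour — how long fragments are, how many duplicates a UMI
accrues, how many internal reads accompany each UMI read, how much
unspliced pre-mRNA a gene carries, what the quality profile looks like —
is driven by *empirical distributions* measured from a real tagged BAM,
not by parametric assumptions. Sampling is always from the weighted
support of those distributions, so simulated values never leave the
observed range.

## Characterization

Read pairs are streamed from the BAM(s) as mated primary alignments;
secondary, supplementary and unmapped records are dropped, and pairs
without a `BC` tag are counted and skipped (real zUMIs output contains
unassigned reads; a missing barcode should not abort a 40-minute pass).
A pair is *UMI-containing* iff its `UB` tag is present and non-empty.

Fragment lengths are measured only on **estimation genes**: genes on
chromosomes 1–22, X or Y (with or without a `chr` prefix) that have
exactly one annotated transcript and whose genomic span overlaps no other
gene, strand-agnostically. Span-level, strand-agnostic overlap is the
conservative reading that minimizes read-assignment ambiguity. The
fragment length of a pair is the count of exonic positions in
`[fragment_start, fragment_end)`, the outermost aligned coordinates of the
pair; soft-clipped bases are not counted (aligned positions only). Pairs
with zero exonic overlap are dropped from the length distributions.

All gene-keyed statistics (reads per UMI, internal:UMI ratio, UMIs per
gene, unspliced fraction) are also computed on the estimation subset,
where read-to-gene assignment is unambiguous — a deliberate choice that
trades sample size for freedom from multi-gene ambiguity. Reads per UMI
is keyed on (barcode, gene, UMI), because random UMIs recur across genes.
The internal:UMI ratio is per gene, pooled over cells; genes with zero
UMI-containing pairs are dropped (the ratio is undefined) and logged. The
unspliced fraction per (gene, cell) is intronic covered positions over
all covered positions, where coverage is the union of aligned block
positions within the gene span and introns are the complement of the
union of the gene's annotated exons; gene-cells with zero coverage are
omitted.

Quality profiles pool all primary reads; the profile length is the modal
read length, with shorter reads contributing to their positions only. A
barcode-segment profile is kept as the first 16 positions of read-1
qualities (tagged BAMs carry no separate barcode quality string); it is
available in the bundle but unused by the simulation default.

The characteristics bundle is serialized as a single schema-versioned
JSON document (support values + weights per distribution, one entry per
read position for the quality profiles), so it is diffable, portable and
round-trips losslessly.

## Ground truth

Coordinates are 0-based half-open internally; GTF input/output converts
at the boundary. Transcript sequences are always reported 5′→3′ in mRNA
sense (minus-strand sequences reverse-complemented).

**Gene UMI matrix.** One base count per gene per population is drawn from
the UMIs-per-gene distribution conditioned on ≥ *n* (equivalent to
redraw-until-minimum, but exact); *n* defaults to the gene's transcript
count so every isoform can receive at least one UMI in expectation. Each
cell scales its population's base counts by a size factor *s* drawn
log2-uniformly on [2⁻², 2²] — the range is stated in powers of two, and
log-uniform makes halving and doubling equally likely — rounded half-even,
with the minimum re-applied after scaling.

**PSI matrix.** Per gene and population the 100 % total is split by a flat
Dirichlet draw (the least-informative "random distribution" over the
simplex). Fixed-splicing genes reuse one draw across populations;
differentially spliced genes (chosen at random under the seed) draw
independently per population. Novel transcripts participate in the PSI
draw as ordinary isoforms of their gene.

**Unspliced matrix.** Fixed genes share one empirical draw across
populations; differential genes draw per population. A custom matrix
(validated to [0, 1] and the right shape) passes through verbatim — the
intended route for single-nuclei-like designs. Unspliced molecules are
represented as one pre-mRNA species per gene (the full genomic span,
introns retained), matching the gene-level granularity of the matrix.

**Combination.** For gene *g*, cell *j* in population *q*:
`u = round(counts[g,j] · unspl[g,q])` UMIs go to the pre-mRNA row; the
remaining `counts[g,j] − u` are apportioned over isoforms by
largest-remainder rounding of their PSI shares. Largest-remainder
apportionment conserves per-gene per-cell totals *exactly* and introduces
no systematic bias; ties break by row order.

**Novel events.** A novel junction joins two non-overlapping exons of the
gene not already joined by any annotated transcript; the chain is built by
editing a randomly chosen annotated backbone and is rejected if it
collides with an annotated chain. A novel exon is placed strictly inside
an intron of a backbone transcript with a 2 nt margin at both intron ends
(the pre-existing splice sites are never touched); with `canonical=True`
the placement is an exhaustive scan for positions whose flanks read `AG`
(acceptor) and `GT` (donor) on the sense strand — on the minus strand the
genomic motifs are `CT`/`AC` — and one admissible (intron, offset, length)
triple is chosen uniformly under the seed. An independent verifier
(`verify_canonical_junctions`) re-reads the genome at every junction of
the emitted transcript and shares no code with the search.

## Simulation

Steps run per cell, in protocol order. Choices the protocol description
leaves open:

- **PAF semantics.** Amplified copies = `max(1, round(r · PAF))` where
  *r* is the molecule's reads-per-UMI draw; subsampling later restores
  exactly *r* UMI pairs per molecule (PAF ≥ 1 guarantees availability).
  This realizes inflate-then-subsample without modeling cycle-by-cycle
  PCR. Default PAF = 5, configurable; any value ≥ 1 satisfies the
  contract.
- **Fragment lengths are clamped**, never resampled, when a draw exceeds
  the available sequence — unbiased for long transcripts, deterministic
  for short ones; a known deviation source for very short transcripts.
- **Internal fragments.** The ratio is drawn once per molecule and
  multiplied by the number of amplified copies; each internal fragment
  picks a copy's post-prefix remainder uniformly (empty remainders
  excluded), then a uniform start offset. Tn5 positional bias is not
  modeled.
- **Subsampling.** UMI pairs: per molecule, `min(r, available)` kept
  uniformly without replacement. Internal pairs: a deterministic global
  count `round(f · n_internal)` with *f* the realized UMI retention
  fraction, preserving the internal:UMI balance set at generation.
- **Errors** are injected on final read sequences (after fragment
  extraction, before quality assignment): independent per-base
  Bernoulli(*P*) substitutions, uniform over the three alternatives, no
  indels. PCR duplicates therefore differ only by sequencing error;
  heritable PCR errors are out of scope.
- **UMI uniqueness** is enforced within (cell, gene) so truth counts stay
  identifiable; cross-gene collisions are allowed, as in real data.
  Defaults: UMI 8 nt, barcode 16 nt (protocol convention), read length
  150 nt.
- **Reproducibility.** One master seed spawns per-cell child generators
  via `numpy.random.SeedSequence`; identical inputs and seed give
  byte-identical FASTQ. The CLI derives per-stage seeds from the global
  seed by hashing the stage name into a `SeedSequence`.

GC bias is deliberately not modeled (none is observed in the protocol's
data), and no BAM output, adapter read-through or indel errors are
produced.

## Synthetic fixtures and what they show

The fixture world fabricates contigs `chr1`/`chr2` with single-exon
estimation genes, one two-exon single-transcript gene (so the unspliced
fraction is exercised), multi-isoform genes whose introns carry planted
canonical novel-exon sites at recorded positions, and decoys that must
fail the estimation filter (a two-transcript gene, an overlapping pair, a
`chrM` gene). The toy BAM draws fragment spans from a discretized
log-normal (mean ≈ 372 nt), duplicates UMI pairs geometrically
(mean 2), and records every sampled value in a ledger, so the
characterization path is tested as parameter recovery against known
inputs. The packaged default characteristics are parametric stand-ins
with the same family shapes (log-normal lengths, geometric reads/UMI,
zero-inflated unspliced fractions, decaying truncated-normal qualities).

The fixtures emulate the *statistical* structure of tagged Smart-seq3
data, not its biology: genomes are random sequence, exon/intron
architecture is regular, expression has no gene-length or GC structure,
and alignment is noiseless (no soft clips, no multimappers, no splicing
across reads). Passing tests therefore demonstrate that the measurement
and simulation machinery is correct and self-consistent — not that any
particular biological dataset is reproduced.

## Problem sizes

The test suite and the acceptance script run a scaled study-shaped
configuration — 50 multi-isoform genes and 2 populations × 10 cells
(≈ 5 × 10⁴ read pairs, ≈ 2 × 10⁷ bases) — which gives 3σ binomial
intervals of ±2 × 10⁻⁴ around the 0.005 error rate and ±0.008 around the
0.5 antisense fraction, and Kolmogorov–Smirnov resolution of ~0.013 for
the distribution round trips. Resampling calibration for the KS
thresholds uses 500 null replicates at the observed sample sizes and the
99.8 % quantile.

## Known limitations

- Fragment-length realism degrades for transcripts shorter than typical
  fragment draws (clamping concentrates mass at the transcript length).
- The estimation-gene restriction can leave few genes in sparse or
  heavily overlapping annotations; the characterization then errors and
  points the user to the packaged defaults rather than silently
  extrapolating.
- Internal reads are subsampled by a global fraction, so per-molecule
  internal counts are binomially thinned rather than exactly preserved.
- Quality scores are sampled independently per position; within-read
  quality autocorrelation is not modeled.
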