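# ss3reads

A splice-aware read simulator for Smart-seq3 single-cell RNA sequencing.

Smart-seq3 captures full-length transcripts while attaching unique
molecular identifiers (UMIs), which makes it the protocol of choice for
isoform reconstruction and alternative-splicing quantification at
single-cell resolution. Benchmarking the computational tools for those
tasks requires datasets with a known ground truth, which real experiments
cannot provide. `ss3reads` fills that gap: it learns empirical protocol
biases from a real tagged BAM, lets the user design a ground truth with
known *and novel* isoforms, and writes raw paired-end FASTQ reads — both
the strand-preserving UMI-containing reads and the strand-less internal
reads characteristic of the protocol — so that genome- or
transcriptome-based pipelines can be scored end to end.

## What it does

**1. Characterization** (`characterize`). From one or more coordinate-sorted
BAMs carrying the cell barcode in the `BC` tag and the UMI in the `UB` tag
(the zUMIs convention), six empirical distributions are extracted: fragment
lengths of UMI-containing and internal reads, reads per UMI, the per-gene
ratio of internal to UMI-containing reads, the per-gene-per-cell unspliced
fraction, UMIs per gene, and per-position Phred quality profiles. Fragment
lengths are measured on an unambiguous subset of genes — single-transcript,
non-overlapping, on chromosomes 1–22/X/Y — so they reflect the protocol
(tagmentation time, library prep) rather than isoform variability. The
fragment length of a read pair is the number of *exonic* positions between
the outermost aligned ends.

**2. Ground truth** (`ground-truth`). For an experiment of `p` cell
populations × `c` cells, the transcript-by-cell UMI count matrix is built
in three steps:

- a gene-level UMI matrix: per population, base counts drawn from the
  empirical UMIs-per-gene distribution (minimum `n` per gene), then scaled
  per cell by a size factor `s` sampled from `[2⁻², 2²]`;
- a transcript PSI matrix: per gene and population, the total PSI of 100 %
  is distributed uniformly at random over the gene's isoforms (Ψ values);
  splicing is population-specific, so fixed-splicing genes share one PSI
  vector across populations while differentially spliced genes draw
  independently;
- an unspliced-fraction matrix per gene and population (a custom matrix,
  e.g. with high fractions for single-nuclei designs, may be supplied).

Novel isoforms can be injected by joining existing exons with unannotated
junctions (`addNewJunction`-style) or by placing a new exon inside an
intron such that both new junctions carry canonical splice sites — `AG`
acceptor and `GT` donor on the sense strand (`canonical=False` lifts the
restriction).

**3. Simulation** (`simulate`). Per cell: each molecule is the transcript
sequence prefixed with the Smart-seq3 tag `ATTGCGCAATG`, its random UMI and
`GGG`; a reads-per-UMI target is drawn and temporarily inflated by the PCR
amplification factor (PAF); UMI-containing fragments are 5′ prefixes with
empirically sampled lengths, internal fragments are random subfragments of
the remainder (count = empirical ratio × UMI fragments) reverse-complemented
with probability 0.5; read 1 / read 2 are the first / last 150 bp of each
fragment; per-base substitution errors at rate *P* (default 0.005); the
read set is subsampled back to the pre-PAF targets; qualities come from the
positional empirical profile. Output: `_R1/_R2` FASTQ, a truth table
mapping every read id to its barcode, UMI, transcript, role and fragment
coordinates, and the barcode list.

## Worked example

Everything below runs from fabricated fixtures — no downloads:

```
ss3reads fixtures   --out-dir fixtures --seed 5
ss3reads characterize --bam fixtures/toy.bam --gtf fixtures/annotation.gtf \
                      --out chars.json
ss3reads ground-truth --gtf fixtures/annotation.gtf --fasta fixtures/genome.fa \
                      --characteristics chars.json --genes 3 \
                      --transcripts-per-gene 2 --novel-exons 1 \
                      --populations 2 --cells 4 --seed 5 --out-dir truth
ss3reads simulate     --truth-dir truth --characteristics chars.json \
                      --out-prefix sim/demo --paf 5 --seed 5
```

which prints

```
characterized 2583 pairs -> chars.json
ground truth: 7 transcripts, 8 cells -> truth
simulated 2432 read pairs -> sim/demo_R1.fastq
```

`characterized 2583 pairs` is the number of mated primary pairs the
characterization consumed; `7 transcripts` is 3 genes × 2 annotated
isoforms + 1 novel-exon isoform; `2432 read pairs` is the post-subsampling
read count over the 8 cells. The first simulated read:

```
@GATCTCCTCATCCAGG:0:U:DECOY2T-t1:4 1
ATTGCGCAATGAAGCCGTGGGGACCAGAAGAGAAGG...
```

The id encodes `barcode:molecule:role:transcript:duplicate` — this is a
UMI-containing (`U`) read of molecule 0 in the cell with barcode
`GATCTCCTCATCCAGG` — and the sequence starts with the Smart-seq3 tag
`ATTGCGCAATG`, the 8 nt UMI `AAGCCGTG` and `GGG`, followed by the 5′ end of
transcript `DECOY2T-t1`, exactly as the protocol dictates. The
accompanying `sim/demo_truth.tsv` records the fragment offset and length,
from which the error-free source sequence of every read can be
reconstructed.

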