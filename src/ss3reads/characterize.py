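"""Empirical protocol-bias extraction from a tagged Smart-seq3 BAM.

The characterization measures six empirical distributions from an aligned,
barcode/UMI-tagged dataset (zUMIs-style ``BC``/``UB`` tags): fragment
lengths for UMI-containing and internal reads, reads per UMI, the per-gene
ratio of internal to UMI-containing reads, the per-gene-per-cell unspliced
fraction, UMIs per gene, and per-position Phred quality profiles.  Fragment
lengths are measured only on an unambiguous "estimation gene" subset:
single-transcript genes on the primary chromosomes that overlap no other
gene, so lengths reflect the protocol rather than isoform variability.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats_io import (
    AlignedReadPair,
    GeneAnnotation,
    Transcript,
    read_alignment_pairs,
)

logger = logging.getLogger(__name__)

_PRIMARY_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}


class EmpiricalDistribution:
    """A weighted discrete empirical distribution.

    Holds support values with non-negative weights; sampling returns only
    support values and is reproducible under a seeded generator.
    """

    def __init__(self, values: Sequence[float], weights: Sequence[float]):
        values = np.asarray(values)
        weights = np.asarray(weights, dtype=float)
        if values.shape != weights.shape or values.ndim != 1:
            raise ValueError("values and weights must be 1-D and equal length")
        if len(values) == 0:
            raise ValueError("empirical distribution needs at least one value")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        total = weights.sum()
        if total <= 0:
            raise ValueError("weights must sum to a positive total")
        self.values = values
        self.weights = weights
        self._probs = weights / total

    @classmethod
    def from_samples(cls, samples: Sequence[float]) -> "EmpiricalDistribution":
        counter = Counter(samples)
        support = sorted(counter)
        return cls(support, [counter[v] for v in support])

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        idx = rng.choice(len(self.values), size=size, p=self._probs)
        return self.values[idx]

    def mean(self) -> float:
        return float(np.dot(self.values, self._probs))

    def var(self) -> float:
        m = self.mean()
        return float(np.dot((self.values - m) ** 2, self._probs))

    def min(self) -> float:
        return float(self.values.min())

    def max(self) -> float:
        return float(self.values.max())

    def restricted(self, lo: float) -> "EmpiricalDistribution":
        """The distribution conditioned on value >= lo."""
        mask = self.values >= lo
        if not mask.any():
            raise ValueError(f"no support value >= {lo}")
        return EmpiricalDistribution(self.values[mask], self.weights[mask])

    def __eq__(self, other) -> bool:
        return (isinstance(other, EmpiricalDistribution)
                and np.array_equal(self.values, other.values)
                and np.array_equal(self.weights, other.weights))

    def __repr__(self) -> str:
        return (f"EmpiricalDistribution(n_support={len(self.values)}, "
                f"mean={self.mean():.3g})")


@dataclass
class DataCharacteristics:
    """Bundle of the empirical distributions driving the simulation."""

    umi_fragment_length: EmpiricalDistribution       # nt, >= 1
    internal_fragment_length: EmpiricalDistribution  # nt, >= 1
    reads_per_umi: EmpiricalDistribution             # count >= 1
    internal_to_umi_ratio: EmpiricalDistribution     # per-gene ratio >= 0
    unspliced_fraction: EmpiricalDistribution        # per gene-cell, [0, 1]
    umis_per_gene: EmpiricalDistribution             # count >= 0
    quality_by_position_read: list[EmpiricalDistribution]
    quality_by_position_barcode: list[EmpiricalDistribution]
    metadata: dict = field(default_factory=dict)

    DISTRIBUTION_NAMES = (
        "umi_fragment_length", "internal_fragment_length", "reads_per_umi",
        "internal_to_umi_ratio", "unspliced_fraction", "umis_per_gene",
    )

    def named_distributions(self) -> dict[str, EmpiricalDistribution]:
        return {name: getattr(self, name) for name in self.DISTRIBUTION_NAMES}

    def validate(self) -> None:
        if self.umi_fragment_length.min() < 1 or self.internal_fragment_length.min() < 1:
            raise ValueError("fragment lengths must be >= 1")
        if self.reads_per_umi.min() < 1:
            raise ValueError("reads per UMI must be >= 1")
        if self.internal_to_umi_ratio.min() < 0:
            raise ValueError("internal:UMI ratio must be >= 0")
        if not (0 <= self.unspliced_fraction.min()
                and self.unspliced_fraction.max() <= 1):
            raise ValueError("unspliced fractions must lie in [0, 1]")
        if self.umis_per_gene.min() < 0:
            raise ValueError("UMIs per gene must be >= 0")
        if not self.quality_by_position_read:
            raise ValueError("read quality profile is empty")

    @property
    def read_length(self) -> int:
        return len(self.quality_by_position_read)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DataCharacteristics):
            return NotImplemented
        return (self.named_distributions() == other.named_distributions()
                and self.quality_by_position_read == other.quality_by_position_read
                and self.quality_by_position_barcode == other.quality_by_position_barcode
                and self.metadata == other.metadata)


# ---------------------------------------------------------------------------
# Estimation-gene filter
# ---------------------------------------------------------------------------

def _normalize_chrom(contig: str) -> str:
    return contig[3:] if contig.lower().startswith("chr") else contig


def select_estimation_genes(ann: GeneAnnotation) -> set[str]:
    """Genes usable for unambiguous parameter estimation.

    A gene qualifies iff it (1) lies on chromosome 1-22, X or Y (with or
    without a ``chr`` prefix), (2) overlaps no other gene on its genomic
    span, strand-agnostically, and (3) has exactly one annotated transcript.
    """
    selected = set()
    by_contig: dict[str, list] = defaultdict(list)
    for g in ann.genes:
        by_contig[g.contig].append(g)
    for g in ann.genes:
        if _normalize_chrom(g.contig).upper() not in _PRIMARY_CHROMS:
            continue
        if len(g.transcripts) != 1:
            continue
        overlapping = any(
            other.id != g.id and other.start < g.end and g.start < other.end
            for other in by_contig[g.contig]
        )
        if not overlapping:
            selected.add(g.id)
    return selected


# ---------------------------------------------------------------------------
# Per-pair measurements
# ---------------------------------------------------------------------------

def classify_pair(pair: AlignedReadPair) -> str:
    """``"umi-containing"`` iff the UB tag is present and non-empty."""
    return "umi-containing" if pair.is_umi_containing else "internal"

def exonic_fragment_length(pair: AlignedReadPair, transcript: Transcript) -> int:
    """Number of exonic positions between the outermost aligned ends of the pair.

    Returns 0 when the fragment span touches no exon (such pairs are dropped
    from the length distribution by the caller).
    """
    fs, fe = pair.fragment_start, pair.fragment_end
    return sum(
        max(0, min(fe, e.end) - max(fs, e.start)) for e in transcript.exons
    )


def _covered_positions(blocks: list[tuple[int, int]],
                       span: tuple[int, int]) -> set[int]:
    lo, hi = span
    pos: set[int] = set()
    for s, e in blocks:
        s, e = max(s, lo), min(e, hi)
        if s < e:
            pos.update(range(s, e))
    return pos


def unspliced_fraction_per_gene_cell(
        blocks_by_gene_cell: dict[tuple[str, str], list[tuple[int, int]]],
        ann: GeneAnnotation) -> dict[tuple[str, str], float]:
    """Intronic covered bases / total covered bases per (gene, cell).

    Coverage is the union of aligned block positions inside the gene span;
    introns are the complement of the union of the gene's annotated exons.
    Gene-cells with zero covered bases are omitted.
    """
    out: dict[tuple[str, str], float] = {}
    for (gid, cell), blocks in blocks_by_gene_cell.items():
        gene = ann.gene(gid)
        covered = _covered_positions(blocks, (gene.start, gene.end))
        if not covered:
            continue
        exonic: set[int] = set()
        for s, e in gene.exon_union():
            exonic.update(range(s, e))
        n_intronic = len(covered - exonic)
        out[(gid, cell)] = n_intronic / len(covered)
    return out


# ---------------------------------------------------------------------------
# characterize_data
# ---------------------------------------------------------------------------

def _assign_gene(pair: AlignedReadPair, genes_by_contig) -> Optional[str]:
    for gene in genes_by_contig.get(pair.contig, ()):
        if pair.fragment_start < gene.end and gene.start < pair.fragment_end:
            return gene.id
    return None


def characterize_data(bams, ann: GeneAnnotation,
                      region: Optional[str] = None,
                      barcode_profile_length: int = 16) -> DataCharacteristics:
    """Extract all empirical distributions from one or more tagged BAMs.

    Gene-keyed statistics are computed on the estimation-gene subset where
    read-to-gene assignment is unambiguous; quality profiles are pooled over
    all primary reads.  Raises if no estimation gene carries data.
    """
    est = select_estimation_genes(ann)
    est_by_contig: dict[str, list] = defaultdict(list)
    for gid in est:
        g = ann.gene(gid)
        est_by_contig[g.contig].append(g)

    umi_lengths: list[int] = []
    internal_lengths: list[int] = []
    reads_per_umi_key: Counter = Counter()          # (barcode, gene, UMI) -> pairs
    pair_roles_per_gene: Counter = Counter()        # (gene, role) -> pairs
    umis_per_gene_cell: defaultdict = defaultdict(set)  # (gene, cell) -> {UMI}
    blocks_by_gene_cell: defaultdict = defaultdict(list)
    qual_read: defaultdict = defaultdict(Counter)   # position -> Counter(phred)
    read_length_counter: Counter = Counter()
    n_pairs = 0
    n_zero_exonic = 0

    for pair in read_alignment_pairs(bams, region=region):
        n_pairs += 1
        for rec in (pair.read1, pair.read2):
            quals = rec.query_qualities
            if quals is not None:
                read_length_counter[len(quals)] += 1
                for i, q in enumerate(quals):
                    qual_read[i][int(q)] += 1
        gid = _assign_gene(pair, est_by_contig)
        if gid is None:
            continue
        gene = ann.gene(gid)
        tx = gene.transcripts[0]
        role = classify_pair(pair)
        length = exonic_fragment_length(pair, tx)
        if length >= 1:
            (umi_lengths if role == "umi-containing" else internal_lengths
             ).append(length)
        else:
            n_zero_exonic += 1
        pair_roles_per_gene[(gid, role)] += 1
        if role == "umi-containing":
            reads_per_umi_key[(pair.cell_barcode, gid, pair.umi)] += 1
            umis_per_gene_cell[(gid, pair.cell_barcode)].add(pair.umi)
        blocks_by_gene_cell[(gid, pair.cell_barcode)].extend(pair.aligned_blocks())

    if n_zero_exonic:
        logger.info("dropped %d pairs with zero exonic overlap", n_zero_exonic)
    if not umi_lengths and not internal_lengths:
        raise ValueError(
            "no read pairs map to estimation genes; characterization is "
            "impossible for this input — use the packaged default "
            "characteristics instead"
        )

    # per-gene internal:UMI ratio; genes with zero UMI-containing pairs dropped
    ratios = []
    genes_seen = {g for g, _ in pair_roles_per_gene}
    n_ratio_dropped = 0
    for gid in sorted(genes_seen):
        n_umi = pair_roles_per_gene[(gid, "umi-containing")]
        n_int = pair_roles_per_gene[(gid, "internal")]
        if n_umi == 0:
            n_ratio_dropped += 1
            continue
        ratios.append(n_int / n_umi)
    if n_ratio_dropped:
        logger.info("dropped %d genes with zero UMI-containing pairs from "
                    "the internal:UMI ratio distribution", n_ratio_dropped)

    umis_per_gene = [len(s) for s in umis_per_gene_cell.values()]
    unspliced = list(
        unspliced_fraction_per_gene_cell(blocks_by_gene_cell, ann).values()
    )

    # quality profile length = modal read length; shorter reads contributed
    # to their positions only
    profile_len = read_length_counter.most_common(1)[0][0]
    qual_profile = []
    for i in range(profile_len):
        counts = qual_read[i]
        support = sorted(counts)
        qual_profile.append(
            EmpiricalDistribution(support, [counts[v] for v in support])
        )
    barcode_profile = qual_profile[:min(barcode_profile_length, profile_len)]

    def dist(samples, fallback=None):
        if samples:
            return EmpiricalDistribution.from_samples(samples)
        return EmpiricalDistribution([fallback], [1.0])

    chars = DataCharacteristics(
        umi_fragment_length=dist(umi_lengths, fallback=1),
        internal_fragment_length=dist(internal_lengths, fallback=1),
        reads_per_umi=dist(list(reads_per_umi_key.values()), fallback=1),
        internal_to_umi_ratio=dist(ratios, fallback=0.0),
        unspliced_fraction=dist(unspliced, fallback=0.0),
        umis_per_gene=dist(umis_per_gene, fallback=0),
        quality_by_position_read=qual_profile,
        quality_by_position_barcode=barcode_profile,
        metadata={
            "n_pairs": n_pairs,
            "n_estimation_genes": len(est),
            "read_length": profile_len,
        },
    )
    chars.validate()
    return chars
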