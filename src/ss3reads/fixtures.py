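"""Self-contained synthetic fixtures: toy genome/annotation, toy tagged BAM,
and parametric default characteristics.

Everything needed to exercise the full pipeline is fabricated from a seed —
no downloads, no shipped data.  The fixture laws are simple parametric
stand-ins (discretized log-normal fragment lengths, geometric reads per
UMI, truncated-normal positional qualities); they emulate the shapes seen
in real tagged Smart-seq3 data, not any particular dataset.

Every planted structure (canonical-splice motif positions, per-pair
fragment lengths, UMI multiplicities, per-gene-cell coverage) is recorded
in a truth ledger so the characterization path can be validated against
known inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam
from scipy import stats

from .characterize import DataCharacteristics, EmpiricalDistribution
from .formats_io import (
    Exon,
    Gene,
    GeneAnnotation,
    GenomeSequence,
    Transcript,
    write_annotation,
)


@dataclass
class FixtureSpec:
    """Parameters of the fabricated test world."""

    n_estimation_genes: int = 6      # single-transcript, non-overlapping
    n_multi_genes: int = 4           # 3 transcripts each, for ground truth
    n_cells: int = 8
    exon_len: int = 3000             # estimation-gene exon length
    multi_exon_len: int = 500        # exon length in multi-transcript genes
    intron_len: int = 400
    read_len: int = 100
    # fragment lengths ~ discretized log-normal
    umi_frag_log_mean: float = float(np.log(350))
    umi_frag_log_sd: float = 0.35
    internal_frag_log_mean: float = float(np.log(280))
    internal_frag_log_sd: float = 0.40
    reads_per_umi_p: float = 0.5     # geometric success prob, support >= 1
    umis_per_gene_mean: float = 12.0
    internal_ratio_log_mean: float = 0.0   # ln of per-gene internal:UMI ratio
    internal_ratio_log_sd: float = 0.4
    unspliced_zero_mass: float = 0.7
    planted_exon_len: int = 80       # novel-exon length plantable in introns

    @property
    def umi_frag_mean(self) -> float:
        return float(np.exp(self.umi_frag_log_mean + self.umi_frag_log_sd**2 / 2))

    @property
    def umi_frag_sd(self) -> float:
        v = (np.exp(self.umi_frag_log_sd**2) - 1) * self.umi_frag_mean**2
        return float(np.sqrt(v))

    @property
    def reads_per_umi_mean(self) -> float:
        return 1.0 / self.reads_per_umi_p

    @property
    def reads_per_umi_sd(self) -> float:
        p = self.reads_per_umi_p
        return float(np.sqrt((1 - p) / p**2))


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _plant(seq: list[str], pos: int, motif: str) -> None:
    seq[pos:pos + len(motif)] = list(motif)


# ---------------------------------------------------------------------------
# Toy reference
# ---------------------------------------------------------------------------

def make_toy_reference(spec: FixtureSpec, seed: int = 0,
                       out_dir: Optional[str | Path] = None,
                       ) -> tuple[GenomeSequence, GeneAnnotation, dict]:
    """Fabricate a toy genome + annotation.

    Layout per contig ``chr1``/``chr2``: single-exon estimation genes, one
    two-exon single-transcript gene (an intron for unspliced-fraction
    estimation), several three-transcript genes with introns carrying
    planted AG..GT motifs (so novel-exon injection has known ground truth),
    plus decoys that must fail the estimation filter: a two-transcript
    gene, an overlapping gene pair, and a gene on ``chrM``.

    Returns (genome, annotation, ledger); the ledger records planted motif
    positions per gene.  With ``out_dir`` the FASTA/GTF are also written.
    """
    rng = np.random.default_rng(seed)
    gap = 500
    genes: list[Gene] = []
    contigs: dict[str, str] = {}
    ledger: dict = {"planted_exons": {}, "estimation_gene_ids": [],
                    "intron_gene_id": None, "multi_gene_ids": []}

    def build_contig(name: str, builders) -> None:
        seq: list[str] = []
        cursor = 0
        for build in builders:
            cursor = len(seq) + gap
            seq.extend(_random_seq(gap, rng))
            cursor = build(name, cursor, seq)
        seq.extend(_random_seq(gap, rng))
        contigs[name] = "".join(seq)

    gene_counter = [0]

    def single_exon_gene(strand="+"):
        def build(contig, start, seq):
            gid = f"EST{gene_counter[0]}"
            gene_counter[0] += 1
            seq.extend(_random_seq(spec.exon_len, rng))
            end = start + spec.exon_len
            genes.append(Gene(gid, contig, strand,
                              [Transcript(gid + "-t1", [Exon(start, end)])]))
            ledger["estimation_gene_ids"].append(gid)
            return end
        return build

    def two_exon_gene():
        def build(contig, start, seq):
            gid = "INTRONIC0"
            e1 = spec.exon_len // 2
            seq.extend(_random_seq(e1, rng))
            intron = list(_random_seq(spec.intron_len, rng))
            _plant(intron, 0, "GT")
            _plant(intron, spec.intron_len - 2, "AG")
            seq.extend(intron)
            seq.extend(_random_seq(e1, rng))
            exons = [Exon(start, start + e1),
                     Exon(start + e1 + spec.intron_len,
                          start + 2 * e1 + spec.intron_len)]
            genes.append(Gene(gid, contig, "+", [Transcript(gid + "-t1", exons)]))
            ledger["estimation_gene_ids"].append(gid)
            ledger["intron_gene_id"] = gid
            return exons[-1].end
        return build

    def multi_transcript_gene(idx: int, strand: str):
        def build(contig, start, seq):
            gid = f"MULTI{idx}"
            exon_len, n_exons = spec.multi_exon_len, 4
            exon_starts, planted = [], []
            pos = start
            for i in range(n_exons):
                exon_starts.append(pos)
                seq.extend(_random_seq(exon_len, rng))
                pos += exon_len
                if i < n_exons - 1:
                    intron = list(_random_seq(spec.intron_len, rng))
                    # existing splice sites, canonical on the sense strand
                    if strand == "+":
                        _plant(intron, 0, "GT")
                        _plant(intron, spec.intron_len - 2, "AG")
                    else:
                        _plant(intron, 0, "CT")
                        _plant(intron, spec.intron_len - 2, "AC")
                    # plant a canonical novel-exon site mid-intron, on the
                    # sense strand of this gene's orientation
                    s = spec.intron_len // 2 - spec.planted_exon_len // 2
                    if strand == "+":
                        _plant(intron, s - 2, "AG")
                        _plant(intron, s + spec.planted_exon_len, "GT")
                    else:
                        _plant(intron, s - 2, "AC")
                        _plant(intron, s + spec.planted_exon_len, "CT")
                    planted.append((pos + s, pos + s + spec.planted_exon_len))
                    seq.extend(intron)
                    pos += spec.intron_len
            exons = [Exon(s, s + exon_len) for s in exon_starts]
            chains = [[exons[0], exons[1], exons[3]],
                      [exons[0], exons[2], exons[3]],
                      [exons[0], exons[1], exons[2], exons[3]]]
            txs = [Transcript(f"{gid}-t{i+1}", list(ch))
                   for i, ch in enumerate(chains)]
            genes.append(Gene(gid, contig, strand, txs))
            ledger["planted_exons"][gid] = planted
            ledger["multi_gene_ids"].append(gid)
            return pos
        return build

    def decoy_two_transcript():
        def build(contig, start, seq):
            gid = "DECOY2T"
            seq.extend(_random_seq(600, rng))
            exons = [Exon(start, start + 600)]
            txs = [Transcript(gid + "-t1", list(exons)),
                   Transcript(gid + "-t2", [Exon(start, start + 300)])]
            genes.append(Gene(gid, contig, "+", txs))
            return start + 600
        return build

    def decoy_overlapping_pair():
        def build(contig, start, seq):
            seq.extend(_random_seq(900, rng))
            genes.append(Gene("DECOYOVL_A", contig, "+",
                              [Transcript("DECOYOVL_A-t1",
                                          [Exon(start, start + 500)])]))
            genes.append(Gene("DECOYOVL_B", contig, "-",
                              [Transcript("DECOYOVL_B-t1",
                                          [Exon(start + 400, start + 900)])]))
            return start + 900
        return build

    half = spec.n_estimation_genes // 2
    chr1 = ([single_exon_gene() for _ in range(half)] + [two_exon_gene()]
            + [multi_transcript_gene(i, "+" if i % 2 == 0 else "-")
               for i in range(spec.n_multi_genes)])
    chr2 = ([single_exon_gene("-" if i % 2 else "+")
             for i in range(spec.n_estimation_genes - half)]
            + [decoy_two_transcript(), decoy_overlapping_pair()])
    build_contig("chr1", chr1)
    build_contig("chr2", chr2)

    # decoy contig outside chromosomes 1-22/X/Y
    m_seq = _random_seq(800, rng)
    contigs["chrM"] = m_seq
    genes.append(Gene("DECOYM", "chrM", "+",
                      [Transcript("DECOYM-t1", [Exon(100, 700)])]))

    genome = GenomeSequence(contigs)
    ann = GeneAnnotation(genes)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(out / "genome.fa")
        write_annotation(ann, out / "annotation.gtf")
    return genome, ann, ledger


# ---------------------------------------------------------------------------
# Toy tagged BAM
# ---------------------------------------------------------------------------

def _draw_read_qualities(rng: np.random.Generator, n_bases: int,
                         read_len: int) -> list[int]:
    """One read's Phred string: truncated normal with a mean that decays
    along the read (the familiar quality drop toward the 3' end)."""
    pos = np.arange(n_bases)
    means = 37.0 - 6.0 * (pos / max(read_len - 1, 1)) ** 2
    q = np.clip(np.rint(rng.normal(means, 2.0)), 2, 40)
    return q.astype(int).tolist()


def make_toy_bam(genome: GenomeSequence, ann: GeneAnnotation,
                 spec: FixtureSpec, path: str | Path, seed: int = 0) -> dict:
    """Write a coordinate-sorted, BC/UB-tagged toy BAM plus a truth ledger.

    UMI-containing pairs on estimation genes have genomic spans drawn from
    the fixture spec's fragment-length law (fully inside one exon, so exonic length
    equals the span), duplicated per a geometric reads-per-UMI law; internal
    pairs (no UB tag) follow a per-gene internal:UMI ratio law.  The
    two-exon gene additionally receives fully-intronic pairs so the
    unspliced fraction is non-trivial.  The ledger records every sampled
    quantity for parameter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    est_genes = [g for g in ann.genes
                 if g.id in {gid for gid in _estimation_ids(ann)}]
    barcodes = [f"BC{j:02d}" for j in range(spec.n_cells)]
    ledger: dict = {
        "umi_fragment_lengths": [], "internal_fragment_lengths": [],
        "reads_per_umi": [], "ratio_per_gene": {},
        "umis_per_gene_cell": {}, "intronic_fraction": {},
        "n_pairs": 0, "n_missing_bc": 0,
    }

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)}
               for name, seq in genome.contigs.items()],
    }
    records = []
    serial = [0]

    def add_pair(gene: Gene, start: int, length: int, barcode: Optional[str],
                 umi: Optional[str], n_dup: int = 1) -> None:
        contig = gene.contig
        for d in range(n_dup):
            name = f"pair{serial[0]}"
            serial[0] += 1
            r1_len = min(spec.read_len, length)
            r2_len = min(spec.read_len, length)
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = genome.fetch(contig, start, start + r1_len)
            a.reference_id = list(genome.contigs).index(contig)
            a.reference_start = start
            a.cigarstring = f"{r1_len}M"
            a.flag = 0x1 | 0x2 | 0x40 | 0x20
            a.query_qualities = _draw_read_qualities(rng, r1_len, spec.read_len)
            b = pysam.AlignedSegment()
            b.query_name = name
            b2_start = start + length - r2_len
            b.query_sequence = genome.fetch(contig, b2_start, b2_start + r2_len)
            b.reference_id = a.reference_id
            b.reference_start = b2_start
            b.cigarstring = f"{r2_len}M"
            b.flag = 0x1 | 0x2 | 0x80 | 0x10
            b.query_qualities = a.query_qualities
            a.next_reference_id = b.reference_id
            a.next_reference_start = b.reference_start
            b.next_reference_id = a.reference_id
            b.next_reference_start = a.reference_start
            a.template_length = length
            b.template_length = -length
            for rec in (a, b):
                if barcode is not None:
                    rec.set_tag("BC", barcode)
                    if umi:
                        rec.set_tag("UB", umi)
            records.extend([a, b])
            ledger["n_pairs"] += 1

    def sample_len(log_mean: float, log_sd: float) -> int:
        return max(30, int(np.rint(rng.lognormal(log_mean, log_sd))))

    for gene in est_genes:
        tx = gene.transcripts[0]
        host_exon = max(tx.exons, key=len)
        n_umi_pairs_gene = 0
        for bc in barcodes:
            n_umis = max(1, int(rng.poisson(spec.umis_per_gene_mean)))
            ledger["umis_per_gene_cell"][(gene.id, bc)] = n_umis
            for u in range(n_umis):
                umi = f"{_random_umi(rng)}"
                L = min(sample_len(spec.umi_frag_log_mean,
                                   spec.umi_frag_log_sd), len(host_exon))
                start = host_exon.start + int(
                    rng.integers(len(host_exon) - L + 1))
                n_dup = 1 + int(rng.geometric(spec.reads_per_umi_p) - 1)
                add_pair(gene, start, L, bc, umi, n_dup=n_dup)
                ledger["umi_fragment_lengths"].extend([L] * n_dup)
                ledger["reads_per_umi"].append(n_dup)
                n_umi_pairs_gene += n_dup
        # internal pairs for this gene
        ratio = float(rng.lognormal(spec.internal_ratio_log_mean,
                                    spec.internal_ratio_log_sd))
        n_internal = int(np.rint(ratio * n_umi_pairs_gene))
        for _ in range(n_internal):
            bc = barcodes[int(rng.integers(len(barcodes)))]
            L = min(sample_len(spec.internal_frag_log_mean,
                               spec.internal_frag_log_sd), len(host_exon))
            start = host_exon.start + int(rng.integers(len(host_exon) - L + 1))
            add_pair(gene, start, L, bc, None)
            ledger["internal_fragment_lengths"].append(L)
        ledger["ratio_per_gene"][gene.id] = n_internal / n_umi_pairs_gene

    # fully intronic pairs on the two-exon gene -> non-zero unspliced fractions
    intron_gene = next(g for g in est_genes if len(g.transcripts[0].exons) == 2)
    itx = intron_gene.transcripts[0]
    istart, iend = itx.introns()[0]
    for bc in barcodes[: spec.n_cells // 2]:
        L = min(150, iend - istart - 4)
        start = istart + 2
        add_pair(intron_gene, start, L, bc, None)

    # a pair with no BC tag: must be skipped, not fatal
    est0 = est_genes[0]
    add_pair(est0, est0.transcripts[0].start + 10, 120, None, None)
    ledger["n_missing_bc"] = 1

    records.sort(key=lambda r: (r.reference_id, r.reference_start))
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for rec in records:
            bam.write(rec)
    pysam.index(path)
    return ledger


def _estimation_ids(ann: GeneAnnotation) -> set[str]:
    from .characterize import select_estimation_genes

    return select_estimation_genes(ann)


def _random_umi(rng: np.random.Generator, n: int = 8) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# Default characteristics
# ---------------------------------------------------------------------------

def make_default_characteristics(spec: Optional[FixtureSpec] = None,
                                 read_len: int = 150) -> DataCharacteristics:
    """A packaged parametric characteristics bundle.

    Fragment lengths are discretized log-normals, reads per UMI geometric,
    the internal:UMI ratio a discretized log-normal, the unspliced fraction
    a zero-inflated grid on [0, 0.5], UMIs per gene negative-binomial, and
    positional qualities truncated normals whose mean decays along the
    read.  Loads and validates with no external data.
    """
    spec = spec or FixtureSpec()

    def lognormal_dist(log_mean, log_sd, lo=30, hi=1500):
        support = np.arange(lo, hi + 1)
        w = stats.lognorm.pdf(support, s=log_sd, scale=np.exp(log_mean))
        return EmpiricalDistribution(support, w)

    support_r = np.arange(1, 31)
    reads_per_umi = EmpiricalDistribution(
        support_r, stats.geom.pmf(support_r, spec.reads_per_umi_p))

    ratio_support = np.round(np.linspace(0.05, 4.0, 80), 3)
    ratio_w = stats.lognorm.pdf(ratio_support,
                                s=spec.internal_ratio_log_sd,
                                scale=np.exp(spec.internal_ratio_log_mean))
    internal_ratio = EmpiricalDistribution(ratio_support, ratio_w)

    unspl_support = np.concatenate([[0.0], np.round(np.linspace(0.02, 0.5, 25), 3)])
    unspl_w = np.concatenate([
        [spec.unspliced_zero_mass],
        np.full(25, (1 - spec.unspliced_zero_mass) / 25),
    ])
    unspliced = EmpiricalDistribution(unspl_support, unspl_w)

    umi_support = np.arange(1, 101)
    n_param, p_param = 4.0, 4.0 / (4.0 + spec.umis_per_gene_mean)
    umis_per_gene = EmpiricalDistribution(
        umi_support, stats.nbinom.pmf(umi_support - 1, n_param, p_param))

    q_support = np.arange(2, 41)
    profile = []
    for i in range(read_len):
        mean = 37.0 - 6.0 * (i / max(read_len - 1, 1)) ** 2
        w = stats.norm.pdf(q_support, loc=mean, scale=2.0)
        profile.append(EmpiricalDistribution(q_support, w))

    chars = DataCharacteristics(
        umi_fragment_length=lognormal_dist(spec.umi_frag_log_mean,
                                           spec.umi_frag_log_sd),
        internal_fragment_length=lognormal_dist(spec.internal_frag_log_mean,
                                                spec.internal_frag_log_sd),
        reads_per_umi=reads_per_umi,
        internal_to_umi_ratio=internal_ratio,
        unspliced_fraction=unspliced,
        umis_per_gene=umis_per_gene,
        quality_by_position_read=profile,
        quality_by_position_barcode=profile[:16],
        metadata={"source": "parametric-default", "read_length": read_len},
    )
    chars.validate()
    return chars
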