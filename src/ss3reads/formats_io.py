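"""Readers and writers for the standard formats the simulator touches.

Internal coordinates are 0-based half-open everywhere; GTF input/output
converts at the boundary (GTF is 1-based inclusive).  The genome is held as
plain uppercase strings restricted to {A, C, G, T, N}; annotations are a
gene -> transcript -> exon hierarchy.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_ALPHABET = set("ACGTN")

CHARACTERISTICS_SCHEMA_VERSION = 1


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

class GenomeSequence:
    """In-memory genome: contig name -> uppercase nucleotide string.

    Subsequences are fetched with 0-based half-open coordinates, so
    ``fetch(c, s, e)`` has length ``e - s``.
    """

    def __init__(self, contigs: dict[str, str]):
        clean = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_ALPHABET
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )
            clean[name] = seq
        self.contigs = clean

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for contig "
                f"{contig!r} of length {len(seq)}"
            )
        return seq[start:end]

    def contig_length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Exon:
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"exon interval [{self.start}, {self.end}) is empty")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    id: str
    exons: list[Exon]  # sorted by genomic coordinate, non-overlapping

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.id} has zero exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.id} has overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def junctions(self) -> list[tuple[int, int]]:
        """(donor_end, acceptor_start) genomic pairs between consecutive exons."""
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]

    def introns(self) -> list[tuple[int, int]]:
        return self.junctions()

    def exon_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exons)


@dataclass
class Gene:
    id: str
    contig: str
    strand: str  # "+" or "-"
    transcripts: list[Transcript]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: invalid strand {self.strand!r}")

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged union of all annotated exon intervals of the gene."""
        ivals = sorted((e.start, e.end) for t in self.transcripts for e in t.exons)
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def distinct_exons(self) -> list[Exon]:
        seen = sorted({(e.start, e.end) for t in self.transcripts for e in t.exons})
        return [Exon(s, e) for s, e in seen]


@dataclass
class GeneAnnotation:
    genes: list[Gene]

    def __post_init__(self):
        self._by_gene = {g.id: g for g in self.genes}
        self._by_transcript: dict[str, tuple[Gene, Transcript]] = {}
        for g in self.genes:
            for t in g.transcripts:
                if t.id in self._by_transcript:
                    raise ValueError(f"duplicate transcript id {t.id}")
                self._by_transcript[t.id] = (g, t)

    def gene(self, gene_id: str) -> Gene:
        return self._by_gene[gene_id]

    def transcript(self, transcript_id: str) -> Transcript:
        try:
            return self._by_transcript[transcript_id][1]
        except KeyError:
            raise KeyError(f"unknown transcript id {transcript_id!r}") from None

    def gene_of_transcript(self, transcript_id: str) -> Gene:
        try:
            return self._by_transcript[transcript_id][0]
        except KeyError:
            raise KeyError(f"unknown transcript id {transcript_id!r}") from None

    def __len__(self) -> int:
        return len(self.genes)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read an Ensembl-dialect GTF into a GeneAnnotation.

    Only ``exon`` features are used; gene/transcript structure is derived
    from their ``gene_id``/``transcript_id`` attributes.  GTF 1-based
    inclusive coordinates are converted to 0-based half-open.
    """
    tx_exons: dict[str, list[Exon]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, contig, strand)
    gene_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            contig, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise ValueError(
                    f"{path}: line {lineno}: malformed attribute string "
                    f"(need gene_id and transcript_id): {attrs.strip()!r}"
                )
            gid, tid = attr["gene_id"], attr["transcript_id"]
            exon = Exon(int(start) - 1, int(end))  # 1-based incl -> 0-based half-open
            if tid not in tx_meta:
                tx_meta[tid] = (gid, contig, strand)
                if gid not in gene_order:
                    gene_order.append(gid)
            tx_exons.setdefault(tid, []).append(exon)

    genes: dict[str, Gene] = {}
    for tid, exons in tx_exons.items():
        gid, contig, strand = tx_meta[tid]
        tx = Transcript(tid, exons)
        if gid not in genes:
            genes[gid] = Gene(gid, contig, strand, [])
        genes[gid].transcripts.append(tx)
    return GeneAnnotation([genes[g] for g in gene_order])


def write_annotation(ann: GeneAnnotation, path: str | Path,
                     source: str = "ss3reads") -> None:
    """Write a GeneAnnotation back to Ensembl-dialect GTF (exon features)."""
    with open(path, "w") as fh:
        for g in ann.genes:
            for t in g.transcripts:
                for e in t.exons:
                    attrs = f'gene_id "{g.id}"; transcript_id "{t.id}";'
                    fh.write(
                        f"{g.contig}\t{source}\texon\t{e.start + 1}\t{e.end}"
                        f"\t.\t{g.strand}\t.\t{attrs}\n"
                    )


def fetch_transcript_sequence(ann: GeneAnnotation, genome: GenomeSequence,
                              transcript_id: str, spliced: bool = True) -> str:
    """Sequence of a transcript in 5'->3' mRNA sense.

    ``spliced=True``: concatenated exon sequences; ``spliced=False``: the
    full genomic span first-exon-start to last-exon-end (pre-mRNA, introns
    retained).  Minus-strand transcripts are reverse-complemented so the
    result always reads in transcript sense.
    """
    gene = ann.gene_of_transcript(transcript_id)
    tx = ann.transcript(transcript_id)
    if spliced:
        seq = "".join(genome.fetch(gene.contig, e.start, e.end) for e in tx.exons)
    else:
        seq = genome.fetch(gene.contig, tx.start, tx.end)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# BAM
# ---------------------------------------------------------------------------

@dataclass
class AlignedReadPair:
    """A mated primary alignment pair with zUMIs-style BC/UB tags."""

    name: str
    contig: str
    cell_barcode: str
    umi: Optional[str]          # None or "" => internal
    read1: pysam.AlignedSegment
    read2: pysam.AlignedSegment

    @property
    def is_umi_containing(self) -> bool:
        return bool(self.umi)

    @property
    def fragment_start(self) -> int:
        return min(self.read1.reference_start, self.read2.reference_start)

    @property
    def fragment_end(self) -> int:
        return max(self.read1.reference_end, self.read2.reference_end)

    def aligned_blocks(self) -> list[tuple[int, int]]:
        return list(self.read1.get_blocks()) + list(self.read2.get_blocks())


def read_alignment_pairs(paths: Sequence[str | Path] | str | Path,
                         region: Optional[str] = None,
                         ) -> Iterator[AlignedReadPair]:
    """Stream mated primary-alignment pairs from one or more BAM files.

    Secondary, supplementary and unmapped records are skipped, as are pairs
    without a BC tag (counted and logged, not fatal: real tagged BAMs
    contain unassigned reads).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    n_missing_bc = 0
    for path in paths:
        with pysam.AlignmentFile(str(path), "rb") as bam:
            it = bam.fetch(region=region) if region else bam.fetch(until_eof=True)
            pending: dict[str, pysam.AlignedSegment] = {}
            for rec in it:
                if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                        or not rec.is_paired):
                    continue
                mate = pending.pop(rec.query_name, None)
                if mate is None:
                    pending[rec.query_name] = rec
                    continue
                r1, r2 = (rec, mate) if rec.is_read1 else (mate, rec)
                if not r1.has_tag("BC"):
                    n_missing_bc += 1
                    continue
                umi = r1.get_tag("UB") if r1.has_tag("UB") else None
                yield AlignedReadPair(
                    name=r1.query_name,
                    contig=bam.get_reference_name(r1.reference_id),
                    cell_barcode=str(r1.get_tag("BC")),
                    umi=str(umi) if umi is not None else None,
                    read1=r1,
                    read2=r2,
                )
    if n_missing_bc:
        logger.info("skipped %d pairs lacking a BC tag", n_missing_bc)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def phred_to_ascii(quals: Iterable[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def write_fastq_pairs(pairs, r1_path: str | Path, r2_path: str | Path,
                      compress: bool = False) -> int:
    """Write simulated read pairs as standard paired FASTQ (Phred+33).

    Read identifiers carry the ground truth (barcode, molecule id, fragment
    role, source transcript) so alignments can be scored without auxiliary
    files.  Returns the number of pairs written.
    """
    opener = (lambda p: gzip.open(p, "wt")) if compress else (lambda p: open(p, "w"))
    n = 0
    with opener(str(r1_path)) as f1, opener(str(r2_path)) as f2:
        for pair in pairs:
            if len(pair.read1_seq) != len(pair.read1_qual) or \
               len(pair.read2_seq) != len(pair.read2_qual):
                raise ValueError(
                    f"read/quality length mismatch for read id {pair.read_id}"
                )
            q1 = phred_to_ascii(pair.read1_qual)
            q2 = phred_to_ascii(pair.read2_qual)
            f1.write(f"@{pair.read_id} 1\n{pair.read1_seq}\n+\n{q1}\n")
            f2.write(f"@{pair.read_id} 2\n{pair.read2_seq}\n+\n{q2}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, sequence, phred qualities) from a possibly gzipped FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:].rstrip("\n"), seq, [ord(c) - 33 for c in qual]


# ---------------------------------------------------------------------------
# Characteristics serialization
# ---------------------------------------------------------------------------

def save_characteristics(chars, path: str | Path) -> None:
    """Serialize a DataCharacteristics bundle to a self-describing JSON text
    document (support values + weights per distribution, schema-versioned)."""
    doc = {
        "schema_version": CHARACTERISTICS_SCHEMA_VERSION,
        "metadata": dict(chars.metadata),
        "distributions": {
            name: {"values": [float(v) for v in d.values],
                   "weights": [float(w) for w in d.weights]}
            for name, d in chars.named_distributions().items()
        },
        "quality_by_position_read": [
            {"values": [int(v) for v in d.values],
             "weights": [float(w) for w in d.weights]}
            for d in chars.quality_by_position_read
        ],
        "quality_by_position_barcode": [
            {"values": [int(v) for v in d.values],
             "weights": [float(w) for w in d.weights]}
            for d in chars.quality_by_position_barcode
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_characteristics(path: str | Path):
    """Inverse of :func:`save_characteristics`; validates schema version and
    the presence of every distribution."""
    from .characterize import DataCharacteristics, EmpiricalDistribution

    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != CHARACTERISTICS_SCHEMA_VERSION:
        raise ValueError(
            f"characteristics schema version mismatch: file has {version!r}, "
            f"expected {CHARACTERISTICS_SCHEMA_VERSION}"
        )
    dists = doc.get("distributions", {})
    for name in DataCharacteristics.DISTRIBUTION_NAMES:
        if name not in dists:
            raise ValueError(f"characteristics file is missing distribution {name!r}")

    def mk(d, integer=False):
        values = [int(v) for v in d["values"]] if integer else d["values"]
        return EmpiricalDistribution(values, d["weights"])

    return DataCharacteristics(
        umi_fragment_length=mk(dists["umi_fragment_length"]),
        internal_fragment_length=mk(dists["internal_fragment_length"]),
        reads_per_umi=mk(dists["reads_per_umi"]),
        internal_to_umi_ratio=mk(dists["internal_to_umi_ratio"]),
        unspliced_fraction=mk(dists["unspliced_fraction"]),
        umis_per_gene=mk(dists["umis_per_gene"]),
        quality_by_position_read=[
            mk(d, integer=True) for d in doc["quality_by_position_read"]
        ],
        quality_by_position_barcode=[
            mk(d, integer=True) for d in doc["quality_by_position_barcode"]
        ],
        metadata=doc.get("metadata", {}),
    )
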