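"""User-controllable simulation ground truth.

Builds the inputs the read simulator consumes: a set of truth transcripts
(annotated isoforms plus optional novel-junction / novel-exon isoforms) and
the transcript-by-cell UMI count matrix obtained by cascading a gene-level
UMI matrix through per-population PSI (percent spliced in) and unspliced
fractions.

The experimental design is ``p`` cell populations of ``c`` cells each.  PSI
and unspliced fractions are population-level quantities: splicing is a cell
type-specific process, so all cells of a population share one PSI vector
per gene and one unspliced fraction per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .characterize import DataCharacteristics
from .formats_io import (
    Exon,
    Gene,
    GeneAnnotation,
    GenomeSequence,
    Transcript,
    fetch_transcript_sequence,
    reverse_complement,
)

logger = logging.getLogger(__name__)

UNSPLICED_SUFFIX = "-unspliced"


@dataclass
class PopulationDesign:
    """Experimental setup: p populations x c cells, with counts of genes
    whose PSI / unspliced fraction differ between populations."""

    p: int = 2
    c: int = 100
    n_diff_splicing: int = 0
    n_diff_unspliced: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.p < 1 or self.c < 1:
            raise ValueError("need at least one population and one cell")

    @property
    def n_cells(self) -> int:
        return self.p * self.c

    def population_of_cell(self, j: int) -> int:
        return j // self.c

    def cell_labels(self) -> list[str]:
        return [f"pop{q}_cell{i}" for q in range(self.p) for i in range(self.c)]


@dataclass
class TruthTranscript:
    """A transcript selected or constructed for simulation."""

    id: str
    gene_id: str
    sequence: str               # spliced, 5'->3' mRNA sense
    novelty: str                # "annotated" | "novel-junction" | "novel-exon"
    exons: tuple[tuple[int, int], ...]
    contig: str = ""
    strand: str = "+"


@dataclass
class GroundTruth:
    """Everything the simulator needs: transcripts and per-cell UMI targets."""

    transcripts: list[TruthTranscript]
    counts: pd.DataFrame        # rows: transcript ids (incl. unspliced), cols: cells
    gene_of: dict[str, str]     # transcript id (incl. unspliced rows) -> gene id
    sequences: dict[str, str]   # transcript id -> sequence to fragment
    psi: Optional[pd.DataFrame] = None
    unspliced: Optional[pd.DataFrame] = None
    design: Optional[PopulationDesign] = None


# ---------------------------------------------------------------------------
# Transcript selection
# ---------------------------------------------------------------------------

def get_transcripts(ann: GeneAnnotation, genome: GenomeSequence,
                    k: Optional[int] = None,
                    gene_list: Optional[Sequence[str]] = None,
                    n: int = 2, seed: int = 0) -> list[TruthTranscript]:
    """Select k random genes (or a user gene list), n annotated transcripts each.

    Genes with fewer than ``n`` transcripts are ineligible: with ``k`` given
    a shortage is a hard error, with ``gene_list`` ineligible genes are
    dropped and logged.
    """
    if (k is None) == (gene_list is None):
        raise ValueError("provide exactly one of k or gene_list")
    rng = np.random.default_rng(seed)
    if gene_list is not None:
        candidates, dropped = [], []
        for gid in gene_list:
            if len(ann.gene(gid).transcripts) >= n:
                candidates.append(gid)
            else:
                dropped.append(gid)
        if dropped:
            logger.info("dropped %d genes with fewer than %d transcripts: %s",
                        len(dropped), n, ", ".join(dropped[:10]))
        chosen = candidates
    else:
        eligible = [g.id for g in ann.genes if len(g.transcripts) >= n]
        if len(eligible) < k:
            raise ValueError(
                f"only {len(eligible)} genes have >= {n} transcripts; "
                f"cannot select k={k}"
            )
        chosen = sorted(rng.choice(eligible, size=k, replace=False).tolist())

    out = []
    for gid in chosen:
        gene = ann.gene(gid)
        tids = [t.id for t in gene.transcripts]
        picked = rng.choice(tids, size=n, replace=False)
        for tid in sorted(picked):
            tx = ann.transcript(tid)
            out.append(TruthTranscript(
                id=tid, gene_id=gid,
                sequence=fetch_transcript_sequence(ann, genome, tid, spliced=True),
                novelty="annotated",
                exons=tx.exon_chain(),
                contig=gene.contig, strand=gene.strand,
            ))
    return out


# ---------------------------------------------------------------------------
# Novel splicing events
# ---------------------------------------------------------------------------

def _assemble_sequence(gene: Gene, genome: GenomeSequence,
                       chain: Sequence[tuple[int, int]]) -> str:
    seq = "".join(genome.fetch(gene.contig, s, e) for s, e in chain)
    return reverse_complement(seq) if gene.strand == "-" else seq


def add_new_junction(ann: GeneAnnotation, genome: GenomeSequence,
                     gene_id: str, seed: int = 0,
                     new_id: Optional[str] = None) -> TruthTranscript:
    """Create a novel isoform by joining two existing exons of the gene with
    a splice junction no annotated transcript uses.

    The novel chain is built by editing a randomly chosen annotated backbone:
    exons upstream of the donor exon, the two joined exons, then exons
    downstream of the acceptor exon.
    """
    gene = ann.gene(gene_id)
    exons = gene.distinct_exons()
    annotated_junctions = {
        j for t in gene.transcripts for j in t.junctions()
    }
    annotated_chains = {t.exon_chain() for t in gene.transcripts}
    candidates = [
        (a, b)
        for i, a in enumerate(exons)
        for b in exons[i + 1:]
        if a.end < b.start and (a.end, b.start) not in annotated_junctions
    ]
    if not candidates:
        raise ValueError(
            f"no novel junction possible for gene {gene_id}: every "
            f"non-overlapping exon pair is already joined by an annotated "
            f"junction"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    backbone = gene.transcripts[int(rng.integers(len(gene.transcripts)))]
    for ci in order:
        a, b = candidates[int(ci)]
        chain = (
            [(e.start, e.end) for e in backbone.exons if e.end <= a.start]
            + [(a.start, a.end), (b.start, b.end)]
            + [(e.start, e.end) for e in backbone.exons if e.start >= b.end]
        )
        chain_t = tuple(chain)
        if chain_t not in annotated_chains:
            tid = new_id or f"{gene_id}-novel-junction"
            return TruthTranscript(
                id=tid, gene_id=gene_id,
                sequence=_assemble_sequence(gene, genome, chain),
                novelty="novel-junction",
                exons=chain_t, contig=gene.contig, strand=gene.strand,
            )
    raise ValueError(
        f"no novel junction possible for gene {gene_id}: all candidate "
        f"chains coincide with annotated transcripts"
    )


def _canonical_exon_positions(intron_seq: str, length: int,
                              strand: str) -> list[int]:
    """Offsets s within the intron where an exon [s, s+length) has canonical
    flanks on the sense strand.

    Plus strand: ``AG`` acceptor immediately 5' of the exon, ``GT`` donor
    immediately 3'.  Minus strand: the sense strand is the reverse
    complement, so the genomic motifs are ``CT`` downstream and ``AC``
    upstream.
    """
    up, down = ("AG", "GT") if strand == "+" else ("AC", "CT")
    hits = []
    for s in range(2, len(intron_seq) - length - 1):
        if intron_seq[s - 2:s] == up and \
           intron_seq[s + length:s + length + 2] == down:
            hits.append(s)
    return hits


def add_new_exon(ann: GeneAnnotation, genome: GenomeSequence, gene_id: str,
                 canonical: bool = True,
                 exon_length_range: tuple[int, int] = (50, 150),
                 seed: int = 0,
                 new_id: Optional[str] = None) -> TruthTranscript:
    """Insert a novel exon strictly inside an intron of an annotated backbone.

    The insertion creates two new junctions.  With ``canonical=True`` the
    exon is placed so that, on the transcript's sense strand, an ``AG``
    acceptor immediately precedes it and a ``GT`` donor immediately follows
    it; the pre-existing flanking splice sites are untouched (a 2 nt margin
    is kept at both intron ends).  With ``canonical=False`` placement is
    uniform over admissible offsets.
    """
    gene = ann.gene(gene_id)
    rng = np.random.default_rng(seed)
    backbones = [t for t in gene.transcripts if len(t.exons) >= 2]
    if not backbones:
        raise ValueError(f"gene {gene_id} has no intron-containing transcript")
    backbone = backbones[int(rng.integers(len(backbones)))]

    lo, hi = exon_length_range
    introns = backbone.introns()
    searched = []
    options: list[tuple[int, int, int]] = []  # (intron_idx, offset, length)
    for idx, (istart, iend) in enumerate(introns):
        intron_seq = genome.fetch(gene.contig, istart, iend)
        searched.append(f"[{istart},{iend})")
        for length in range(lo, hi + 1):
            if length + 4 > len(intron_seq):
                continue
            if canonical:
                offsets = _canonical_exon_positions(intron_seq, length,
                                                    gene.strand)
            else:
                offsets = list(range(2, len(intron_seq) - length - 1))
            options.extend((idx, s, length) for s in offsets)
    if not options:
        if canonical:
            raise ValueError(
                f"no canonical AG/GT placement for a novel exon of length "
                f"{lo}-{hi} in gene {gene_id}; introns searched: "
                f"{', '.join(searched)}"
            )
        raise ValueError(
            f"no intron of gene {gene_id} can host an exon of length {lo}-{hi}"
        )
    idx, s, length = options[int(rng.integers(len(options)))]
    istart, _ = introns[idx]
    new_exon = (istart + s, istart + s + length)
    chain = sorted([(e.start, e.end) for e in backbone.exons] + [new_exon])
    tid = new_id or f"{gene_id}-novel-exon"
    return TruthTranscript(
        id=tid, gene_id=gene_id,
        sequence=_assemble_sequence(gene, genome, chain),
        novelty="novel-exon",
        exons=tuple(chain), contig=gene.contig, strand=gene.strand,
    )


def verify_canonical_junctions(genome: GenomeSequence,
                               tx: TruthTranscript) -> bool:
    """Independent check that every intron of ``tx`` has a GT donor and AG
    acceptor on the sense strand (reads the genome directly)."""
    for (dend, astart) in zip((e for _, e in tx.exons[:-1]),
                              (s for s, _ in tx.exons[1:])):
        donor = genome.fetch(tx.contig, dend, dend + 2)
        acceptor = genome.fetch(tx.contig, astart - 2, astart)
        if tx.strand == "+":
            if donor != "GT" or acceptor != "AG":
                return False
        else:
            # sense strand is the reverse complement: genomic CT ... AC
            if acceptor != "AC" or donor != "CT":
                return False
    return True


# ---------------------------------------------------------------------------
# Matrix cascade
# ---------------------------------------------------------------------------

def _round_half_even(x) -> np.ndarray:
    return np.rint(x).astype(int)


def sample_cell_size_factors(n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Per-cell size factors, log2-uniform on [2^-2, 2^2]: halving and
    doubling of a cell's RNA content are equally likely."""
    return 2.0 ** rng.uniform(-2.0, 2.0, size=n_cells)


def generate_gene_umi_matrix(chars: DataCharacteristics,
                             design: PopulationDesign,
                             genes: Sequence[str],
                             n_min: int = 1,
                             seed: int = 0) -> pd.DataFrame:
    """Gene-by-cell UMI count matrix.

    One base count per gene per population is drawn from the empirical
    UMIs-per-gene distribution conditioned on >= ``n_min`` (equivalent to
    redrawing until the minimum is met); each cell scales its population's
    base counts by a size factor s in [2^-2, 2^2] (round-half-even), with
    the ``n_min`` floor re-applied after scaling.
    """
    if chars.umis_per_gene.max() < n_min:
        raise ValueError(
            f"UMIs-per-gene distribution maximum "
            f"{chars.umis_per_gene.max():g} is below the required minimum "
            f"count {n_min}"
        )
    rng = np.random.default_rng(seed)
    law = chars.umis_per_gene.restricted(n_min)
    base = np.asarray(
        [law.sample(rng, size=len(genes)) for _ in range(design.p)]
    ).T  # genes x populations
    s = sample_cell_size_factors(design.n_cells, rng)
    cols = design.cell_labels()
    counts = np.empty((len(genes), design.n_cells), dtype=int)
    for j in range(design.n_cells):
        q = design.population_of_cell(j)
        counts[:, j] = np.maximum(n_min, _round_half_even(base[:, q] * s[j]))
    df = pd.DataFrame(counts, index=list(genes), columns=cols)
    df.attrs["size_factors"] = s
    df.attrs["design"] = design
    return df


def generate_psi_matrix(transcripts_by_gene: dict[str, Sequence[str]],
                        design: PopulationDesign,
                        seed: int = 0) -> pd.DataFrame:
    """Transcript-by-population PSI matrix (percent spliced in).

    Per gene and population the total of 100% is distributed uniformly over
    the gene's transcripts (flat Dirichlet).  Fixed-splicing genes reuse a
    single draw across all populations; the ``n_diff_splicing`` genes chosen
    at random under the seed draw independently per population.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(transcripts_by_gene)
    n_diff = min(design.n_diff_splicing, len(gene_ids))
    diff_genes = set(rng.choice(gene_ids, size=n_diff, replace=False).tolist()) \
        if n_diff else set()
    rows, index = [], []
    for gid in gene_ids:
        tids = list(transcripts_by_gene[gid])
        m = len(tids)
        if gid in diff_genes:
            block = rng.dirichlet(np.ones(m), size=design.p).T * 100.0
        else:
            block = np.tile(rng.dirichlet(np.ones(m))[:, None], design.p) * 100.0
        rows.append(block)
        index.extend(tids)
    psi = pd.DataFrame(np.vstack(rows), index=index,
                       columns=[f"pop{q}" for q in range(design.p)])
    psi.attrs["diff_genes"] = sorted(diff_genes)
    return psi


def generate_unspliced_matrix(chars: Optional[DataCharacteristics],
                              genes: Sequence[str],
                              design: PopulationDesign,
                              custom_matrix: Optional[pd.DataFrame] = None,
                              seed: int = 0) -> pd.DataFrame:
    """Gene-by-population unspliced-fraction matrix in [0, 1].

    A user-supplied custom matrix (e.g. high fractions for single-nuclei
    scenarios) is validated and returned verbatim; otherwise fractions are
    sampled from the empirical distribution, one shared draw per gene for
    fixed genes and independent per-population draws for the
    ``n_diff_unspliced`` differential genes.
    """
    cols = [f"pop{q}" for q in range(design.p)]
    if custom_matrix is not None:
        m = custom_matrix
        if m.shape != (len(genes), design.p):
            raise ValueError(
                f"custom unspliced matrix has shape {m.shape}, expected "
                f"({len(genes)}, {design.p})"
            )
        vals = m.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("custom unspliced matrix values must lie in [0, 1]")
        out = pd.DataFrame(vals, index=list(genes), columns=cols)
        return out
    if chars is None:
        raise ValueError("need characteristics or a custom unspliced matrix")
    rng = np.random.default_rng(seed)
    n_diff = min(design.n_diff_unspliced, len(genes))
    diff_genes = set(
        rng.choice(list(genes), size=n_diff, replace=False).tolist()
    ) if n_diff else set()
    law = chars.unspliced_fraction
    mat = np.empty((len(genes), design.p))
    for i, gid in enumerate(genes):
        if gid in diff_genes:
            mat[i] = law.sample(rng, size=design.p)
        else:
            mat[i] = law.sample(rng)
    return pd.DataFrame(mat, index=list(genes), columns=cols)


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``shares`` with
    exact conservation (largest-remainder rule, ties by index)."""
    if total == 0 or shares.sum() == 0:
        out = np.zeros(len(shares), dtype=int)
        if total > 0 and len(shares) > 0:
            out[0] = total  # degenerate: all shares zero, give everything to the first
        return out
    exact = shares / shares.sum() * total
    floors = np.floor(exact).astype(int)
    remainder = total - floors.sum()
    order = np.argsort(-(exact - floors), kind="stable")
    floors[order[:remainder]] += 1
    return floors


def combine_truth(gene_matrix: pd.DataFrame, psi: pd.DataFrame,
                  unspliced: pd.DataFrame,
                  transcripts_by_gene: dict[str, Sequence[str]],
                  design: PopulationDesign) -> pd.DataFrame:
    """Combine gene UMI counts, PSI and unspliced fractions into the
    transcript UMI count matrix.

    For gene g in cell j (population q): unspliced UMIs
    u = round(counts[g,j] * unspliced[g,q]) go to the gene's pre-mRNA row
    ``<gene>-unspliced``; the remaining counts[g,j] - u spliced UMIs are
    apportioned over the gene's transcripts by largest-remainder rounding of
    their PSI shares.  Per-gene per-cell totals are conserved exactly.
    """
    rows: list[str] = []
    gene_rows: dict[str, list[str]] = {}
    for gid in gene_matrix.index:
        tids = list(transcripts_by_gene[gid])
        gene_rows[gid] = tids + [gid + UNSPLICED_SUFFIX]
        rows.extend(gene_rows[gid])
    out = pd.DataFrame(0, index=rows, columns=gene_matrix.columns, dtype=int)
    for j, cell in enumerate(gene_matrix.columns):
        q = design.population_of_cell(j)
        pop = f"pop{q}"
        for gid in gene_matrix.index:
            total = int(gene_matrix.at[gid, cell])
            u = int(np.rint(total * float(unspliced.at[gid, pop])))
            u = min(u, total)
            tids = list(transcripts_by_gene[gid])
            shares = psi.loc[tids, pop].to_numpy(dtype=float)
            spliced_counts = _largest_remainder(shares, total - u)
            if spliced_counts.sum() + u != total:
                raise AssertionError("conservation violated in combine_truth")
            out.loc[tids, cell] = spliced_counts
            out.at[gid + UNSPLICED_SUFFIX, cell] = u
    return out


# ---------------------------------------------------------------------------
# End-to-end builder + on-disk layout
# ---------------------------------------------------------------------------

def build_ground_truth(ann: GeneAnnotation, genome: GenomeSequence,
                       chars: DataCharacteristics,
                       design: PopulationDesign,
                       k: Optional[int] = None,
                       gene_list: Optional[Sequence[str]] = None,
                       n: int = 2,
                       n_novel_junctions: int = 0,
                       n_novel_exons: int = 0,
                       canonical: bool = True,
                       n_min: Optional[int] = None,
                       custom_unspliced: Optional[pd.DataFrame] = None,
                       seed: int = 0) -> GroundTruth:
    """Run the full cascade: transcript selection, novel-event injection,
    gene UMI matrix, PSI, unspliced fractions, and the combined transcript
    UMI matrix.

    ``n_min`` (the per-gene minimum UMI count) defaults to the number of
    transcripts per gene so every isoform can receive at least one UMI in
    expectation.
    """
    ss = np.random.SeedSequence(seed)
    s_select, s_novel, s_gene, s_psi, s_unspl = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    transcripts = get_transcripts(ann, genome, k=k, gene_list=gene_list,
                                  n=n, seed=s_select)
    by_gene: dict[str, list[str]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t.id)

    gene_ids = list(by_gene)
    rng = np.random.default_rng(s_novel)
    novel: list[TruthTranscript] = []
    for i in range(n_novel_junctions):
        for gid in rng.permutation(gene_ids):
            try:
                tx = add_new_junction(ann, genome, gid,
                                      seed=int(rng.integers(2**31)),
                                      new_id=f"{gid}-novel-junction-{i}")
            except ValueError:
                continue
            novel.append(tx)
            break
    for i in range(n_novel_exons):
        for gid in rng.permutation(gene_ids):
            try:
                tx = add_new_exon(ann, genome, gid, canonical=canonical,
                                  seed=int(rng.integers(2**31)),
                                  new_id=f"{gid}-novel-exon-{i}")
            except ValueError:
                continue
            novel.append(tx)
            break
    for tx in novel:
        by_gene[tx.gene_id].append(tx.id)
    transcripts = transcripts + novel

    if n_min is None:
        n_min = max(len(v) for v in by_gene.values())
    gene_matrix = generate_gene_umi_matrix(chars, design, gene_ids,
                                           n_min=n_min, seed=s_gene)
    psi = generate_psi_matrix(by_gene, design, seed=s_psi)
    unspl = generate_unspliced_matrix(chars, gene_ids, design,
                                      custom_matrix=custom_unspliced,
                                      seed=s_unspl)
    counts = combine_truth(gene_matrix, psi, unspl, by_gene, design)

    sequences = {t.id: t.sequence for t in transcripts}
    gene_of = {t.id: t.gene_id for t in transcripts}
    for gid in gene_ids:
        gene = ann.gene(gid)
        tx0 = gene.transcripts[0]
        # one pre-mRNA species per gene: full genomic span, introns retained
        sequences[gid + UNSPLICED_SUFFIX] = fetch_transcript_sequence(
            ann, genome, tx0.id, spliced=False
        )
        gene_of[gid + UNSPLICED_SUFFIX] = gid
    return GroundTruth(transcripts=transcripts, counts=counts,
                       gene_of=gene_of, sequences=sequences,
                       psi=psi, unspliced=unspl, design=design)


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Write transcript FASTA, novel-structure GTF, and matrix tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "transcripts.fa", "w") as fh:
        for tid, seq in truth.sequences.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(out / "novel_structures.gtf", "w") as fh:
        for t in truth.transcripts:
            if t.novelty == "annotated":
                continue
            for s, e in t.exons:
                fh.write(
                    f"{t.contig}\tss3reads\texon\t{s + 1}\t{e}\t.\t{t.strand}"
                    f'\t.\tgene_id "{t.gene_id}"; transcript_id "{t.id}"; '
                    f'novelty "{t.novelty}";\n'
                )
    truth.counts.to_csv(out / "transcript_umi_counts.tsv", sep="\t")
    if truth.psi is not None:
        truth.psi.to_csv(out / "psi_per_population.tsv", sep="\t")
    if truth.unspliced is not None:
        truth.unspliced.to_csv(out / "unspliced_per_population.tsv", sep="\t")
    pd.Series(truth.gene_of, name="gene_id").to_csv(
        out / "transcript_gene_map.tsv", sep="\t",
        index_label="transcript_id")


def load_ground_truth(truth_dir: str | Path) -> GroundTruth:
    """Load a ground truth written by :func:`write_ground_truth` (or an
    equivalent user-supplied transcript FASTA + count matrix)."""
    from pyfaidx import Fasta

    d = Path(truth_dir)
    fa = Fasta(str(d / "transcripts.fa"), as_raw=True,
               sequence_always_upper=True)
    sequences = {name: str(fa[name][:]) for name in fa.keys()}
    counts = pd.read_csv(d / "transcript_umi_counts.tsv", sep="\t", index_col=0)
    gmap = pd.read_csv(d / "transcript_gene_map.tsv", sep="\t", index_col=0)
    gene_of = gmap["gene_id"].to_dict()
    transcripts = [
        TruthTranscript(id=tid, gene_id=gene_of.get(tid, tid),
                        sequence=seq, novelty="annotated", exons=())
        for tid, seq in sequences.items()
        if not tid.endswith(UNSPLICED_SUFFIX)
    ]
    return GroundTruth(transcripts=transcripts, counts=counts,
                       gene_of=gene_of, sequences=sequences)
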