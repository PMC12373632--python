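"""Smart-seq3 paired-end read simulation.

The pipeline mimics the library-preparation workflow per cell:

1.  Barcode/UMI assignment and tagging: each molecule is the transcript
    sequence prefixed with the protocol tag ``ATTGCGCAATG``, its random UMI,
    and ``GGG`` (the template-switch trace of tagmentation).
2.  PCR amplification: a reads-per-UMI target r is drawn per molecule and
    temporarily inflated by the PCR amplification factor (PAF).
3.  UMI-containing fragments: 5' prefixes of each amplified copy with
    empirically sampled lengths; the remainder feeds step 4.
4.  Internal fragments: random subfragments of the remainders; the count is
    an empirical internal:UMI ratio times the number of UMI fragments.
5.  Read generation: first and last ``read_len`` bases of each fragment
    (FR geometry); internal fragments lose strand by a fair coin flip.
6.  Error injection: per-base substitutions with probability P.
7.  Subsampling back to the pre-PAF targets.
8.  Quality assignment from the per-position empirical Phred profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .characterize import DataCharacteristics, EmpiricalDistribution
from .formats_io import reverse_complement, write_fastq_pairs
from .ground_truth import GroundTruth

logger = logging.getLogger(__name__)

SMARTSEQ3_TAG = "ATTGCGCAATG"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    read_len: int = 150
    error_rate: float = 0.005
    paf: float = 5.0            # PCR amplification factor
    umi_len: int = 8
    barcode_len: int = 16
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error rate must lie in [0, 1]")
        if self.read_len < 1:
            raise ValueError("read length must be >= 1")
        if self.paf < 1:
            raise ValueError("PCR amplification factor must be >= 1")


@dataclass
class TaggedMolecule:
    cell_barcode: str
    umi: str
    transcript_id: str
    sequence: str  # tag + UMI + GGG + transcript sequence

    @property
    def molecule_prefix_len(self) -> int:
        return len(SMARTSEQ3_TAG) + len(self.umi) + 3


@dataclass
class Fragment:
    role: str                   # "umi-containing" | "internal"
    sequence: str
    molecule: TaggedMolecule
    offset: int                 # start within the tagged molecule
    orientation: str = "sense"  # internal fragments may become "antisense"


@dataclass
class SimulatedReadPair:
    read_id: str
    read1_seq: str
    read2_seq: str
    read1_qual: list[int] = field(default_factory=list)
    read2_qual: list[int] = field(default_factory=list)
    # ground-truth annotations
    cell: str = ""
    barcode: str = ""
    umi: str = ""
    transcript_id: str = ""
    role: str = ""
    orientation: str = "sense"
    frag_offset: int = 0        # within the tagged molecule, pre-orientation
    frag_len: int = 0
    molecule_index: int = -1


# ---------------------------------------------------------------------------
# Step operations
# ---------------------------------------------------------------------------

def assign_barcodes(n_cells: int, barcode_len: int,
                    rng: np.random.Generator) -> list[str]:
    """n_cells distinct random cell barcodes over {A,C,G,T}."""
    if 4 ** barcode_len < n_cells:
        raise ValueError(
            f"barcode space 4^{barcode_len} is too small for {n_cells} cells"
        )
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n_cells:
        bc = "".join(rng.choice(list("ACGT"), size=barcode_len))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _random_umi(umi_len: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=umi_len))


def assign_umis(counts_column, gene_of: dict[str, str], umi_len: int,
                rng: np.random.Generator) -> list[tuple[str, str]]:
    """Expand one cell's count column into (transcript_id, UMI) molecules.

    Each molecule gets an independent random UMI; UMIs are unique within
    (cell, gene) so truth counts stay identifiable, while collisions across
    genes are allowed (as in real data).
    """
    molecules: list[tuple[str, str]] = []
    used_per_gene: dict[str, set[str]] = {}
    for tid, m in counts_column.items():
        gene = gene_of.get(tid, tid)
        used = used_per_gene.setdefault(gene, set())
        for _ in range(int(m)):
            umi = _random_umi(umi_len, rng)
            while umi in used:
                umi = _random_umi(umi_len, rng)
            used.add(umi)
            molecules.append((tid, umi))
    return molecules


def tag_molecule(barcode: str, umi: str, transcript_id: str,
                 transcript_seq: str) -> TaggedMolecule:
    """Prefix the transcript with tag + UMI + GGG (tagmentation mimic)."""
    if not transcript_seq:
        logger.debug("degenerate molecule: empty transcript %s", transcript_id)
    return TaggedMolecule(
        cell_barcode=barcode, umi=umi, transcript_id=transcript_id,
        sequence=SMARTSEQ3_TAG + umi + "GGG" + transcript_seq,
    )


def pcr_amplify(reads_per_umi: EmpiricalDistribution, paf: float,
                rng: np.random.Generator) -> tuple[int, int]:
    """Draw the molecule's sequencing target r and its amplified copy count.

    Copies = max(1, round(r * PAF)); r is the post-subsampling target.
    """
    r = int(reads_per_umi.sample(rng))
    copies = max(1, int(np.rint(r * paf)))
    return copies, r


def extract_umi_fragment(tagged: TaggedMolecule,
                         umi_fragment_length: EmpiricalDistribution,
                         rng: np.random.Generator) -> tuple[Fragment, str]:
    """5' prefix fragment of sampled length (clamped) plus the remainder."""
    L = min(int(umi_fragment_length.sample(rng)), len(tagged.sequence))
    frag = Fragment(role="umi-containing", sequence=tagged.sequence[:L],
                    molecule=tagged, offset=0)
    return frag, tagged.sequence[L:]


def extract_internal_fragments(remainders: list[tuple[str, int]],
                               n_umi_frags: int,
                               internal_to_umi_ratio: EmpiricalDistribution,
                               internal_fragment_length: EmpiricalDistribution,
                               molecule: TaggedMolecule,
                               rng: np.random.Generator) -> list[Fragment]:
    """Random subfragments of the post-prefix remainders.

    The fragment count is a single ratio draw times the number of UMI
    fragments; each fragment picks a non-empty remainder uniformly, then a
    uniformly positioned start with an empirically sampled (clamped) length.
    ``remainders`` holds (sequence, offset-within-molecule) pairs.
    """
    nonempty = [(seq, off) for seq, off in remainders if seq]
    if not nonempty or n_umi_frags == 0:
        return []
    ratio = float(internal_to_umi_ratio.sample(rng))
    count = int(np.rint(ratio * n_umi_frags))
    frags: list[Fragment] = []
    for _ in range(count):
        seq, off = nonempty[int(rng.integers(len(nonempty)))]
        L = min(int(internal_fragment_length.sample(rng)), len(seq))
        start = int(rng.integers(len(seq) - L + 1))
        frags.append(Fragment(role="internal", sequence=seq[start:start + L],
                              molecule=molecule, offset=off + start))
    return frags


def orient_internal(frag: Fragment, rng: np.random.Generator) -> Fragment:
    """Flip an internal fragment to antisense with probability 0.5
    (internal reads carry no strand information)."""
    if frag.role != "internal":
        raise ValueError("orient_internal applies to internal fragments only")
    if rng.random() < 0.5:
        frag.sequence = reverse_complement(frag.sequence)
        frag.orientation = "antisense" if frag.orientation == "sense" else "sense"
    return frag


def make_read_pair(frag: Fragment, read_len: int) -> tuple[str, str]:
    """FR paired-end geometry: read1 = first min(read_len, L) bases of the
    fragment, read2 = reverse complement of the last min(read_len, L)."""
    seq = frag.sequence
    n = min(read_len, len(seq))
    return seq[:n], reverse_complement(seq[len(seq) - n:])


def inject_errors(seq: str, p: float, rng: np.random.Generator) -> str:
    """Independent per-base substitutions with probability p; a substituted
    base becomes one of the other three nucleotides uniformly."""
    if p == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < p)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        if len(choices) == 4:  # N or unexpected base: any ACGT
            choices = _BASES
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def subsample_reads(pairs: list[SimulatedReadPair],
                    targets: dict[int, int],
                    rng: np.random.Generator) -> list[SimulatedReadPair]:
    """Undo the PAF inflation.

    UMI-containing pairs: per molecule, keep min(target, available) uniformly
    without replacement.  Internal pairs: keep round(f * n) globally, where f
    is the realized UMI retention fraction, preserving the internal:UMI
    balance established at fragment generation.
    """
    umi_by_mol: dict[int, list[SimulatedReadPair]] = {}
    internal: list[SimulatedReadPair] = []
    for p in pairs:
        if p.role == "umi-containing":
            umi_by_mol.setdefault(p.molecule_index, []).append(p)
        else:
            internal.append(p)
    kept: list[SimulatedReadPair] = []
    n_avail = n_kept = 0
    for mol, group in umi_by_mol.items():
        t = min(targets.get(mol, len(group)), len(group))
        n_avail += len(group)
        n_kept += t
        if t == len(group):
            kept.extend(group)
        else:
            idx = rng.choice(len(group), size=t, replace=False)
            kept.extend(group[i] for i in sorted(idx))
    f = (n_kept / n_avail) if n_avail else 1.0
    n_int_keep = int(np.rint(f * len(internal)))
    if n_int_keep >= len(internal):
        kept.extend(internal)
    else:
        idx = rng.choice(len(internal), size=n_int_keep, replace=False)
        kept.extend(internal[i] for i in sorted(idx))
    return kept


def assign_quality(read_len: int, profile: list[EmpiricalDistribution],
                   rng: np.random.Generator) -> list[int]:
    """Per-position Phred draw from the empirical profile; positions past
    the profile end reuse the final position's distribution."""
    return _batch_assign_quality([read_len], profile, rng)[0]


def _batch_assign_quality(lengths: list[int],
                          profile: list[EmpiricalDistribution],
                          rng: np.random.Generator) -> list[list[int]]:
    """Vectorized quality assignment: one per-position draw for all reads."""
    if not profile:
        raise ValueError("empty quality profile")
    if not lengths:
        return []
    max_len = max(lengths)
    last = len(profile) - 1
    mat = np.empty((len(lengths), max_len), dtype=int)
    for i in range(max_len):
        mat[:, i] = profile[min(i, last)].sample(rng, size=len(lengths))
    return [mat[r, :L].tolist() for r, L in enumerate(lengths)]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_pairs(truth: GroundTruth, chars: DataCharacteristics,
                   config: SimulationConfig) -> Iterator[SimulatedReadPair]:
    """Run the eight simulation steps per cell, yielding finished read pairs.

    Fully reproducible: one master seed spawns per-cell generators, so a
    given (truth, characteristics, config) triple always yields byte-
    identical reads.
    """
    chars.validate()
    counts = truth.counts
    cells = list(counts.columns)
    ss = np.random.SeedSequence(config.seed)
    bc_rng = np.random.default_rng(ss.spawn(1)[0])
    barcodes = assign_barcodes(len(cells), config.barcode_len, bc_rng)
    cell_seeds = ss.spawn(len(cells))

    for j, cell in enumerate(cells):
        rng = np.random.default_rng(cell_seeds[j])
        barcode = barcodes[j]
        molecules = assign_umis(counts[cell], truth.gene_of,
                                config.umi_len, rng)
        cell_pairs: list[SimulatedReadPair] = []
        targets: dict[int, int] = {}
        for mol_idx, (tid, umi) in enumerate(molecules):
            tagged = tag_molecule(barcode, umi, tid, truth.sequences[tid])
            copies, target = pcr_amplify(chars.reads_per_umi, config.paf, rng)
            targets[mol_idx] = target
            remainders: list[tuple[str, int]] = []
            frags: list[Fragment] = []
            for _ in range(copies):
                frag, rem = extract_umi_fragment(
                    tagged, chars.umi_fragment_length, rng)
                frags.append(frag)
                remainders.append((rem, len(frag.sequence)))
            frags.extend(extract_internal_fragments(
                remainders, copies, chars.internal_to_umi_ratio,
                chars.internal_fragment_length, tagged, rng))
            for dup, frag in enumerate(frags):
                if frag.role == "internal":
                    frag = orient_internal(frag, rng)
                r1, r2 = make_read_pair(frag, config.read_len)
                r1 = inject_errors(r1, config.error_rate, rng)
                r2 = inject_errors(r2, config.error_rate, rng)
                role_code = "U" if frag.role == "umi-containing" else "I"
                rid = (f"{barcode}:{mol_idx}:{role_code}:{tid}:{dup}")
                cell_pairs.append(SimulatedReadPair(
                    read_id=rid, read1_seq=r1, read2_seq=r2,
                    cell=cell, barcode=barcode, umi=umi,
                    transcript_id=tid, role=frag.role,
                    orientation=frag.orientation,
                    frag_offset=frag.offset, frag_len=len(frag.sequence),
                    molecule_index=mol_idx,
                ))
        kept = subsample_reads(cell_pairs, targets, rng)
        q1 = _batch_assign_quality([len(p.read1_seq) for p in kept],
                                   chars.quality_by_position_read, rng)
        q2 = _batch_assign_quality([len(p.read2_seq) for p in kept],
                                   chars.quality_by_position_read, rng)
        for pair, a, b in zip(kept, q1, q2):
            pair.read1_qual = a
            pair.read2_qual = b
            yield pair


TRUTH_COLUMNS = ("read_id", "cell", "barcode", "umi", "transcript_id",
                 "role", "orientation", "frag_offset", "frag_len")


def simulate(truth: GroundTruth, chars: DataCharacteristics,
             config: SimulationConfig, out_prefix: str | Path,
             compress: bool = False) -> dict:
    """Simulate and write R1/R2 FASTQ, the truth table and the barcode list.

    The truth table maps every read id to its cell, barcode, UMI, source
    transcript, fragment role/orientation and fragment coordinates within
    the tagged molecule, so benchmarks can score alignments (and reconstruct
    the error-free source substring) without re-running the simulator.
    """
    prefix = str(out_prefix)
    parent = Path(prefix).parent
    if str(parent):
        parent.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if compress else ".fastq"
    truth_rows = []
    barcodes_seen: dict[str, str] = {}

    def annotated():
        for pair in simulate_pairs(truth, chars, config):
            truth_rows.append([getattr(pair, c) for c in TRUTH_COLUMNS])
            barcodes_seen.setdefault(pair.cell, pair.barcode)
            yield pair

    n = write_fastq_pairs(annotated(), prefix + "_R1" + suffix,
                          prefix + "_R2" + suffix, compress=compress)
    import pandas as pd

    pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS).to_csv(
        prefix + "_truth.tsv", sep="\t", index=False)
    pd.Series(barcodes_seen, name="barcode").to_csv(
        prefix + "_barcodes.tsv", sep="\t", index_label="cell")
    logger.info("wrote %d read pairs to %s_R{1,2}%s", n, prefix, suffix)
    return {"n_pairs": n, "r1": prefix + "_R1" + suffix,
            "r2": prefix + "_R2" + suffix,
            "truth_table": prefix + "_truth.tsv"}


def reconstruct_fragment(truth: GroundTruth, umi: str, transcript_id: str,
                         frag_offset: int, frag_len: int,
                         orientation: str = "sense") -> str:
    """Rebuild a fragment's error-free sequence from the truth table fields
    (independent of the simulator's fragment bookkeeping)."""
    tagged = SMARTSEQ3_TAG + umi + "GGG" + truth.sequences[transcript_id]
    frag = tagged[frag_offset:frag_offset + frag_len]
    return reverse_complement(frag) if orientation == "antisense" else frag
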