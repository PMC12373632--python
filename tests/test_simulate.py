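"""Step-by-step simulation operations and the orchestrated pipeline."""

import numpy as np
import pandas as pd
import pytest

import ss3reads as s3
from ss3reads.formats_io import read_fastq, reverse_complement
from ss3reads.simulate import (
    SMARTSEQ3_TAG,
    Fragment,
    TaggedMolecule,
    _batch_assign_quality,
)


def _dist(values, weights=None):
    return s3.EmpiricalDistribution(
        values, weights if weights is not None else [1] * len(values))


def _molecule(seq="A" * 100, umi="C" * 8):
    return s3.tag_molecule("B" * 16, umi, "tx", seq)


class TestBarcodes:
    def test_distinct_and_correct_length(self):
        rng = np.random.default_rng(0)
        bcs = s3.assign_barcodes(200, 16, rng)
        assert len(set(bcs)) == 200
        assert all(len(b) == 16 and set(b) <= set("ACGT") for b in bcs)

    def test_space_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            s3.assign_barcodes(5, 1, np.random.default_rng(0))

    def test_seed_determinism(self):
        a = s3.assign_barcodes(10, 8, np.random.default_rng(7))
        b = s3.assign_barcodes(10, 8, np.random.default_rng(7))
        assert a == b


class TestAssignUmis:
    def test_counts_expand_to_molecules(self):
        col = pd.Series({"t1": 3, "t2": 0})
        mols = s3.assign_umis(col, {"t1": "g", "t2": "g"}, 8,
                              np.random.default_rng(0))
        assert len(mols) == 3
        assert {t for t, _ in mols} == {"t1"}
        assert len({u for _, u in mols}) == 3  # distinct within (cell, gene)

    def test_total_equals_column_sum(self):
        rng = np.random.default_rng(1)
        col = pd.Series({f"t{i}": int(c) for i, c in
                         enumerate(rng.integers(0, 9, size=20))})
        mols = s3.assign_umis(col, {t: "g1" for t in col.index}, 8, rng)
        assert len(mols) == col.sum()

    def test_umis_unique_within_gene(self):
        rng = np.random.default_rng(2)
        col = pd.Series({"t1": 40, "t2": 40})
        mols = s3.assign_umis(col, {"t1": "g", "t2": "g"}, 4, rng)
        assert len({u for _, u in mols}) == 80


class TestTagging:
    def test_exact_concatenation(self):
        m = s3.tag_molecule("B" * 16, "CCCCCCCC", "tx", "AAAA")
        assert m.sequence == "ATTGCGCAATGCCCCCCCCGGGAAAA"

    def test_length_identity(self):
        m = s3.tag_molecule("B" * 16, "ACGTACGT", "tx", "G" * 57)
        assert len(m.sequence) == 11 + 8 + 3 + 57

    def test_empty_transcript_degenerate(self):
        m = s3.tag_molecule("B" * 16, "ACGTACGT", "tx", "")
        assert m.sequence == SMARTSEQ3_TAG + "ACGTACGT" + "GGG"


class TestPcrAmplify:
    def test_arithmetic(self):
        copies, target = s3.pcr_amplify(_dist([2]), 3.0,
                                        np.random.default_rng(0))
        assert (copies, target) == (6, 2)

    def test_paf_one_is_identity(self):
        copies, target = s3.pcr_amplify(_dist([4]), 1.0,
                                        np.random.default_rng(0))
        assert copies == target == 4

    def test_mean_copies_tracks_paf(self):
        rng = np.random.default_rng(3)
        law = _dist([1, 2, 3, 4], [4, 3, 2, 1])
        paf = 2.5
        copies = np.array([s3.pcr_amplify(law, paf, rng)[0]
                           for _ in range(10_000)])
        expected = paf * law.mean()
        se = np.sqrt(law.var()) * paf / np.sqrt(len(copies))
        # round() adds at most 0.5 of systematic offset
        assert abs(copies.mean() - expected) < 3 * se + 0.5


class TestUmiFragment:
    def test_prefix_and_remainder(self):
        m = _molecule(seq="G" * 978)  # tagged length 1000
        frag, rem = s3.extract_umi_fragment(m, _dist([300]),
                                            np.random.default_rng(0))
        assert frag.sequence == m.sequence[:300]
        assert rem == m.sequence[300:]
        assert frag.role == "umi-containing" and frag.offset == 0

    def test_clamped_to_molecule_length(self):
        m = _molecule(seq="G" * 50)
        frag, rem = s3.extract_umi_fragment(m, _dist([5000]),
                                            np.random.default_rng(0))
        assert frag.sequence == m.sequence and rem == ""

    def test_fragment_starts_with_tag(self):
        m = _molecule()
        frag, _ = s3.extract_umi_fragment(m, _dist([40]),
                                          np.random.default_rng(0))
        assert frag.sequence.startswith(SMARTSEQ3_TAG)


class TestInternalFragments:
    def test_count_is_ratio_times_umi_fragments(self):
        m = _molecule(seq="G" * 2000)
        frags = s3.extract_internal_fragments(
            [(m.sequence[300:], 300)], 3, _dist([2.0]), _dist([100]),
            m, np.random.default_rng(0))
        assert len(frags) == 6
        assert all(f.role == "internal" for f in frags)

    def test_empty_remainder_yields_nothing(self):
        m = _molecule()
        frags = s3.extract_internal_fragments(
            [("", 100)], 5, _dist([2.0]), _dist([100]), m,
            np.random.default_rng(0))
        assert frags == []

    def test_fragments_are_substrings_at_recorded_offsets(self):
        rng = np.random.default_rng(4)
        m = _molecule(seq="".join(rng.choice(list("ACGT"), 3000)))
        rem_off = 250
        rem = m.sequence[rem_off:]
        frags = s3.extract_internal_fragments(
            [(rem, rem_off)], 10, _dist([1.5]), _dist([80, 120, 500]),
            m, rng)
        for f in frags:
            assert f.sequence in rem
            assert m.sequence[f.offset:f.offset + len(f.sequence)] == f.sequence


class TestOrientation:
    def test_flip_is_involution(self):
        f = Fragment(role="internal", sequence="ACGTT",
                     molecule=_molecule(), offset=0)

        class ForcedFlip:
            def random(self):
                return 0.0  # always below 0.5 -> always flip

        s3.orient_internal(f, ForcedFlip())
        assert f.sequence == reverse_complement("ACGTT")
        s3.orient_internal(f, ForcedFlip())
        assert f.sequence == "ACGTT" and f.orientation == "sense"

    def test_umi_fragment_rejected(self):
        f = Fragment(role="umi-containing", sequence="ACGT",
                     molecule=_molecule(), offset=0)
        with pytest.raises(ValueError, match="internal"):
            s3.orient_internal(f, np.random.default_rng(0))

    def test_antisense_fraction_is_half(self):
        rng = np.random.default_rng(5)
        n = 10_000
        flips = 0
        for _ in range(n):
            f = Fragment(role="internal", sequence="ACGT",
                         molecule=_molecule(), offset=0)
            s3.orient_internal(f, rng)
            flips += f.orientation == "antisense"
        assert abs(flips / n - 0.5) < 3 * np.sqrt(0.25 / n)


class TestReadPairGeometry:
    def test_400nt_fragment(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 400))
        f = Fragment(role="internal", sequence=seq, molecule=_molecule(),
                     offset=0)
        r1, r2 = s3.make_read_pair(f, 150)
        assert r1 == seq[:150]
        assert r2 == reverse_complement(seq[250:400])

    def test_short_fragment_full_overlap(self):
        seq = "ACGT" * 25
        f = Fragment(role="internal", sequence=seq, molecule=_molecule(),
                     offset=0)
        r1, r2 = s3.make_read_pair(f, 150)
        assert len(r1) == len(r2) == 100
        assert r2 == reverse_complement(r1)

    def test_umi_read1_keeps_tag(self):
        m = _molecule(seq="G" * 500)
        frag, _ = s3.extract_umi_fragment(m, _dist([300]),
                                          np.random.default_rng(0))
        r1, _ = s3.make_read_pair(frag, 150)
        assert r1.startswith(SMARTSEQ3_TAG)


class TestErrorInjection:
    def test_p_zero_is_identity(self):
        seq = "ACGT" * 100
        assert s3.inject_errors(seq, 0.0, np.random.default_rng(0)) == seq

    def test_p_one_changes_every_base(self):
        seq = "ACGT" * 100
        out = s3.inject_errors(seq, 1.0, np.random.default_rng(0))
        assert len(out) == len(seq)
        assert all(a != b for a, b in zip(seq, out))

    def test_substitutions_uniform_over_alternatives(self):
        rng = np.random.default_rng(8)
        out = s3.inject_errors("A" * 30_000, 1.0, rng)
        from collections import Counter

        c = Counter(out)
        assert set(c) == {"C", "G", "T"}
        for b in "CGT":
            assert abs(c[b] / 30_000 - 1 / 3) < 0.02


class TestSubsampling:
    def _pairs(self, mol, role, n):
        return [s3.SimulatedReadPair(read_id=f"{mol}:{role}:{i}",
                                     read1_seq="A", read2_seq="T",
                                     role=role, molecule_index=mol)
                for i in range(n)]

    def test_exact_target_retained(self):
        pairs = self._pairs(0, "umi-containing", 6)
        kept = s3.subsample_reads(pairs, {0: 2}, np.random.default_rng(0))
        assert len(kept) == 2

    def test_paf_one_is_noop(self):
        pairs = self._pairs(0, "umi-containing", 3)
        kept = s3.subsample_reads(pairs, {0: 3}, np.random.default_rng(0))
        assert len(kept) == 3

    def test_internal_follows_global_retention(self):
        pairs = (self._pairs(0, "umi-containing", 10)
                 + self._pairs(0, "internal", 20))
        kept = s3.subsample_reads(pairs, {0: 5}, np.random.default_rng(0))
        roles = [p.role for p in kept]
        assert roles.count("umi-containing") == 5
        assert roles.count("internal") == 10  # retention 0.5


class TestQuality:
    def test_degenerate_profile(self):
        q = s3.assign_quality(5, [_dist([30])], np.random.default_rng(0))
        assert q == [30] * 5

    def test_profile_extension_rule(self):
        profile = [_dist([10]), _dist([20])]
        q = s3.assign_quality(6, profile, np.random.default_rng(0))
        assert q == [10, 20, 20, 20, 20, 20]

    def test_positional_means_track_profile(self, default_chars):
        rng = np.random.default_rng(9)
        profile = default_chars.quality_by_position_read
        n = 10_000
        quals = np.array(_batch_assign_quality([len(profile)] * n,
                                               profile, rng))
        for i in [0, 75, len(profile) - 1]:
            d = profile[i]
            se = np.sqrt(d.var() / n)
            assert abs(quals[:, i].mean() - d.mean()) < 4 * se


class TestPipeline:
    def test_hand_traceable_single_molecule(self, tmp_path):
        """1 cell / 1 transcript / 1 UMI, PAF=1, P=0: the reads must be
        reconstructible by hand from the tagged sequence and the truth
        table's recorded fragment coordinates."""
        rng = np.random.default_rng(10)
        seq = "".join(rng.choice(list("ACGT"), 600))
        counts = pd.DataFrame({"pop0_cell0": [1]}, index=["t1"])
        truth = s3.GroundTruth(transcripts=[], counts=counts,
                               gene_of={"t1": "g1"}, sequences={"t1": seq})
        chars = _make_simple_chars()
        config = s3.SimulationConfig(read_len=150, error_rate=0.0, paf=1.0,
                                     seed=1)
        pairs = list(s3.simulate_pairs(truth, chars, config))
        umi_pairs = [p for p in pairs if p.role == "umi-containing"]
        assert len(umi_pairs) == 1  # reads-per-UMI law is a point mass at 1
        p = umi_pairs[0]
        tagged = SMARTSEQ3_TAG + p.umi + "GGG" + seq
        frag = tagged[p.frag_offset:p.frag_offset + p.frag_len]
        assert p.read1_seq == frag[:150]
        assert p.read1_seq.startswith(SMARTSEQ3_TAG + p.umi + "GGG")
        assert p.read2_seq == reverse_complement(frag[-150:])
        for q in pairs:
            rec = s3.reconstruct_fragment(truth, q.umi, q.transcript_id,
                                          q.frag_offset, q.frag_len,
                                          q.orientation)
            assert q.read1_seq == rec[:len(q.read1_seq)]

    def test_empty_count_matrix_gives_empty_fastq(self, tmp_path,
                                                  default_chars):
        counts = pd.DataFrame({"pop0_cell0": []}, dtype=int)
        truth = s3.GroundTruth(transcripts=[], counts=counts, gene_of={},
                               sequences={})
        config = s3.SimulationConfig(seed=0)
        info = s3.simulate(truth, default_chars, config, tmp_path / "empty")
        assert info["n_pairs"] == 0
        assert list(read_fastq(info["r1"])) == []

    def test_seed_determinism_byte_identical(self, small_truth,
                                             default_chars, tmp_path):
        config = s3.SimulationConfig(read_len=100, seed=23, paf=2.0)
        a = s3.simulate(small_truth, default_chars, config, tmp_path / "a")
        b = s3.simulate(small_truth, default_chars, config, tmp_path / "b")
        for key in ("r1", "r2"):
            with open(a[key], "rb") as fa, open(b[key], "rb") as fb:
                assert fa.read() == fb.read()

    def test_umi_triples_match_matrix(self, small_sim, small_truth):
        tt = small_sim["truth"]
        umi = tt[tt.role == "umi-containing"]
        triples = umi[["cell", "transcript_id", "umi"]].drop_duplicates()
        assert len(triples) == small_truth.counts.to_numpy().sum()

    def test_truth_table_covers_every_read(self, small_sim):
        ids = {rid for rid, _, _ in read_fastq(small_sim["r1"])}
        ids = {i.split()[0] for i in ids}
        assert ids == set(small_sim["truth"].read_id)


def _make_simple_chars():
    """Point-mass characteristics for hand-traceable runs."""
    one = s3.EmpiricalDistribution([1], [1.0])
    return s3.DataCharacteristics(
        umi_fragment_length=s3.EmpiricalDistribution([400], [1.0]),
        internal_fragment_length=s3.EmpiricalDistribution([100], [1.0]),
        reads_per_umi=one,
        internal_to_umi_ratio=s3.EmpiricalDistribution([2.0], [1.0]),
        unspliced_fraction=s3.EmpiricalDistribution([0.0], [1.0]),
        umis_per_gene=s3.EmpiricalDistribution([5], [1.0]),
        quality_by_position_read=[s3.EmpiricalDistribution([30], [1.0])] * 150,
        quality_by_position_barcode=[s3.EmpiricalDistribution([30], [1.0])] * 16,
    )
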