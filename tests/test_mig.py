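"""MIG grouping, UMI collision correction and consensus assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umicall import simdata
from umicall.mig import (AssemblyRejection, Mig, assemble_all,
                         assemble_consensus, compute_size_threshold,
                         correct_umi_collisions, cqs, group_migs)
from umicall.preprocess import TaggedRead
from conftest import make_read


def tagged(umi, seq, qual=30, sample="s", rid="r"):
    return TaggedRead(make_read(seq, qual, rid), umi,
                      np.full(len(umi), 30, dtype=np.int32), sample)


def make_mig(umi, seqs, qual=30):
    return Mig(umi, "s", [tagged(umi, s, qual, rid=f"r{i}")
                          for i, s in enumerate(seqs)])


class TestGroupMigs:
    def test_groups_by_umi(self):
        reads = ([tagged("AAAA", "ACGT" * 10, rid=f"a{i}") for i in range(7)]
                 + [tagged("CCCC", "ACGT" * 10, rid=f"c{i}") for i in range(3)])
        migs = group_migs(reads)
        assert sorted((m.umi, m.size) for m in migs) == [("AAAA", 7),
                                                         ("CCCC", 3)]

    def test_empty_input_gives_empty_collection(self):
        assert group_migs([]) == []

    def test_mixed_umi_lengths_rejected(self):
        reads = [tagged("AAAA", "ACGT"), tagged("AAAAA", "ACGT")]
        with pytest.raises(ValueError, match="mixed UMI lengths"):
            group_migs(reads)

    def test_total_reads_conserved_on_simulated_data(self, small_sim):
        cfg, reads, truth = small_sim
        from umicall.preprocess import extract_reads
        res = extract_reads(reads, cfg.patterns())
        migs = group_migs(res.tagged)
        assert sum(m.size for m in migs) == len(res.tagged)


class TestCollisionCorrection:
    def _mig(self, umi, size):
        return make_mig(umi, ["ACGTACGT" * 5] * size)

    def test_one_mismatch_twentyfold_discards_smaller(self):
        migs = [self._mig("AAAA", 1000), self._mig("AAAT", 40)]
        kept, discarded = correct_umi_collisions(migs)
        assert [m.umi for m in kept] == ["AAAA"]
        assert discarded[0][0].umi == "AAAT"
        assert discarded[0][1] == "AAAA"

    def test_below_ratio_keeps_both(self):
        migs = [self._mig("AAAA", 1000), self._mig("AAAT", 100)]
        kept, discarded = correct_umi_collisions(migs)
        assert len(kept) == 2 and not discarded

    def test_two_mismatches_need_four_hundred_fold(self):
        migs = [self._mig("AAAA", 1000), self._mig("AATT", 2)]
        kept, _ = correct_umi_collisions(migs)
        assert [m.umi for m in kept] == ["AAAA"]
        migs = [self._mig("AAAA", 1000), self._mig("AATT", 3)]
        kept, _ = correct_umi_collisions(migs)   # ratio 333 < 400
        assert len(kept) == 2

    def test_order_independence(self, rng):
        sizes = {"AAAA": 900, "AAAT": 30, "AATT": 2, "CCCC": 500, "CCCG": 10}
        base = [self._mig(u, s) for u, s in sizes.items()]
        ref_kept, _ = correct_umi_collisions(base)
        ref_umis = sorted(m.umi for m in ref_kept)
        for _ in range(5):
            perm = list(base)
            rng.shuffle(perm)
            kept, _ = correct_umi_collisions(perm)
            assert sorted(m.umi for m in kept) == ref_umis

    def test_discarded_mig_cannot_absorb_others(self):
        # chain: big absorbs mid; mid may not then absorb small
        migs = [self._mig("AAAA", 8000), self._mig("AAAT", 400),
                self._mig("AATT", 30)]
        kept, discarded = correct_umi_collisions(migs)
        parents = {c.umi: p for c, p in discarded}
        assert parents["AAAT"] == "AAAA"
        # AATT vs AAAT ratio 13 < 20 and AAAT is gone; vs AAAA d=2 ratio 266 < 400
        assert "AATT" in {m.umi for m in kept}

    def test_merge_reassigns_reads(self):
        migs = [self._mig("AAAA", 100), self._mig("AAAT", 5)]
        kept, _ = correct_umi_collisions(migs, merge=True)
        assert kept[0].size == 105


class TestSizeThreshold:
    def test_sqrt_of_read_weighted_peak(self):
        # bulk of reads in MIGs of size 64 -> threshold 8
        migs = ([make_mig(f"A{i:03d}"[:4], ["ACGT"] * 64) for i in range(50)]
                + [make_mig(f"C{i:03d}"[:4], ["ACGT"]) for i in range(100)])
        assert compute_size_threshold(migs) == 8

    def test_floor_dominates_small_migs(self):
        migs = [make_mig(f"G{i:03d}"[:4], ["ACGT"]) for i in range(20)]
        assert compute_size_threshold(migs) == 5

    def test_no_migs_is_an_error(self):
        with pytest.raises(ValueError):
            compute_size_threshold([])

    def test_simulated_mean_hundred_gives_about_ten(self, rng):
        sizes = np.maximum(1, rng.lognormal(np.log(100), 0.4, 2000).round())
        migs = [make_mig(f"{i:04d}", ["ACGT"] * int(s))
                for i, s in enumerate(sizes)]
        assert 8 <= compute_size_threshold(migs) <= 12


class TestCqs:
    def test_endpoints_are_exact(self):
        assert cqs(0.25) == 0.0
        assert cqs(1.0) == 40.0

    def test_formula_midpoint(self):
        assert cqs(0.7) == pytest.approx(24.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cqs(0.2)
        with pytest.raises(ValueError):
            cqs(1.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.25, 1.0), st.floats(0.25, 1.0))
    def test_strictly_increasing(self, f1, f2):
        if f1 < f2:
            assert cqs(f1) < cqs(f2)


SEQ = "ACGTAGCTAGGATCCATGCAGTCCATGGACTTGCACCAGTAA"  # 42 bases


class TestAssembleConsensus:
    def test_identical_reads_give_perfect_consensus(self):
        out = assemble_consensus(make_mig("AAAA", [SEQ] * 5), 5)
        consensus, minors, dropped = out
        assert consensus.sequence == SEQ
        assert np.all(consensus.f == 1.0)
        assert np.all(consensus.cqs_scores == 40.0)
        assert consensus.reads_used == 5 and consensus.reads_dropped == 0
        assert minors.total() == 0 and not dropped

    def test_single_substitution_majority_vote(self):
        mutant = SEQ[:20] + "T" + SEQ[21:]
        assert SEQ[20] != "T"
        consensus, minors, _ = assemble_consensus(
            make_mig("AAAA", [SEQ] * 4 + [mutant]), 5)
        assert consensus.sequence == SEQ
        assert consensus.f[20] == pytest.approx(0.8)
        assert consensus.cqs_scores[20] == pytest.approx((40 / 3) * (4 * 0.8 - 1))
        assert minors.counts[(20, SEQ[20], "T")] == 1

    def test_deletion_read_dropped_for_consecutive_mismatches(self):
        deleted = SEQ[:25] + SEQ[27:]    # 2-base deletion mid-read
        consensus, _, dropped = assemble_consensus(
            make_mig("AAAA", [SEQ] * 5 + [deleted]), 5)
        assert consensus.sequence == SEQ
        assert len(dropped) == 1
        assert dropped[0].sequence == deleted

    def test_below_threshold_is_rejected(self):
        out = assemble_consensus(make_mig("AAAA", [SEQ] * 3), 5)
        assert isinstance(out, AssemblyRejection)
        assert out.reason == "below_threshold"

    def test_short_reads_cannot_seed_a_core(self):
        out = assemble_consensus(make_mig("AAAA", ["ACGT" * 5] * 5), 5)
        assert isinstance(out, AssemblyRejection)

    def test_random_offsets_are_anchored(self, rng):
        reads = [("ACGT"[rng.integers(4)] * k) + SEQ for k in (0, 2, 4, 1, 3)]
        consensus, _, _ = assemble_consensus(make_mig("AAAA", reads), 5)
        assert SEQ in consensus.sequence

    def test_minor_quality_floor(self):
        mutant = SEQ[:20] + "T" + SEQ[21:]
        mig = Mig("AAAA", "s",
                  [tagged("AAAA", SEQ, rid=f"r{i}") for i in range(4)]
                  + [tagged("AAAA", mutant, qual=20, rid="rm")])
        _, minors, _ = assemble_consensus(mig, 5, q_minor=30)
        assert minors.total() == 0     # minor base below Phred 30


class TestAssembleAll:
    def test_read_conservation(self, small_sim):
        cfg, reads, _ = small_sim
        from umicall.preprocess import extract_reads
        res = extract_reads(reads, cfg.patterns())
        migs = group_migs(res.tagged)
        migs, discarded = correct_umi_collisions(migs)
        thr = compute_size_threshold(migs)
        result = assemble_all(migs, thr)
        used = sum(c.reads_used for c in result.consensuses)
        dropped_in_cons = sum(c.reads_dropped for c in result.consensuses)
        rejected = sum(r.reads for r in result.rejections)
        in_collisions = sum(m.size for m, _ in discarded)
        assert (used + dropped_in_cons + rejected + in_collisions
                == len(res.tagged))

    def test_consensus_positions_match_template(self, rng):
        """Phred-20-style 1% read errors, MIG >= 5: >= 99.99% accuracy."""
        n_positions = 0
        n_correct = 0
        bases = np.array(list("ACGT"))
        for m in range(300):
            reads = []
            for i in range(5):
                arr = np.array(list(SEQ))
                errs = rng.random(len(arr)) < 0.01
                arr[errs] = bases[rng.integers(0, 4, errs.sum())]
                reads.append("".join(arr))
            out = assemble_consensus(make_mig("AAAA", reads), 5)
            if isinstance(out, AssemblyRejection):
                continue
            consensus = out[0]
            if len(consensus.sequence) == len(SEQ):
                n_positions += len(SEQ)
                n_correct += sum(a == b for a, b in
                                 zip(consensus.sequence, SEQ))
        assert n_positions > 0
        assert n_correct / n_positions > 0.9999

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            assemble_all([], preset="pacbio")
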