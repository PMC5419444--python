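"""Pileup construction, variant calling and VCF output."""

import itertools

import numpy as np
import pytest
import scipy.stats as st

from umicall.aligner import (Alignment, AlignmentHit, ReferenceLibrary,
                             ReferenceRecord, write_sam)
from umicall.caller import (build_pileup, call_indels, call_substitutions,
                            empirical_pvalue, read_vcf, shared_umi_cooccurrence,
                            write_vcf)
from umicall.error_model import SubstitutionErrorModel, betabinom_tail_p, q_score

REF = ("ACGTAGCTAGGATCCATGCAGTCCATGGACTTGCACCAGTAAGGCATGCATCCGGAT"
       "CTTGAACCGGTATCCGGAAGCTAGCAAT")


@pytest.fixture(scope="module")
def library():
    return ReferenceLibrary([ReferenceRecord("amp", REF, "chr1", 100, "+")])


def make_hit(name, seq, ref_start=0, cigar=None, umi=None):
    cigar = cigar or [("M", len(seq))]
    qlen = len(seq)
    n_m = sum(n for op, n in cigar if op == "M")
    aln = Alignment(score=n_m, query_start=0,
                    query_end=sum(n for op, n in cigar if op in "MI"),
                    ref_start=ref_start,
                    ref_end=ref_start + sum(n for op, n in cigar if op in "MD"),
                    cigar=cigar, n_match=n_m, n_mismatch=0, query_length=qlen)
    return AlignmentHit(name, "amp", "+", 30.0, 3.0, 0.0, aln, seq,
                        np.full(qlen, 40),
                        {"UM": umi or name, "MS": 10})


def sam_of(hits, library, tmp_path, name="x.sam"):
    path = tmp_path / name
    write_sam(hits, library, path)
    return path


class TestBuildPileup:
    def test_identical_consensuses(self, library, tmp_path):
        hits = [make_hit(f"u{i}", REF) for i in range(100)]
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        rp = pileup.references["amp"]
        assert np.all(rp.coverage == 100)
        ref_idx = [("ACGT".index(b)) for b in REF]
        alt_total = rp.base_counts.sum() - sum(
            rp.base_counts[bi, k] for k, bi in enumerate(ref_idx))
        assert alt_total == 0

    def test_three_of_hundred_substitution(self, library, tmp_path):
        pos = 17
        assert REF[pos] == "G"
        mutant = REF[:pos] + "A" + REF[pos + 1:]
        hits = ([make_hit(f"u{i}", REF) for i in range(97)]
                + [make_hit(f"m{i}", mutant) for i in range(3)])
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        rp = pileup.references["amp"]
        assert rp.coverage[pos] == 100
        assert rp.base_counts["ACGT".index("A"), pos] == 3

    def test_deletion_skips_columns(self, library, tmp_path):
        seq = REF[:20] + REF[22:]
        hits = ([make_hit(f"u{i}", REF) for i in range(9)]
                + [make_hit("d", seq,
                            cigar=[("M", 20), ("D", 2), ("M", len(REF) - 22)])])
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        rp = pileup.references["amp"]
        assert rp.deletions[(20, REF[20:22])] == 1
        assert rp.coverage[19] == 10
        assert rp.coverage[20] == 9      # deleted-over position not covered
        assert rp.coverage[22] == 10

    def test_unknown_reference_is_an_error(self, library, tmp_path):
        other = ReferenceLibrary([ReferenceRecord("other", REF)])
        path = sam_of([make_hit("u", REF[:40])], library, tmp_path, "o.sam")
        with pytest.raises(ValueError, match="unknown"):
            build_pileup(path, other)

    def test_shared_umi_counts_once_per_position(self, library, tmp_path):
        hits = [make_hit("a", REF[:50], umi="U1"),
                make_hit("b", REF[:50], umi="U1"),
                make_hit("c", REF[:50], umi="U2")]
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        assert pileup.references["amp"].coverage[0] == 2


class TestCallSubstitutions:
    def test_no_alt_no_call(self, library, tmp_path):
        hits = [make_hit(f"u{i}", REF) for i in range(20)]
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        calls = call_substitutions(
            pileup, SubstitutionErrorModel.default(), library)
        assert calls == []

    def test_q_matches_enumeration_oracle(self, library, tmp_path):
        pos = 17                      # G>A, class C>T/G>A
        mutant = REF[:pos] + "A" + REF[pos + 1:]
        hits = ([make_hit(f"u{i}", REF) for i in range(97)]
                + [make_hit(f"m{i}", mutant) for i in range(3)])
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        model = SubstitutionErrorModel.default()
        calls = call_substitutions(pileup, model, library)
        call = next(c for c in calls if c.local_pos == pos and c.alt == "A")
        a, b = model.parameters["C>T/G>A"]
        p_oracle = st.betabinom.pmf(np.arange(3, 101), 100, a, b).sum()
        assert call.q == pytest.approx(min(100.0, -10 * np.log10(p_oracle)),
                                       rel=1e-6)
        assert call.frequency == pytest.approx(0.03)
        assert call.pos == 100 + pos + 1     # BED offset + 1-based
        assert call.contig == "chr1"

    def test_multiallelic_site_one_call_per_alt(self, library, tmp_path):
        pos = 17
        m1 = REF[:pos] + "A" + REF[pos + 1:]
        m2 = REF[:pos] + "T" + REF[pos + 1:]
        hits = ([make_hit(f"u{i}", REF) for i in range(40)]
                + [make_hit("a", m1), make_hit("t", m2)])
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        calls = call_substitutions(
            pileup, SubstitutionErrorModel.default(), library)
        alts = {c.alt for c in calls if c.local_pos == pos}
        assert alts == {"A", "T"}


class TestCallIndels:
    def test_deletion_reported_without_quality(self, library, tmp_path):
        seq = REF[:20] + REF[35:]         # 15-base deletion
        hits = ([make_hit(f"u{i}", REF) for i in range(99)]
                + [make_hit("d", seq,
                            cigar=[("M", 20), ("D", 15), ("M", len(REF) - 35)])])
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        calls = call_indels(pileup, library)
        assert len(calls) == 1
        c = calls[0]
        assert c.kind == "deletion" and c.q is None
        assert c.filter == "NO_QUAL"
        assert c.frequency == pytest.approx(0.01)
        assert len(c.ref) - len(c.alt) == 15

    def test_no_indels_empty(self, library, tmp_path):
        hits = [make_hit(f"u{i}", REF) for i in range(5)]
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        assert call_indels(pileup, library) == []

    def test_left_normalization(self, library, tmp_path):
        # delete one G of the GG at positions 9-10: canonical start is 9
        assert REF[9:11] == "GG"
        seq = REF[:10] + REF[11:]
        hits = [make_hit("d", seq,
                         cigar=[("M", 10), ("D", 1), ("M", len(REF) - 11)]),
                make_hit("u", REF)]
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        call = call_indels(pileup, library)[0]
        assert call.pos == 100 + 9       # anchor at local_pos 8 (1-based 9+100)
        assert call.ref == REF[8:10] and call.alt == REF[8]


class TestEmpiricalPvalue:
    def _calls(self, freqs, cls="C>T/G>A"):
        from umicall.caller import VariantCall
        return [VariantCall("c", i + 1, "G", "A", "substitution", f,
                            int(f * 1000), 1000, 50.0, cls)
                for i, f in enumerate(freqs)]

    def test_single_call_p_one(self):
        calls = empirical_pvalue(self._calls([0.01]))
        assert calls[0].empirical_p == 1.0

    def test_top_of_hundred(self):
        freqs = [0.001 * (i + 1) for i in range(100)]
        calls = empirical_pvalue(self._calls(freqs))
        assert max(calls, key=lambda c: c.frequency).empirical_p == 0.01

    def test_rank_within_class_only(self):
        a = self._calls([0.1, 0.2], cls="C>T/G>A")
        b = self._calls([0.5], cls="A>T/T>A")
        calls = empirical_pvalue(a + b)
        assert calls[2].empirical_p == 1.0


class TestVcf:
    def _full_calls(self, library, tmp_path):
        pos = 17
        mutant = REF[:pos] + "A" + REF[pos + 1:]
        dels = REF[:20] + REF[35:]
        hits = ([make_hit(f"u{i}", REF) for i in range(50)]
                + [make_hit("m", mutant)]
                + [make_hit("d", dels,
                            cigar=[("M", 20), ("D", 15), ("M", len(REF) - 35)])])
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        calls = call_substitutions(
            pileup, SubstitutionErrorModel.default(), library)
        calls = empirical_pvalue(calls)
        return calls + call_indels(pileup, library), pileup

    def test_round_trip(self, library, tmp_path):
        calls, _ = self._full_calls(library, tmp_path)
        path = tmp_path / "out.vcf"
        write_vcf(calls, path, library)
        loaded = read_vcf(path)
        assert len(loaded) == len(calls)
        orig = sorted((c.contig, c.pos, c.ref, c.alt) for c in calls)
        back = sorted((c.contig, c.pos, c.ref, c.alt) for c in loaded)
        assert orig == back
        by_key = {(c.contig, c.pos, c.ref, c.alt): c for c in loaded}
        for c in calls:
            lc = by_key[(c.contig, c.pos, c.ref, c.alt)]
            assert lc.count == c.count and lc.coverage == c.coverage
            assert lc.frequency == pytest.approx(c.frequency, rel=1e-4)

    def test_byte_identical_output(self, library, tmp_path):
        calls, _ = self._full_calls(library, tmp_path)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(calls, p1, library)
        write_vcf(list(reversed(calls)), p2, library)
        assert p1.read_bytes() == p2.read_bytes()


class TestCooccurrence:
    def test_shared_umi_pairs_reported(self, library, tmp_path):
        p1, p2 = 17, 40
        double = REF[:p1] + "A" + REF[p1 + 1:p2] + "C" + REF[p2 + 1:]
        assert REF[p2] != "C"
        hits = ([make_hit(f"u{i}", REF) for i in range(20)]
                + [make_hit(f"dbl{i}", double) for i in range(3)])
        pileup = build_pileup(sam_of(hits, library, tmp_path), library)
        calls = call_substitutions(
            pileup, SubstitutionErrorModel.default(), library)
        rows = shared_umi_cooccurrence(pileup, calls)
        assert any(r["shared_umis"] == 3 for r in rows)
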