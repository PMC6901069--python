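import numpy as np
import pytest
from hypothesis import given, strategies as st

import tagcascade as tc
from tagcascade.read_qc import (
    MergeParams, PrimerSpec, QCParams, ScreenParams, canonical_kmers,
)
from tagcascade.seq_io import reverse_complement

from conftest import random_dna


def rec(seq, ident="r", qual=None):
    if qual is None:
        qual = [35] * len(seq)
    return tc.SeqRecord(ident, seq, qual)


class TestScreen:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.phix = tc.SeqRecord("phix", random_dna(rng, 400))
        self.adapter = tc.SeqRecord("ad", random_dna(rng, 60))

    def test_read_with_phix_kmer_goes_to_phix(self):
        rng = np.random.default_rng(2)
        read = rec(random_dna(rng, 100) + self.phix.seq[50:71] + random_dna(rng, 50))
        res = tc.screen_contaminants([read], [self.phix], [self.adapter])
        assert res.counts["phix"] == 1 and res.counts["kept"] == 0

    def test_random_read_kept_when_no_shared_kmer(self):
        # oracle: explicitly enumerate shared canonical k-mers first
        rng = np.random.default_rng(3)
        read = rec(random_dna(rng, 150))
        refs = canonical_kmers(self.phix.seq, 21) | canonical_kmers(self.adapter.seq, 21)
        assert not (canonical_kmers(read.seq, 21) & refs)
        res = tc.screen_contaminants([read], [self.phix], [self.adapter])
        assert res.counts["kept"] == 1

    def test_adapter_read_flagged_contaminant(self):
        rng = np.random.default_rng(4)
        read = rec(self.adapter.seq + random_dna(rng, 100))
        res = tc.screen_contaminants([read], [self.phix], [self.adapter])
        assert res.counts["contaminant"] == 1

    def test_reverse_complement_still_detected(self):
        read = rec(reverse_complement(self.phix.seq[100:200]))
        res = tc.screen_contaminants([read], [self.phix], [self.adapter])
        assert res.counts["phix"] == 1

    def test_short_read_kept_and_counted(self):
        res = tc.screen_contaminants([rec("ACGTACGTACGTACG")], [self.phix], [self.adapter])
        assert res.counts["too_short_to_screen"] == 1 and res.counts["kept"] == 1

    @given(st.integers(0, 2**31 - 1))
    def test_bucket_counts_conserve_input(self, seed):
        rng = np.random.default_rng(seed)
        reads = [rec(random_dna(rng, int(rng.integers(15, 120))), f"r{i}")
                 for i in range(20)]
        res = tc.screen_contaminants(reads, [self.phix], [self.adapter])
        assert (res.counts["kept"] + res.counts["contaminant"] + res.counts["phix"]
                == res.counts["total"] == 20)


class TestSyncPairs:
    def test_intersection_kept_in_r1_order(self):
        r1 = [rec("AAAA", i) for i in ("a", "b", "c")]
        r2 = [rec("TTTT", i) for i in ("b", "c", "d")]
        pairs, orphans = tc.sync_pairs(r1, r2)
        assert [p[0].id for p in pairs] == ["b", "c"]
        assert orphans == 2

    def test_identical_sets_no_orphans(self):
        r1 = [rec("AAAA", "x"), rec("CCCC", "y")]
        pairs, orphans = tc.sync_pairs(r1, r1)
        assert len(pairs) == 2 and orphans == 0

    def test_mate_suffixes_stripped(self):
        pairs, orphans = tc.sync_pairs([rec("AAAA", "x/1")], [rec("TTTT", "x/2")])
        assert len(pairs) == 1 and orphans == 0

    def test_duplicate_id_raises(self):
        with pytest.raises(ValueError, match="x"):
            tc.sync_pairs([rec("AAAA", "x"), rec("CCCC", "x")], [rec("TTTT", "x")])


class TestTrimFixed:
    def test_trims_three_prime(self):
        out = tc.trim_fixed(rec("A" * 250), 200)
        assert len(out.seq) == 200 and len(out.qual) == 200

    def test_short_read_discarded_not_padded(self):
        assert tc.trim_fixed(rec("A" * 150), 200) is None

    def test_exact_length_is_identity(self):
        r = rec("ACGT" * 50)
        out = tc.trim_fixed(r, 200)
        assert out.seq == r.seq and out.qual == r.qual


class TestMergePairs:
    def _pair(self, rng, len1=100, len2=100, overlap=20):
        frag = random_dna(rng, len1 + len2 - overlap)
        f = rec(frag[:len1], "p")
        r = tc.SeqRecord("p", reverse_complement(frag[-len2:]), [35] * len2)
        return f, r, frag

    def test_perfect_overlap_length_arithmetic(self):
        rng = np.random.default_rng(5)
        f, r, frag = self._pair(rng)
        merged = tc.merge_pairs(f, r)
        assert merged is not None and merged.seq == frag and len(merged.seq) == 180

    def test_disjoint_reads_unmerged(self):
        # oracle: confirm every candidate overlap exceeds the mismatch ratio
        rng = np.random.default_rng(6)
        f, r = rec(random_dna(rng, 80), "q"), rec(random_dna(rng, 80), "q")
        rr = reverse_complement(r.seq)
        params = MergeParams(min_overlap=10)
        ratios = [
            sum(a != b for a, b in zip(f.seq[-o:], rr[:o])) / o
            for o in range(10, 81)
        ]
        assert min(ratios) > params.max_mismatch_ratio
        assert tc.merge_pairs(f, r, params) is None

    def test_mismatch_resolved_by_higher_quality(self):
        rng = np.random.default_rng(7)
        f, r, frag = self._pair(rng)
        # corrupt one overlap base on the forward read, with low quality
        pos = 90
        wrong = {"A": "C", "C": "G", "G": "T", "T": "A"}[f.seq[pos]]
        fq = list(f.qual)
        fq[pos] = 5
        f2 = tc.SeqRecord("p", f.seq[:pos] + wrong + f.seq[pos + 1:], fq)
        merged = tc.merge_pairs(f2, r)
        assert merged is not None
        assert merged.seq == frag  # reverse read (Q35) wins the dispute
        assert merged.qual[pos] == 35

    def test_quality_tie_favors_forward(self):
        rng = np.random.default_rng(8)
        f, r, frag = self._pair(rng)
        pos = 90
        wrong = {"A": "C", "C": "G", "G": "T", "T": "A"}[f.seq[pos]]
        f2 = tc.SeqRecord("p", f.seq[:pos] + wrong + f.seq[pos + 1:], f.qual)
        merged = tc.merge_pairs(f2, r)
        assert merged.seq[pos] == wrong

    @given(st.integers(0, 2**31 - 1), st.integers(15, 60))
    def test_merged_length_arithmetic(self, seed, overlap):
        rng = np.random.default_rng(seed)
        f, r, frag = self._pair(rng, 80, 80, overlap)
        merged = tc.merge_pairs(f, r)
        if merged is not None and len(merged.seq) == len(frag):
            assert merged.seq == frag


class TestHandlePrimers:
    spec = PrimerSpec(forward="GTGCCAGCAGCCGCGGTAA", reverse="GGACTACAGGGGTATCTAAT")

    def _insert(self, seed=9, n=120):
        return random_dna(np.random.default_rng(seed), n)

    def test_forward_primer_removed(self):
        insert = self._insert()
        read = rec(self.spec.forward + insert)
        assert tc.handle_primers(read, self.spec).seq == insert

    def test_reverse_complemented_read_reoriented(self):
        insert = self._insert(10)
        read = rec(reverse_complement(self.spec.forward + insert))
        out = tc.handle_primers(read, self.spec, orient=True)
        assert out is not None and out.seq == insert

    def test_absent_primer_discards(self):
        assert tc.handle_primers(rec(self._insert(11)), self.spec, orient=True) is None

    def test_reverse_primer_clipped_from_three_prime(self):
        insert = self._insert(12)
        read = rec(self.spec.forward + insert + reverse_complement(self.spec.reverse))
        assert tc.handle_primers(read, self.spec).seq == insert

    def test_primer_outside_window_not_found(self):
        insert = self._insert(13)
        read = rec("A" * 40 + self.spec.forward + insert)
        assert tc.handle_primers(read, self.spec) is None

    def test_degenerate_positions_match(self):
        spec = PrimerSpec(forward="GTGYCAGCMGCCGCGGTAA", max_mismatches=0)
        insert = self._insert(14)
        read = rec("GTGTCAGCAGCCGCGGTAA" + insert)
        assert tc.handle_primers(read, spec).seq == insert


class TestQualityFilter:
    def test_good_read_passes(self):
        ok, reason = tc.quality_filter(rec("ACGT" * 25, qual=[40] * 100))
        assert ok and reason is None

    def test_low_average_quality(self):
        ok, reason = tc.quality_filter(rec("ACGT" * 25, qual=[20] * 100))
        assert not ok and reason == "avg_q"

    def test_too_many_n(self):
        ok, reason = tc.quality_filter(rec("NN" + "ACGT" * 25, qual=[40] * 102))
        assert not ok and reason == "too_many_n"

    def test_single_n_allowed_by_default(self):
        ok, _ = tc.quality_filter(rec("N" + "ACGT" * 25, qual=[40] * 101))
        assert ok

    def test_max_n_zero_rejects_single_n(self):
        ok, reason = tc.quality_filter(
            rec("N" + "ACGT" * 25, qual=[40] * 101), QCParams(max_n=0)
        )
        assert not ok and reason == "too_many_n"

    def test_six_bases_below_q15_fail(self):
        # 94 x Q30 + 6 x Q14: mean 29.04 >= 27, but 6 > 5 low-quality bases
        qual = [30] * 94 + [14] * 6
        assert float(np.mean(qual)) >= 27
        ok, reason = tc.quality_filter(rec("ACGT" * 25, qual=qual))
        assert not ok and reason == "low_q_bases"

    def test_five_bases_below_q15_pass(self):
        ok, _ = tc.quality_filter(rec("ACGT" * 25, qual=[30] * 95 + [14] * 5))
        assert ok

    def test_reason_order_avg_q_first(self):
        ok, reason = tc.quality_filter(rec("NN" + "ACGT" * 25, qual=[10] * 102))
        assert not ok and reason == "avg_q"

    def test_missing_qualities_error(self):
        with pytest.raises(ValueError):
            tc.quality_filter(tc.SeqRecord("r", "ACGT"))

    def test_pure_predicate(self):
        r = rec("ACGT" * 25, qual=[28] * 100)
        assert tc.quality_filter(r) == tc.quality_filter(r)
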