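import numpy as np
import pytest
from hypothesis import given, strategies as st

import tagcascade as tc
from tagcascade.clustering import CascadeParams, DerepSeq

from conftest import random_dna
from oracles import greedy_cluster_oracle, identity_oracle


def reads(*seqs):
    return [tc.SeqRecord(f"r{i}", s) for i, s in enumerate(seqs)]


def mutate(seq, rng, n_subs):
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for p in pos:
        chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
    return "".join(chars)


class TestDereplicate:
    def test_collapses_exact_duplicates(self):
        out = tc.dereplicate(reads("ACGT", "ACGT", "ACGA"))
        assert [(d.seq, d.size) for d in out] == [("ACGT", 2), ("ACGA", 1)]

    def test_all_distinct(self):
        rng = np.random.default_rng(0)
        rs = reads(*(random_dna(rng, 30) for _ in range(10)))
        out = tc.dereplicate(rs)
        assert len(out) == 10 and all(d.size == 1 for d in out)

    def test_empty(self):
        assert tc.dereplicate([]) == []

    @given(st.lists(st.sampled_from(["AAAA", "CCCC", "GGGG", "ACGT", "TTTT"]),
                    max_size=40))
    def test_sizes_conserve_and_sorted(self, seqs):
        out = tc.dereplicate(reads(*seqs))
        assert sum(d.size for d in out) == len(seqs)
        keys = [(-d.size, d.seq) for d in out]
        assert keys == sorted(keys)
        assert all(len(d.member_ids) == d.size for d in out)


class TestIdentity:
    def test_self_identity(self):
        assert tc.identity("ACGTACGTAC", "ACGTACGTAC") == 1.0

    def test_one_substitution_in_fifty(self):
        rng = np.random.default_rng(1)
        a = random_dna(rng, 50)
        b = mutate(a, rng, 1)
        assert tc.identity(a, b) == pytest.approx(0.98)

    def test_terminal_gaps_free(self):
        # a shorter fragment contained in a longer sequence is 100% identical
        rng = np.random.default_rng(2)
        long = random_dna(rng, 120)
        assert tc.identity(long[20:80], long) == 1.0

    @given(st.integers(0, 2**31 - 1))
    def test_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, int(rng.integers(20, 90)))
        if rng.random() < 0.5:
            b = mutate(a, rng, int(rng.integers(0, 6)))
            if rng.random() < 0.5:
                b = b[int(rng.integers(0, 5)):len(b) - int(rng.integers(0, 5))]
        else:
            b = random_dna(rng, int(rng.integers(20, 90)))
        assert tc.identity(a, b) == pytest.approx(identity_oracle(a, b))
        assert tc.identity(a, b) == pytest.approx(tc.identity(b, a))


class TestGreedyCluster:
    def test_similar_pair_joins_first_centroid(self):
        rng = np.random.default_rng(3)
        s = random_dna(rng, 50)
        s2 = mutate(s, rng, 1)
        assert identity_oracle(s, s2) == pytest.approx(0.98)
        out = tc.greedy_cluster(
            [DerepSeq(seq=s, size=10), DerepSeq(seq=s2, size=5)], 0.97
        )
        assert len(out) == 1 and out[0].abundance == 15

    def test_threshold_one_keeps_distinct_separate(self):
        rng = np.random.default_rng(4)
        inputs = sorted(
            (DerepSeq(seq=random_dna(rng, 40), size=1) for _ in range(6)),
            key=lambda d: (-d.size, d.seq),
        )
        out = tc.greedy_cluster(inputs, 1.0)
        assert len(out) == len({d.seq for d in inputs})

    def test_empty_input(self):
        assert tc.greedy_cluster([], 0.97) == []

    def test_members_reach_threshold_to_centroid(self):
        rng = np.random.default_rng(5)
        base = random_dna(rng, 60)
        inputs = [DerepSeq(seq=base, size=50)] + [
            DerepSeq(seq=mutate(base, rng, 1), size=1) for _ in range(8)
        ]
        inputs.sort(key=lambda d: (-d.size, d.seq))
        for cl in tc.greedy_cluster(inputs, 0.97):
            for m in cl.members:
                assert tc.identity(m.seq, cl.centroid.seq) >= 0.97

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        templates = [random_dna(rng, 60) for _ in range(3)]
        entries = []
        for i in range(24):
            t = templates[int(rng.integers(3))]
            entries.append((mutate(t, rng, int(rng.integers(0, 4))),
                            int(rng.integers(1, 20))))
        entries.sort(key=lambda e: (-e[1], e[0]))
        inputs = [DerepSeq(seq=s, size=n) for s, n in entries]
        ours = tc.greedy_cluster(inputs, 0.95)
        theirs = greedy_cluster_oracle(entries, 0.95)
        pos = {id(d): i for i, d in enumerate(inputs)}
        ours_members = [
            sorted(pos[id(m)] for m in cl.members) for cl in ours
        ]
        assert ours_members == [sorted(c) for c in theirs]


class TestCascade:
    def test_error_free_even_mock_recovers_all_templates(self):
        rng = np.random.default_rng(6)
        templates = tc.generate_templates(20, 250, 0.10, seed=1)
        rs = []
        for t in templates:
            rs += [tc.SeqRecord(f"{t.record.id}.{i}", t.record.seq) for i in range(50)]
        final, counts = tc.run_cascade(rs, CascadeParams(min_cluster_size=25))
        assert len(final) == 20
        assert counts["clustered_reads"] == len(rs)

    def test_abundance_below_floor_dropped(self):
        rs = [tc.SeqRecord(f"r{i}", "ACGTACGT" * 8) for i in range(24)]
        final, counts = tc.run_cascade(rs, CascadeParams(min_cluster_size=25))
        assert final == [] and counts["final_clusters"] == 0

    def test_abundance_at_floor_kept(self):
        rs = [tc.SeqRecord(f"r{i}", "ACGTACGT" * 8) for i in range(25)]
        final, _ = tc.run_cascade(rs, CascadeParams(min_cluster_size=25))
        assert len(final) == 1

    def test_pacbio_mode_floor_two(self):
        rng = np.random.default_rng(7)
        a, b = random_dna(rng, 200), random_dna(rng, 200)
        rs = reads(a, a, b)  # b is a singleton
        final, counts = tc.run_cascade(
            rs, CascadeParams(pacbio_mode=True, pacbio_min_size=2)
        )
        assert len(final) == 1 and final[0].abundance == 2

    def test_abundance_conservation_before_size_filter(self):
        rng = np.random.default_rng(8)
        base = random_dna(rng, 80)
        rs = reads(*(mutate(base, rng, int(rng.integers(0, 3))) for _ in range(40)))
        derep = tc.dereplicate(rs)
        clusters = tc.greedy_cluster(derep, 0.99)
        assert sum(cl.abundance for cl in clusters) == len(rs)

    def test_stage_counts_monotone(self):
        rng = np.random.default_rng(9)
        templates = tc.generate_templates(5, 150, 0.1, seed=2)
        rs = []
        for t in templates:
            rs += [tc.SeqRecord(f"{t.record.id}.{i}", mutate(t.record.seq, rng, int(rng.integers(0, 2))))
                   for i in range(40)]
        _, counts = tc.run_cascade(rs, CascadeParams(min_cluster_size=25))
        assert (counts["input_reads"] >= counts["reads_after_size_filter"]
                >= counts["clustered_reads"])


class TestFilterAsvTable:
    def test_total_abundance_boundary(self):
        rng = np.random.default_rng(10)
        feats = [
            (random_dna(rng, 60), {"s1": 20, "s2": 10}),   # 30 kept
            (random_dna(rng, 60), {"s1": 25}),             # 25 kept
            (random_dna(rng, 60), {"s1": 24}),             # 24 dropped
        ]
        out = tc.filter_asv_table(feats, min_total=25)
        assert [f[0] for f in out] == [feats[0][0], feats[1][0]]

    def test_injected_chimera_removed(self):
        rng = np.random.default_rng(11)
        templates = tc.generate_templates(4, 200, 0.12, seed=3)
        a, b = templates[0].record.seq, templates[1].record.seq
        chim = a[:100] + b[100:]
        feats = [(a, {"s": 500}), (b, {"s": 400}),
                 (templates[2].record.seq, {"s": 300}), (chim, {"s": 30})]
        out = tc.filter_asv_table(feats, min_total=25)
        assert chim not in [f[0] for f in out]
        assert a in [f[0] for f in out] and b in [f[0] for f in out]

    def test_empty_input(self):
        assert tc.filter_asv_table([], min_total=25) == []
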