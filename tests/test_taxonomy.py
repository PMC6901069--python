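from itertools import product

import numpy as np
import pytest

import tagcascade as tc
from tagcascade.taxonomy import (
    DEFAULT_RANKS, Classification, _words, deconflict_lineages,
    parse_lineage_string,
)

from conftest import random_dna


def lineage(*names):
    return tc.Lineage(DEFAULT_RANKS, tuple(names))


@pytest.fixture(scope="module")
def two_genus_fixture():
    """Two well-separated genera (~20% divergent), three references each."""
    rng = np.random.default_rng(30)
    templates = tc.generate_templates(2, 300, 0.20, seed=31)
    refs = []
    for t in templates:
        for k in range(3):
            # light within-genus variation
            chars = list(t.record.seq)
            for p in rng.choice(300, size=3, replace=False):
                chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
            refs.append((tc.SeqRecord(f"{t.record.id}.{k}", "".join(chars)), t.lineage))
    ts = tc.build_training_set(refs)
    return refs, ts


class TestDeconflict:
    def test_shared_genus_name_suffixed_by_parent(self):
        lins = [
            lineage("Bacteria", "P1", "C1", "O1", "FamA", "Clostridium"),
            lineage("Bacteria", "P1", "C1", "O1", "FamB", "Clostridium"),
        ]
        out = deconflict_lineages(lins)
        assert out[0].names[-1] == "Clostridium_FamA"
        assert out[1].names[-1] == "Clostridium_FamB"

    def test_empty_rank_filled_with_parent_unclassified(self):
        lins = [lineage("Bacteria", "P1", "C1", "O1", "F1", "")]
        out = deconflict_lineages(lins)
        assert out[0].names[-1] == "F1_unclassified"

    def test_no_name_under_two_parents_after(self):
        rng = np.random.default_rng(32)
        lins = [
            lineage("Bacteria", f"P{i%3}", f"C{i%4}", f"O{i%5}", f"F{i%2}", f"G{i%6}")
            for i in range(30)
        ]
        out = deconflict_lineages(lins)
        for r in range(1, 6):
            parents = {}
            for l in out:
                parents.setdefault(l.names[r], set()).add(l.names[:r])
            assert all(len(p) == 1 for p in parents.values())


class TestBuildTrainingSet:
    def test_reference_words_present_in_own_leaf(self, two_genus_fixture):
        refs, ts = two_genus_fixture
        for rec, lin_str in refs:
            leaf = ts.leaf_lineages[parse_lineage_string(lin_str).names[-1]].names[-1]
            row = ts.leaves.index(leaf)
            for word in _words(rec.seq, ts.word_size):
                assert ts.presence[row, ts.word_index[word]] >= 1

    def test_conditional_probabilities_in_unit_interval(self, two_genus_fixture):
        _, ts = two_genus_fixture
        probs = (ts.presence + 1.0) / (ts.leaf_sizes[:, None] + 2.0)
        assert np.all(probs > 0) and np.all(probs <= 1)

    def test_missing_lineage_skipped_with_warning(self, caplog):
        refs = [
            (tc.SeqRecord("a", "ACGTACGTACGT" * 4), "Bacteria;P;C;O;F;G"),
            (tc.SeqRecord("b", "TTTTACGTACGT" * 4), ""),
        ]
        with caplog.at_level("WARNING"):
            ts = tc.build_training_set(refs)
        assert sum(ts.leaf_sizes) == 1

    def test_rank_count_mismatch_names_record(self):
        with pytest.raises(ValueError, match="bad_rec"):
            tc.build_training_set(
                [(tc.SeqRecord("bad_rec", "ACGT" * 10), "Bacteria;OnlyTwo")]
            )


class TestClassify:
    def test_training_sequences_self_classify_with_full_confidence(
        self, two_genus_fixture
    ):
        refs, ts = two_genus_fixture
        for rec, lin_str in refs:
            c = tc.classify(rec.seq, ts, seed=5)
            expected = parse_lineage_string(lin_str)
            assert c.names == expected.names
            assert all(conf == 1.0 for conf in c.confidences)

    def test_sequence_shorter_than_word_errors(self, two_genus_fixture):
        _, ts = two_genus_fixture
        with pytest.raises(ValueError):
            tc.classify("ACGTACG", ts)

    def test_all_ambiguous_sequence_errors(self, two_genus_fixture):
        _, ts = two_genus_fixture
        with pytest.raises(ValueError):
            tc.classify("N" * 50, ts)

    def test_mosaic_splits_genus_confidence_but_not_kingdom(self):
        # exactly balanced fixture: the two genera differ at evenly spaced
        # positions, so a midpoint mosaic carries equal evidence per half;
        # residual bias comes from the deterministic lexicographic tie-break
        rng = np.random.default_rng(40)
        base = "".join(rng.choice(list("ACGT"), size=320))
        chars = list(base)
        for p in range(8, 320, 16):
            chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
        other = "".join(chars)
        ts = tc.build_training_set([
            (tc.SeqRecord("a", base), "Bacteria;P1;C1;O1;F1;GenA"),
            (tc.SeqRecord("b", other), "Bacteria;P2;C2;O2;F2;GenB"),
        ])
        c = tc.classify(base[:160] + other[160:], ts, n_bootstrap=200, seed=2)
        assert c.confidences[0] == 1.0  # kingdom shared
        assert abs(c.confidences[-1] - 0.5) <= 0.15

    def test_confidences_monotone_on_random_queries(self, two_genus_fixture):
        _, ts = two_genus_fixture
        rng = np.random.default_rng(33)
        for _ in range(50):
            c = tc.classify(random_dna(rng, 120), ts, n_bootstrap=50, seed=rng)
            assert all(
                a >= b for a, b in zip(c.confidences, c.confidences[1:])
            )

    def test_deterministic_under_fixed_seed(self, two_genus_fixture):
        _, ts = two_genus_fixture
        rng = np.random.default_rng(34)
        q = random_dna(rng, 200)
        c1 = tc.classify(q, ts, seed=77)
        c2 = tc.classify(q, ts, seed=77)
        assert c1 == c2


class TestReconstructLineage:
    RANKS = DEFAULT_RANKS

    def _cls(self, confs):
        names = tuple(f"n{i}" for i in range(len(confs)))
        return Classification(self.RANKS[: len(confs)], names, tuple(confs), 100)

    def test_prefix_kept_through_order(self):
        lin = tc.reconstruct_lineage(self._cls((1.0, 0.99, 0.8, 0.6, 0.4, 0.3)))
        assert len(lin) == 4 and lin.ranks[-1] == "order"

    def test_full_lineage_when_all_pass(self):
        assert len(tc.reconstruct_lineage(self._cls((1.0,) * 6))) == 6

    def test_unclassified_when_kingdom_below_cutoff(self):
        assert len(tc.reconstruct_lineage(self._cls((0.4, 0.9, 0.9, 0.9, 0.9, 0.9)))) == 0

    def test_later_rank_rebound_still_dropped(self):
        lin = tc.reconstruct_lineage(self._cls((1.0, 0.4, 0.9, 0.9, 0.9, 0.9)))
        assert len(lin) == 1

    def test_exhaustive_maximal_qualifying_prefix(self):
        for confs in product((0.3, 0.5, 0.7), repeat=6):
            lin = tc.reconstruct_lineage(self._cls(confs))
            k = len(lin)
            assert all(c >= 0.5 for c in confs[:k])
            assert k == 6 or confs[k] < 0.5
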