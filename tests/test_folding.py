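import math

import numpy as np
import pytest

from backfold import (
    FoldParams,
    dbf,
    enumerate_structures,
    pair_probabilities,
    pair_probabilities_global,
    pair_probabilities_local,
    pairedness_profile,
)
from backfold.folding import BuiltinEngine, PairProbMatrix
from backfold.sequence_io import reverse_complement

BASES = np.array(list("ACGT"))


def random_seq(rng, n, alphabet="ACGT"):
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(len(letters), size=n)])


class TestGlobalFolding:
    def test_unpairable_homopolymer_is_zero(self):
        m = pair_probabilities_global("AAAAAAA")
        assert m.toarray().sum() == 0.0

    def test_min_hairpin_forbids_short_spans(self):
        # ACGU: only potential pair G-U etc., but all spans < 4
        m = pair_probabilities_global("ACGT")
        assert m.toarray().sum() == 0.0

    def test_two_structure_closed_form(self):
        # GAAAC: open chain vs the single G-C pair, weight e^3
        m = pair_probabilities_global("GAAAC")
        expected = math.exp(3) / (1 + math.exp(3))
        assert m.get(0, 4) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle_on_hairpin(self):
        dp = pair_probabilities_global("GGGAAAACCC").toarray()
        oracle = enumerate_structures("GGGAAAACCC").toarray()
        assert np.abs(dp - oracle).max() < 1e-9

    def test_accepts_rna_alphabet(self):
        assert pair_probabilities_global("GAAAC").get(0, 4) == pytest.approx(
            pair_probabilities_global("GAAAC".replace("T", "U")).get(0, 4)
        )

    def test_rejects_ambiguous_base(self):
        with pytest.raises(ValueError):
            pair_probabilities_global("GANAC")


class TestEnumerationOracle:
    def test_refuses_long_sequences(self):
        with pytest.raises(ValueError):
            enumerate_structures("A" * 26)

    def test_open_chain_only_for_unpairable(self):
        m = enumerate_structures("AAAAA")
        assert m.toarray().sum() == 0.0

    def test_dp_equivalence_on_random_sequences(self):
        # smoke-scale version of the full equivalence check in acceptance
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(25):
            seq = random_seq(rng, int(rng.integers(8, 21)))
            dev = np.abs(
                pair_probabilities_global(seq).toarray()
                - enumerate_structures(seq).toarray()
            ).max()
            worst = max(worst, dev)
        assert worst < 1e-9


class TestProfileAndDbf:
    def test_zero_matrix_zero_profile(self):
        prof = pairedness_profile(pair_probabilities_global("AAAAAAA"))
        assert prof.sum() == 0.0
        assert dbf(prof) == 0.0

    def test_single_pair_profile_symmetry(self):
        band = np.zeros((5, 4))
        band[1, 2] = 0.9  # pair (1, 4)
        prof = pairedness_profile(PairProbMatrix(band))
        assert prof.tolist() == [0.0, 0.9, 0.0, 0.0, 0.9]

    def test_profile_equals_oracle_row_sums(self):
        m = enumerate_structures("GGGAAAACCC")
        assert np.allclose(pairedness_profile(m), m.toarray().sum(0) + m.toarray().sum(1))

    def test_dbf_is_mean_pairedness(self):
        assert dbf(np.array([1.0, 1.0, 0.0, 0.0])) == 0.5
        m = enumerate_structures("GAAAC")
        assert dbf(pairedness_profile(m)) == pytest.approx(2 * m.get(0, 4) / 5)

    def test_global_profile_beyond_one_raises(self):
        band = np.zeros((5, 4))
        band[0, 3] = 0.7
        band[0, 2] = 0.7  # position 0 "paired" with prob 1.4
        with pytest.raises(ArithmeticError):
            pairedness_profile(PairProbMatrix(band, windowed=False))
        # windowed matrices are exempt (window averaging is a mixture)
        assert pairedness_profile(PairProbMatrix(band, windowed=True))[0] == pytest.approx(1.4)

    def test_dbf_rejects_empty_profile(self):
        with pytest.raises(ValueError):
            dbf(np.array([]))


class TestLocalFolding:
    def test_dispatcher_routes_short_to_global(self):
        seq = "GGGAAAACCC"
        m = pair_probabilities(seq)  # length 10 < threshold 100
        assert not m.windowed
        assert np.allclose(m.toarray(), pair_probabilities_global(seq).toarray())

    def test_homopolymer_windowed_all_zero(self):
        m = pair_probabilities_local("A" * 150)
        assert m.windowed
        assert m.band.sum() == 0.0

    def test_shorter_than_window_falls_back_to_global(self):
        with pytest.warns(UserWarning, match="global"):
            m = pair_probabilities_local("GGGAAAACCC")
        assert not m.windowed

    def test_window_agreement_at_window_length(self):
        # a window-length sequence has exactly one window: local == global
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 100)
        local = pair_probabilities_local(seq)
        glob = pair_probabilities_global(seq)
        n = len(seq)
        for d in range(1, 100):
            assert np.allclose(local.band[: n - d, d - 1], glob.band[: n - d, d - 1], atol=1e-9)

    def test_pairs_spanning_beyond_window_are_zero(self):
        # complementary decamers 110 nt apart: global folds them, local cannot
        stem1, stem2 = "GGGGGGGGGG", "CCCCCCCCCC"
        spacer = "A" * 100
        seq = stem1 + spacer + stem2  # length 120, span of the stem pair ~110
        params = FoldParams()
        local = pair_probabilities_local(seq, params)
        assert local.band.sum() == 0.0  # nothing pairable within any window
        glob = pair_probabilities_global(seq, params)
        assert glob.toarray().sum() > 1.0  # global mode finds the distant stem


class TestInvariantProperties:
    def test_row_sums_bounded_in_global_mode(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            seq = random_seq(rng, int(rng.integers(30, 90)))
            q = pairedness_profile(pair_probabilities_global(seq))
            assert q.min() >= 0.0 and q.max() <= 1.0

    def test_inserting_complementary_repeat_never_decreases_dbf(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            base = random_seq(rng, 40, alphabet="ACT")  # weakly structured
            engine = BuiltinEngine()
            before = engine.dbf(base)
            stem = "GGGGGGGG" + "AAAA" + "CCCCCCCC"
            after = engine.dbf(base[:20] + stem + base[20:])
            assert after >= before

    def test_reverse_complement_symmetry_without_gu(self):
        # over {A,T} or {G,C} alone, reverse complement preserves the pair set
        rng = np.random.default_rng(9)
        for alphabet in ("AT", "GC"):
            seq = random_seq(rng, 30, alphabet=alphabet)
            prof = pairedness_profile(pair_probabilities_global(seq))
            rc = pairedness_profile(pair_probabilities_global(reverse_complement(seq)))
            assert np.allclose(prof, rc[::-1], atol=1e-9)


class TestBatchedEngine:
    def test_dbf_many_matches_scalar_path(self):
        rng = np.random.default_rng(2)
        seqs = [random_seq(rng, 60) for _ in range(5)]
        engine = BuiltinEngine()
        batched = engine.dbf_many(seqs)
        scalar = [engine.dbf(s) for s in seqs]
        assert np.allclose(batched, scalar, atol=1e-12)

    def test_dbf_many_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            BuiltinEngine().dbf_many(["ACGT" * 5, "ACGT"])
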