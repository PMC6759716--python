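"""The 473-feature extractor: block formulas, layout, and invariants."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antioxpred import (
    N_FEATURES,
    ProfileFeaturizer,
    PSSMProfile,
    SSProfile,
    ValidationError,
    extract_features,
)
from antioxpred.features import (
    ONE_GRAM_WEIGHT,
    TWO_GRAM_WEIGHT,
    assemble_feature_vector,
    compute_feature_vector,
    compute_fpssm,
    compute_frequency_matrix,
    compute_one_gram,
    compute_prob_features,
    compute_ss_sequence_features,
    compute_two_gram,
    derive_consensus,
    segment_sequence,
    weight_ngrams,
)
from antioxpred.types import ProteinRecord


def pssm(scores, seq=None):
    scores = np.asarray(scores, dtype=float)
    return PSSMProfile("x", scores, sequence=seq or "A" * scores.shape[0])


def random_profiles(rng, L):
    scores = rng.integers(-8, 13, size=(L, 20)).astype(float)
    seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=L))
    states = "".join(rng.choice(list("HEC"), size=L))
    probs = rng.dirichlet([3, 3, 3], size=L)
    return (
        ProteinRecord("x", seq),
        PSSMProfile("x", scores, sequence=seq),
        SSProfile("x", states, probs),
    )


class TestFpssm:
    def test_zero_input(self):
        assert np.array_equal(compute_fpssm(pssm(np.zeros((10, 20)))), np.zeros(20))

    def test_constant_column(self):
        scores = np.zeros((7, 20))
        scores[:, 4] = 3.0
        assert compute_fpssm(pssm(scores))[4] == 3.0

    def test_hand_average(self):
        scores = np.zeros((3, 20))
        scores[:, 0] = [1, 2, 6]
        assert compute_fpssm(pssm(scores))[0] == 3.0

    def test_row_permutation_invariant(self, rng):
        scores = rng.normal(size=(15, 20))
        perm = rng.permutation(15)
        assert np.allclose(
            compute_fpssm(pssm(scores)), compute_fpssm(pssm(scores[perm]))
        )


class TestFrequencyMatrix:
    def test_zero_scores_give_ones(self):
        out = compute_frequency_matrix(pssm(np.zeros((4, 20))))
        assert np.array_equal(out, np.ones((4, 20)))

    def test_exponent_one_gives_two(self):
        bf = np.full(20, 0.05)
        scores = np.zeros((1, 20))
        scores[0, :] = 1 / 0.05
        out = compute_frequency_matrix(pssm(scores), bf=bf)
        assert np.allclose(out, 2.0)

    def test_hand_value(self):
        bf = np.full(20, 0.05)
        bf[0] = 0.25
        bf /= bf.sum()
        # renormalization changes bf; compute expected directly
        scores = np.zeros((1, 20))
        scores[0, 0] = 4.0
        out = compute_frequency_matrix(pssm(scores), bf=bf)
        assert np.isclose(out[0, 0], 2 ** (4 * bf[0]))

    def test_all_entries_positive(self, rng):
        scores = rng.integers(-8, 13, size=(9, 20)).astype(float)
        assert np.all(compute_frequency_matrix(pssm(scores)) > 0)


class TestConsensus:
    def test_tie_breaks_to_alanine(self):
        assert derive_consensus(np.ones((3, 20))) == "AAA"

    def test_unique_max_column(self):
        row = np.ones((1, 20))
        row[0, 17] = 5.0  # W column
        assert derive_consensus(row) == "W"

    def test_rowwise_argmax(self):
        freq = np.ones((3, 20))
        freq[0, 1] = 2.0
        freq[1, 1] = 3.0
        freq[2, 19] = 4.0
        assert derive_consensus(freq) == "RRV"


class TestNgrams:
    def test_one_gram_single_letter(self):
        out = compute_one_gram("AAAA")
        assert out[0] == 1.0
        assert out[1:].sum() == 0.0

    def test_one_gram_hand_count(self):
        out = compute_one_gram("ARAR")
        assert out[0] == 0.5 and out[1] == 0.5

    def test_two_gram_single_pair(self):
        out = compute_two_gram("AAAA")
        assert out[0] == 1.0 and out.sum() == 1.0

    def test_two_gram_hand_count(self):
        out = compute_two_gram("ARAR").reshape(20, 20)
        assert np.isclose(out[0, 1], 2 / 3)  # AR
        assert np.isclose(out[1, 0], 1 / 3)  # RA

    @pytest.mark.parametrize("L", [2, 5, 40])
    def test_blocks_sum_to_one(self, rng, L):
        seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=L))
        assert np.isclose(compute_one_gram(seq).sum(), 1.0)
        assert np.isclose(compute_two_gram(seq).sum(), 1.0)

    def test_two_gram_needs_two_residues(self):
        with pytest.raises(ValidationError):
            compute_two_gram("A")

    def test_weighting(self):
        one = np.zeros(20)
        one[0] = 1.0
        two = np.full(400, 1 / 400)
        out = weight_ngrams(one, two)
        assert np.isclose(out[0], ONE_GRAM_WEIGHT)
        assert np.isclose(out[:20].sum(), ONE_GRAM_WEIGHT)
        assert np.isclose(out[20:].sum(), TWO_GRAM_WEIGHT)
        assert np.isclose(out.sum(), 1.0)


class TestSSFeatures:
    def test_worked_segment_example(self):
        feats = compute_ss_sequence_features("EECCCHHHEEECHHHEECCEE")
        assert feats.segment == "βαβαββ"
        assert feats.count_bab == 2
        assert np.isclose(feats.f_freq_bab, 2 / 19)

    def test_all_coil_closed_form(self):
        for L in (3, 10, 21):
            feats = compute_ss_sequence_features("C" * L)
            assert feats.f_h == 0 and feats.f_e == 0
            assert feats.f_max_h == 0 and feats.f_max_e == 0
            assert np.isclose(feats.f_c, (L + 1) / (2 * (L - 1)))
            assert feats.segment == "" and feats.f_freq_bab == 0

    def test_all_helix_longest_run(self):
        assert compute_ss_sequence_features("H" * 12).f_max_h == 1.0

    def test_counts_partition_length(self, rng):
        states = "".join(rng.choice(list("HEC"), size=30))
        feats = compute_ss_sequence_features(states)
        assert feats.count_h + feats.count_e + feats.count_c == 30
        assert feats.max_length_h <= feats.count_h
        assert 0 <= feats.f_max_h <= 1 and 0 <= feats.f_max_e <= 1

    def test_too_short(self):
        with pytest.raises(ValidationError):
            compute_ss_sequence_features("HE")

    def test_segment_matches_regex_oracle(self, rng):
        # independent route: regex run extraction instead of groupby
        def oracle(states):
            return "".join(
                "α" if run[0] == "H" else "β"
                for run in re.findall(r"H+|E+", states)
            )

        for _ in range(1000):
            L = int(rng.integers(3, 60))
            states = "".join(rng.choice(list("HEC"), size=L))
            assert segment_sequence(states) == oracle(states)


class TestSSProperties:
    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.text(alphabet="HEC", min_size=3, max_size=80))
    def test_score_ranges_and_partition(self, states):
        feats = compute_ss_sequence_features(states)
        L = len(states)
        assert feats.count_h + feats.count_e + feats.count_c == L
        assert feats.posi_h + feats.posi_e + feats.posi_c == L * (L + 1) // 2
        for value in feats.as_vector():
            assert np.isfinite(value) and value >= 0
        assert 0 <= feats.f_max_h <= 1 and 0 <= feats.f_max_e <= 1
        assert set(feats.segment) <= {"α", "β"}

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.text(alphabet="ARNDCQEGHILKMFPSTWYV", min_size=2, max_size=60))
    def test_ngram_mass_conservation(self, seq):
        assert np.isclose(compute_one_gram(seq).sum(), 1.0)
        assert np.isclose(compute_two_gram(seq).sum(), 1.0)


class TestProbFeatures:
    def test_constant_rows(self):
        probs = np.tile([0.2, 0.5, 0.3], (16, 1))
        out = compute_prob_features(probs, lam=8)
        assert out.shape == (27,)
        assert np.allclose(out.reshape(9, 3), [0.2, 0.5, 0.3])

    def test_single_row_blocks(self, rng):
        probs = rng.dirichlet([2, 2, 2], size=8)
        out = compute_prob_features(probs, lam=8)
        assert np.allclose(out[:24].reshape(8, 3), probs)

    def test_uneven_split_larger_blocks_first(self):
        probs = np.zeros((9, 3))
        probs[:, 0] = np.arange(9, dtype=float)
        out = compute_prob_features(probs, lam=8)
        locals_ = out[:24].reshape(8, 3)
        # block sizes (2,1,1,1,1,1,1,1): first block = mean of rows 1-2
        assert locals_[0, 0] == 0.5
        assert np.array_equal(locals_[1:, 0], np.arange(2, 9, dtype=float))
        assert np.isclose(out[24], np.arange(9).mean())

    def test_too_short(self):
        with pytest.raises(ValidationError):
            compute_prob_features(np.full((5, 3), 1 / 3), lam=8)


class TestAssembly:
    def test_block_layout_and_length(self, rng):
        record, profile, ss = random_profiles(rng, 30)
        vec = compute_feature_vector(profile, ss)
        assert vec.shape == (N_FEATURES,)
        # positions 421-440 (1-based) are the PSSM column means, A first
        assert np.allclose(vec[420:440], compute_fpssm(profile))
        assert vec[420] == compute_fpssm(profile)[0]
        ss_feats = compute_ss_sequence_features(ss.states)
        assert np.allclose(vec[440:446], ss_feats.as_vector())
        assert np.allclose(vec[446:473], compute_prob_features(ss.probabilities))

    def test_zero_blocks_give_zero_vector(self):
        vec = assemble_feature_vector(
            np.zeros(420), np.zeros(20), np.zeros(6), np.zeros(27)
        )
        assert vec.shape == (N_FEATURES,) and np.all(vec == 0)

    def test_wrong_block_length_is_error(self):
        with pytest.raises(ValidationError, match="PSSM means"):
            assemble_feature_vector(np.zeros(420), np.zeros(19), np.zeros(6), np.zeros(27))
        with pytest.raises(ValidationError, match="probability features"):
            assemble_feature_vector(np.zeros(420), np.zeros(20), np.zeros(6), np.zeros(26))

    def test_ngram_block_order_sensitivity(self):
        # F_pssm ignores row order; n-grams do not
        scores = np.zeros((4, 20))
        scores[[0, 2], 0] = 10  # consensus A at rows 1,3
        scores[[1, 3], 1] = 10  # consensus R at rows 2,4 -> "ARAR"
        swapped = scores[[1, 0, 3, 2]]  # consensus "RARA": adjacency changes
        a = compute_feature_vector(pssm(scores), SSProfile("x", "CHEC", np.full((4, 3), 1 / 3)), lam=4)
        b = compute_feature_vector(pssm(swapped), SSProfile("x", "CHEC", np.full((4, 3), 1 / 3)), lam=4)
        assert np.allclose(a[420:440], b[420:440])
        assert not np.allclose(a[:420], b[:420])


class TestBatchExtraction:
    def test_batch_matches_single(self, rng):
        triplets = [random_profiles(rng, int(L)) for L in rng.integers(20, 50, size=4)]
        table = extract_features(triplets, [1, 0, 1, 0])
        assert table.matrix.shape == (4, N_FEATURES)
        for i, (_, profile, ss) in enumerate(triplets):
            assert np.array_equal(table.matrix[i], compute_feature_vector(profile, ss))

    def test_permuting_inputs_permutes_rows(self, rng):
        triplets = [random_profiles(rng, 25) for _ in range(4)]
        labels = [1, 0, 1, 0]
        table = extract_features(triplets, labels)
        order = [2, 0, 3, 1]
        permuted = extract_features([triplets[i] for i in order],
                                    [labels[i] for i in order])
        assert np.array_equal(permuted.matrix, table.matrix[order])

    def test_length_mismatch_names_protein(self, rng):
        record, profile, ss = random_profiles(rng, 20)
        _, profile2, _ = random_profiles(rng, 21)
        with pytest.raises(ValidationError, match="x"):
            extract_features([(record, profile2, ss)], [1])

    def test_featurizer_transformer(self, rng):
        triplets = [random_profiles(rng, 30) for _ in range(3)]
        out = ProfileFeaturizer().fit(triplets).transform(triplets)
        assert out.shape == (3, N_FEATURES)
        assert np.array_equal(out[0], compute_feature_vector(triplets[0][1], triplets[0][2]))
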