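"""Kernel, training, weight-table and cross-validation behaviour of the
gapped k-mer SVM engine."""

import itertools
import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crevip.gkm import (GkmParams, cross_class_score_matrix, cross_validate,
                        decode_codes, encode_sequence, extract_kmer_weights,
                        gkm_kernel, gkm_pair_contribution, predict_score,
                        predict_scores, revcomp_codes, reverse_complement,
                        sliding_codes, train_model)


def brute_force_kernel(x, y, l, k, both_strands):
    """Independent oracle: inner product of explicitly enumerated gapped
    k-mer count vectors."""
    def features(seq):
        c = Counter()
        for i in range(len(seq) - l + 1):
            word = seq[i : i + l]
            for subset in itertools.combinations(range(l), k):
                c[(subset, tuple(word[p] for p in subset))] += 1
        return c

    fx = features(x)
    total = 0
    for yy in ([y, reverse_complement(y)] if both_strands else [y]):
        fy = features(yy)
        total += sum(v * fy.get(key, 0) for key, v in fx.items())
    return total


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestEncoding:
    def test_sliding_codes_roundtrip(self):
        seq = "ACGTTGCA"
        codes = sliding_codes(seq, 5)
        assert decode_codes(codes, 5) == [seq[i:i + 5] for i in range(4)]

    def test_revcomp_codes_matches_string_revcomp(self):
        rng = random.Random(3)
        for _ in range(20):
            seq = rand_seq(rng, 7)
            (code,) = sliding_codes(seq, 7)
            (rc,) = revcomp_codes(np.array([code], dtype=np.uint32), 7)
            assert decode_codes(np.array([rc]), 7) == [reverse_complement(seq)]

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            encode_sequence("ACGNT")


class TestPairContribution:
    @pytest.mark.parametrize("m,l,k,expected", [
        (0, 11, 7, 330),   # C(11,7)
        (4, 11, 7, 1),     # C(7,7)
        (5, 11, 7, 0),     # l-m < k
        (0, 4, 3, 4),
    ])
    def test_closed_form(self, m, l, k, expected):
        assert gkm_pair_contribution(m, l, k) == expected


class TestKernel:
    def test_self_kernel_example(self):
        p = GkmParams(word_length=4, k=3, both_strands=False)
        assert gkm_kernel("ACGTA", "ACGTA", p, normalized=False) == 8.0

    def test_single_mismatch_example(self):
        p = GkmParams(word_length=4, k=3, both_strands=False)
        assert gkm_kernel("AAAA", "AAAT", p, normalized=False) == 1.0
        assert gkm_kernel("AAAA", "AAAT", p) == pytest.approx(0.25)

    def test_normalized_self_is_one(self):
        p = GkmParams(word_length=5, k=3)
        for seq in ["ACGTACGTAC", "TTTTTTT", "GATTACAGATTACA"]:
            assert gkm_kernel(seq, seq, p) == pytest.approx(1.0)

    def test_matches_brute_force_feature_oracle(self):
        rng = random.Random(11)
        for _ in range(30):
            l = rng.randint(3, 6)
            k = rng.randint(1, min(4, l))
            both = rng.random() < 0.5
            x = rand_seq(rng, rng.randint(l, 25))
            y = rand_seq(rng, rng.randint(l, 25))
            p = GkmParams(word_length=l, k=k, both_strands=both)
            assert gkm_kernel(x, y, p, normalized=False) == \
                brute_force_kernel(x, y, l, k, both)

    def test_symmetry_and_cauchy_schwarz(self):
        rng = random.Random(5)
        p = GkmParams(word_length=5, k=3)
        for _ in range(20):
            x, y = rand_seq(rng, 20), rand_seq(rng, 15)
            assert gkm_kernel(x, y, p, normalized=False) == \
                gkm_kernel(y, x, p, normalized=False)
            assert abs(gkm_kernel(x, y, p)) <= 1.0 + 1e-12

    def test_short_sequence_is_error(self):
        with pytest.raises(ValueError):
            gkm_kernel("ACG", "ACGTACGT", GkmParams(word_length=5, k=3))


dna = st.text(alphabet="ACGT", min_size=6, max_size=20)


class TestKernelProperties:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(l=st.integers(2, 8), k=st.integers(1, 8), m=st.integers(0, 8))
    def test_pair_contribution_counts_agreeing_subsets(self, l, k, m):
        """C(l-m, k) equals an explicit enumeration of the k-position
        subsets on which two words at Hamming distance m agree."""
        if k > l or m > l:
            return
        x = "A" * l
        y = "C" * m + "A" * (l - m)
        enumerated = sum(
            1 for subset in itertools.combinations(range(l), k)
            if all(x[p] == y[p] for p in subset))
        assert gkm_pair_contribution(m, l, k) == enumerated

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(x=dna, y=dna, both=st.booleans())
    def test_symmetry_normalisation_and_bounds(self, x, y, both):
        p = GkmParams(word_length=5, k=3, both_strands=both)
        assert gkm_kernel(x, y, p, normalized=False) == \
            gkm_kernel(y, x, p, normalized=False)
        assert gkm_kernel(x, x, p) == pytest.approx(1.0)
        assert abs(gkm_kernel(x, y, p)) <= 1.0 + 1e-12

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(x=dna, y=dna)
    def test_reverse_complement_invariance_of_kernel(self, x, y):
        p = GkmParams(word_length=4, k=3, both_strands=True)
        assert gkm_kernel(x, y, p, normalized=False) == \
            gkm_kernel(x, reverse_complement(y), p, normalized=False)


@pytest.fixture(scope="module")
def separable_toy():
    """20 sequences carrying GATTACA vs 20 plain backgrounds."""
    rng = random.Random(1)
    pos = [rand_seq(rng, 10) + "GATTACA" + rand_seq(rng, 10) for _ in range(20)]
    neg = [rand_seq(rng, 27) for _ in range(20)]
    params = GkmParams(word_length=5, k=3)
    model = train_model(pos, neg, params, seed=0, class_label="toy")
    return pos, neg, params, model


class TestTraining:
    def test_separable_toy_reaches_perfect_training_accuracy(self, separable_toy):
        _, _, _, model = separable_toy
        assert model.training_accuracy == 1.0

    def test_support_vector_scores_respect_margin_sign(self, separable_toy):
        pos, _, _, model = separable_toy
        assert predict_score(model, pos[0]) > 0

    def test_planted_motif_scores_above_background(self, separable_toy):
        _, _, _, model = separable_toy
        rng = random.Random(99)
        planted = rand_seq(rng, 8) + "GATTACA" + rand_seq(rng, 8)
        background = rand_seq(rng, 23)
        assert predict_score(model, planted) > predict_score(model, background)

    def test_reverse_complement_invariance(self, separable_toy):
        pos, _, _, model = separable_toy
        for seq in pos[:5]:
            assert predict_score(model, seq) == \
                pytest.approx(predict_score(model, reverse_complement(seq)), abs=1e-9)

    def test_identical_positives_and_negatives_give_zero_decisions(self):
        """Perfectly symmetric labels carry no signal: every decision value
        collapses to zero (chance-level discrimination)."""
        rng = random.Random(2)
        seqs = [rand_seq(rng, 20) for _ in range(10)]
        model = train_model(seqs, seqs, GkmParams(word_length=5, k=3), seed=0)
        scores = predict_scores(model, seqs)
        assert np.allclose(scores, 0.0, atol=1e-9)

    def test_empty_negative_set_is_error(self):
        with pytest.raises(ValueError):
            train_model(["ACGTACGT"], [], GkmParams(word_length=5, k=3))

    def test_model_json_roundtrip(self, separable_toy, tmp_path):
        from crevip.gkm import GkmModel
        pos, _, _, model = separable_toy
        path = tmp_path / "m.json"
        model.to_json(path)
        back = GkmModel.from_json(path)
        assert predict_score(back, pos[0]) == \
            pytest.approx(predict_score(model, pos[0]), abs=1e-12)


class TestWeightTable:
    def test_table_is_complete_and_rc_symmetric(self, separable_toy):
        _, _, _, model = separable_toy
        table = extract_kmer_weights(model)
        assert len(table) == 4 ** 5
        rc = revcomp_codes(np.arange(4 ** 5, dtype=np.uint32), 5)
        np.testing.assert_allclose(table.weights, table.weights[rc], atol=1e-9)

    def test_fast_path_equals_decision_value_definition(self, separable_toy):
        """The subset-table construction must equal predict(u) - bias exactly."""
        _, _, _, model = separable_toy
        table = extract_kmer_weights(model)
        kmers = decode_codes(np.arange(4 ** 5, dtype=np.uint32), 5)
        direct = predict_scores(model, kmers) - model.bias
        np.testing.assert_allclose(table.weights, direct, atol=1e-9)

    def test_truncated_profile_falls_back_consistently(self):
        rng = random.Random(4)
        pos = [rand_seq(rng, 6) + "GATTA" + rand_seq(rng, 6) for _ in range(12)]
        neg = [rand_seq(rng, 17) for _ in range(12)]
        params = GkmParams(word_length=5, k=3, max_mismatch=1)
        model = train_model(pos, neg, params, seed=0)
        table = extract_kmer_weights(model)
        kmers = decode_codes(np.arange(4 ** 5, dtype=np.uint32), 5)
        direct = predict_scores(model, kmers) - model.bias
        np.testing.assert_allclose(table.weights, direct, atol=1e-9)

    def test_top_kmer_lies_in_planted_motif(self, separable_toy):
        _, _, _, model = separable_toy
        table = extract_kmer_weights(model)
        best = decode_codes(np.array([int(np.argmax(table.weights))]), 5)[0]
        context = "GATTACA" + "/" + reverse_complement("GATTACA")
        assert best in context

    def test_tsv_roundtrip(self, separable_toy, tmp_path):
        from crevip.gkm import KmerWeightTable
        _, _, _, model = separable_toy
        table = extract_kmer_weights(model)
        path = tmp_path / "w.tsv"
        table.to_tsv(path)
        back = KmerWeightTable.from_tsv(path)
        np.testing.assert_allclose(back.weights, table.weights, atol=1e-7)


class TestCrossValidation:
    def test_separable_fixture_has_perfect_auroc(self):
        rng = random.Random(1)
        pos = [rand_seq(rng, 5) + "GATTACA" + rand_seq(rng, 5) + "GATTACA"
               + rand_seq(rng, 5) for _ in range(30)]
        neg = [rand_seq(rng, 29) for _ in range(30)]
        cv = cross_validate(pos, neg, GkmParams(word_length=5, k=3),
                            folds=5, seed=0)
        assert all(a == 1.0 for a in cv.fold_auroc)
        assert cv.pooled_auroc == 1.0

    def test_random_labels_are_near_chance(self):
        rng = random.Random(7)
        seqs = [rand_seq(rng, 30) for _ in range(200)]
        cv = cross_validate(seqs[:100], seqs[100:],
                            GkmParams(word_length=5, k=3), folds=5, seed=0)
        assert 0.4 <= cv.pooled_auroc <= 0.6

    def test_too_few_folds_is_error(self, separable_toy):
        pos, neg, params, _ = separable_toy
        with pytest.raises(ValueError):
            cross_validate(pos, neg, params, folds=1)

    def test_folds_partition_data(self, separable_toy):
        pos, neg, params, _ = separable_toy
        cv = cross_validate(pos, neg, params, folds=5, seed=3)
        assert len(cv.fold_auroc) == 5
        assert cv.summary().shape[0] == 6  # five folds + pooled row


class TestCrossClassMatrix:
    def test_single_model_single_set(self, separable_toy):
        pos, _, _, model = separable_toy
        df, order, linkage = cross_class_score_matrix([model], {"toy": pos[:5]})
        assert df.shape == (1, 1)
        assert linkage is None
        assert df.iloc[0, 0] > 0  # positives score positively

    def test_empty_set_is_error(self, separable_toy):
        _, _, _, model = separable_toy
        with pytest.raises(ValueError):
            cross_class_score_matrix([model], {"toy": []})
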