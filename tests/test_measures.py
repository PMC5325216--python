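"""Discrimination-based lexical measures against dense brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from ndlkit import (
    MeasureTable,
    WeightMatrix,
    activation,
    activation_vector,
    a_diversity,
    assemble_measure_table,
    concept_frequency,
    cosine_similarity_matrix,
    extract_letter_ngrams,
    l_diversity,
    mad,
    pnorm,
    prior,
    semantic_density,
    semantic_typicality,
    synthetic_semantic_matrix,
)

vectors = arrays(
    float,
    st.integers(min_value=1, max_value=12),
    elements=st.floats(-50, 50, allow_nan=False),
)


class TestNorms:
    @pytest.mark.parametrize(
        "v, p, expected", [([3, -4], 1, 7.0), ([3, -4], 2, 5.0), ([0, 0], 1, 0.0)]
    )
    def test_pnorm_examples(self, v, p, expected):
        assert pnorm(v, p) == pytest.approx(expected)

    def test_mad_of_constant_vector_is_zero(self):
        assert mad([2.5] * 7) == 0.0

    def test_pnorm_rejects_nonpositive_p(self):
        with pytest.raises(ValueError):
            pnorm([1.0], 0)

    @given(vectors, st.floats(0.5, 4.0))
    @settings(max_examples=60, deadline=None)
    def test_pnorm_homogeneity_and_norm_ordering(self, v, p):
        c = 3.7
        assert pnorm(c * v, p) == pytest.approx(abs(c) * pnorm(v, p), rel=1e-9)
        assert pnorm(v, 1) >= pnorm(v, 2) - 1e-12
        assert pnorm(v, p) >= 0


class TestActivation:
    def test_summed_afferent_weights(self):
        W = WeightMatrix(["qa", "ai", "id"], ["qaid"], [[0.73], [0.18], [0.09]])
        assert activation(W, {"qa", "ai", "id"}, "qaid") == pytest.approx(1.00)

    def test_unknown_cues_contribute_zero(self):
        W = WeightMatrix(["a"], ["o"], [[0.4]])
        assert activation(W, {"zz", "yy"}, "o") == 0.0

    def test_unknown_outcome_warns_and_returns_zero(self):
        W = WeightMatrix(["a"], ["o"], [[0.4]])
        with pytest.warns(UserWarning):
            assert activation(W, {"a"}, "nope") == 0.0

    def test_linearity_in_weights(self, random_sparse_matrix):
        W, arr, cues, outs = random_sparse_matrix(seed=5)
        W2 = WeightMatrix(cues, outs, 2 * arr)
        sel = set(cues[:4])
        assert activation(W2, sel, outs[0]) == pytest.approx(
            2 * activation(W, sel, outs[0])
        )

    def test_vector_matches_per_outcome_activation(self, random_sparse_matrix):
        W, arr, cues, outs = random_sparse_matrix(seed=2)
        sel = set(cues[::3])
        vec = activation_vector(W, sel)
        for o in outs:
            assert vec[o] == pytest.approx(activation(W, sel, o), abs=1e-12)


class TestMatrixMeasuresAgainstDenseOracle:
    def test_adiversity_prior_ldiversity(self, random_sparse_matrix):
        W, arr, cues, outs = random_sparse_matrix(k=15, n=11, seed=9)
        sel = set(cues[2:8])
        rows = [cues.index(c) for c in sel]
        assert a_diversity(W, sel) == pytest.approx(
            np.abs(arr[rows].sum(axis=0)).sum(), abs=1e-10
        )
        for j, o in enumerate(outs):
            assert prior(W, o) == pytest.approx(np.abs(arr[:, j]).sum(), abs=1e-10)
        for i, c in enumerate(cues):
            assert l_diversity(W, c) == pytest.approx(np.abs(arr[i]).sum(), abs=1e-10)

    def test_adiversity_bounds_every_activation(self, random_sparse_matrix):
        W, arr, cues, outs = random_sparse_matrix(seed=4)
        sel = set(cues[:5])
        div = a_diversity(W, sel)
        for o in outs:
            assert div >= abs(activation(W, sel, o)) - 1e-12

    def test_cosine_matrix_against_oracle(self, random_sparse_matrix):
        W, arr, cues, outs = random_sparse_matrix(k=8, n=6, seed=1)
        S = cosine_similarity_matrix(W)
        assert np.allclose(S.to_numpy(), S.to_numpy().T)
        for i in range(8):
            for j in range(8):
                ni, nj = np.linalg.norm(arr[i]), np.linalg.norm(arr[j])
                if i == j:
                    expected = 1.0
                elif ni == 0 or nj == 0:
                    expected = 0.0
                else:
                    expected = arr[i] @ arr[j] / (ni * nj)
                assert S.iat[i, j] == pytest.approx(expected, abs=1e-10)

    def test_zero_row_conventions(self):
        W = WeightMatrix(["a", "b"], ["x", "y"], [[0.0, 0.0], [1.0, 2.0]])
        S = cosine_similarity_matrix(W)
        assert S.at["a", "a"] == 1.0
        assert S.at["a", "b"] == 0.0

    def test_typicality_against_oracle(self, random_sparse_matrix):
        W, arr, cues, outs = random_sparse_matrix(k=7, n=9, seed=6)
        mean = arr.mean(axis=0)
        for i, c in enumerate(cues):
            ni, nm = np.linalg.norm(arr[i]), np.linalg.norm(mean)
            expected = 0.0 if ni == 0 or nm == 0 else arr[i] @ mean / (ni * nm)
            assert semantic_typicality(W, c) == pytest.approx(expected, abs=1e-10)

    def test_identical_rows_have_unit_typicality(self):
        arr = np.tile([1.0, 2.0, -1.0], (4, 1))
        W = WeightMatrix(list("abcd"), ["x", "y", "z"], arr)
        for c in "abcd":
            assert semantic_typicality(W, c) == pytest.approx(1.0)


class TestSemanticDensity:
    def test_identical_rows_count_everyone_else(self):
        arr = np.tile([1.0, 1.0], (5, 1))
        S = cosine_similarity_matrix(WeightMatrix(list("abcde"), ["x", "y"], arr))
        assert semantic_density(S, "a") == 4

    def test_threshold_above_one_gives_zero(self):
        arr = np.tile([1.0, 1.0], (5, 1))
        S = cosine_similarity_matrix(WeightMatrix(list("abcde"), ["x", "y"], arr))
        assert semantic_density(S, "a", threshold=1.01) == 0

    def test_monotone_nonincreasing_in_threshold(self, random_sparse_matrix):
        W, *_ = random_sparse_matrix(k=10, n=6, seed=8)
        S = cosine_similarity_matrix(W)
        lex = W.cues[0]
        counts = [semantic_density(S, lex, t) for t in (-1.0, 0.0, 0.5, 0.9, 0.99)]
        assert counts == sorted(counts, reverse=True)

    def test_clustered_rows_recover_cluster_size(self):
        W = synthetic_semantic_matrix(3, 6, noise=0.01, seed=0)
        S = cosine_similarity_matrix(W)
        assert semantic_density(S, "cat0_word0", 0.9) == 5


class TestConceptFrequency:
    def test_exact_linear_combination_gives_zero_residuals(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = pd.Series(1.5 + X @ np.array([2.0, -1.0, 0.5]))
        resid = concept_frequency(y, X)
        assert np.abs(resid).max() < 1e-10

    def test_constant_predictors_center_the_response(self):
        X = pd.DataFrame({"a": np.ones(10)})
        y = pd.Series(np.arange(10, dtype=float))
        with pytest.warns(UserWarning):
            resid = concept_frequency(y, X)
        assert np.allclose(resid, y - y.mean())

    def test_residuals_orthogonal_to_predictors(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = pd.Series(X @ np.array([1.0, 2.0, 0.0, -1.0]) + rng.normal(size=40))
        resid = concept_frequency(y, X)
        for col in X:
            centered = X[col] - X[col].mean()
            assert abs(float(resid @ centered)) <= 1e-8

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame(np.ones((3, 3)))
        with pytest.raises(ValueError):
            concept_frequency(pd.Series([1.0, 2.0, 3.0]), X)


class TestMeasureTable:
    def test_toy_lexicon_table(self, toy_equilibrium):
        words = ["paid", "pail", "qaid", "said", "sail"]
        cue_map = {
            w: set(extract_letter_ngrams(w, 2, boundaries=False)) for w in words
        }
        freq = dict(zip(words, [550.0, 50.0, 1.0, 9900.0, 50.0]))
        mt = assemble_measure_table(
            toy_equilibrium, toy_equilibrium, cue_map, freq, skew_threshold=np.inf
        )
        assert len(mt.table) == 5
        assert mt.table.at["qaid", "g2l_activation"] == pytest.approx(1.00, abs=1e-9)
        assert mt.table.at["said", "g2l_prior"] > mt.table.at["qaid", "g2l_prior"]

    def test_empty_lexome_list_keeps_header(self, toy_equilibrium):
        mt = assemble_measure_table(toy_equilibrium, toy_equilibrium, {}, {})
        assert list(mt.table.columns) == [
            "g2l_activation",
            "g2l_adiversity",
            "g2l_prior",
            "l2l_prior",
            "l2l_ldiversity",
            "sem_density",
            "sem_typicality",
            "concept_frequency",
        ]
        assert len(mt.table) == 0

    def test_missing_lexome_gets_na_not_zero(self, toy_equilibrium):
        mt = assemble_measure_table(
            toy_equilibrium, toy_equilibrium, {"ghost": {"gh"}}, {}
        )
        assert np.isnan(mt.table.at["ghost", "g2l_activation"])

    def test_tsv_round_trip(self, tmp_path, toy_equilibrium):
        words = ["paid", "pail", "qaid", "said", "sail"]
        cue_map = {
            w: set(extract_letter_ngrams(w, 2, boundaries=False)) for w in words
        }
        mt = assemble_measure_table(
            toy_equilibrium, toy_equilibrium, cue_map, dict.fromkeys(words, 10.0)
        )
        path = tmp_path / "measures.tsv"
        mt.to_tsv(path)
        back = MeasureTable.from_tsv(path)
        pd.testing.assert_frame_equal(back.table, mt.table)
        assert back.log_transformed == mt.log_transformed
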