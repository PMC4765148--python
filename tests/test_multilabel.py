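"""One-vs-rest training, essential-term selection, scoring and decisions."""

import numpy as np
import pytest

import sparseloc as sl
from sparseloc.go_features import GoTerm, GoVocabulary
from sparseloc.multilabel import (
    EssentialTermSet,
    NullFeatureVector,
    decide,
    fit_feature_selection,
    predict,
    project_features,
    refit_selected,
    score,
    select_essential_terms,
    train,
    transform_labels,
)
from sparseloc.solver import PenaltyParams, RegressionProblem, fit_lasso


def make_vocab(T, category="CC"):
    terms = tuple(GoTerm(f"GO:{1000000 + j:07d}", category) for j in range(T))
    return GoVocabulary(terms, {t.id: j for j, t in enumerate(terms)})


class TestTransformLabels:
    def test_single_label(self):
        np.testing.assert_array_equal(transform_labels([{1}], 3), [[1, -1, -1]])

    def test_all_labels(self):
        np.testing.assert_array_equal(transform_labels([{1, 2, 3}], 3), [[1, 1, 1]])

    def test_column_sums_match_locative_counts(self, rng):
        ds = sl.make_benchmark_like_composition(scale=0.02, seed=4)
        Y = transform_labels(ds.label_sets, ds.M)
        counts = ((Y + 1) / 2).sum(axis=0)
        for m in range(ds.M):
            assert counts[m] == sum(1 for y in ds.label_sets if m + 1 in y)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            transform_labels([set()], 3)

    def test_label_above_m_rejected(self):
        with pytest.raises(ValueError):
            transform_labels([{4}], 3)


class TestSelectionStage:
    def test_huge_lambda_gives_empty_essential_set(self, rng):
        X = rng.poisson(1.0, size=(30, 10)).astype(float)
        Y = transform_labels([{1 + i % 2} for i in range(30)], 2)
        model = fit_feature_selection(X, Y, penalties=PenaltyParams(lam=1e9))
        essential = select_essential_terms(model, make_vocab(10))
        assert essential.size == 0

    def test_single_class_reduces_to_plain_fit(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.choice([-1.0, 1.0], size=25)
        model = fit_feature_selection(X, y[:, None], penalties=PenaltyParams(lam=0.7))
        direct = fit_lasso(RegressionProblem(X, y), PenaltyParams(lam=0.7))
        np.testing.assert_array_equal(model.fits[0].beta, direct.beta)

    def test_union_of_supports(self):
        vocab = make_vocab(6)
        model = fit_feature_selection(
            np.eye(6), transform_labels([{1}, {2}, {1}, {2}, {1}, {2}], 2),
            penalties=PenaltyParams(lam=1e9),
        )
        # overwrite fits with prescribed supports to isolate the union logic
        model.fits[0].beta = np.array([0, 0, 1.0, 0, 0, 0])
        model.fits[0].active_set = np.array([2])
        model.fits[1].beta = np.array([0, 0, 0.5, 0, -1.0, 0])
        model.fits[1].active_set = np.array([2, 4])
        essential = select_essential_terms(model, vocab)
        assert essential.indices.tolist() == [2, 4]
        assert [t.id for t in essential.terms] == [vocab.terms[2].id, vocab.terms[4].id]

    def test_class_order_permutation_permutes_model(self, rng):
        ds, _ = sl.make_planted_dataset(N=60, T=30, M=3, k=3, n_corr_blocks=1, seed=11)
        Y = transform_labels(ds.label_sets, 3)
        params = [PenaltyParams(lam=5.0), PenaltyParams(lam=8.0), PenaltyParams(lam=11.0)]
        model = fit_feature_selection(ds.X, Y, penalties=params)
        perm = [2, 0, 1]
        permuted = fit_feature_selection(
            ds.X, Y[:, perm], penalties=[params[m] for m in perm]
        )
        for new_m, old_m in enumerate(perm):
            np.testing.assert_array_equal(permuted.fits[new_m].beta, model.fits[old_m].beta)


class TestProjection:
    def test_identity_projection(self, rng):
        X = rng.normal(size=(5, 4))
        vocab = make_vocab(4)
        essential = EssentialTermSet(np.arange(4), vocab.terms)
        np.testing.assert_array_equal(project_features(X, essential), X)

    def test_empty_selection_advises_hib(self):
        essential = EssentialTermSet(np.array([], dtype=int), ())
        with pytest.raises(NullFeatureVector, match="HIB"):
            project_features(np.ones((2, 3)), essential)

    def test_matches_brute_force_gather(self, rng):
        X = rng.normal(size=(7, 9))
        idx = np.array([1, 4, 6])
        vocab = make_vocab(9)
        essential = EssentialTermSet(idx, tuple(vocab.terms[j] for j in idx))
        expect = np.stack([[X[i, j] for j in idx] for i in range(7)])
        np.testing.assert_array_equal(project_features(X, essential), expect)


class TestRefitAndScore:
    def test_ols_refit_with_zero_penalties(self, rng):
        ds, _ = sl.make_planted_dataset(N=50, T=8, M=2, k=2, n_corr_blocks=0, seed=3)
        Y = transform_labels(ds.label_sets, 2)
        vocab = make_vocab(8)
        essential = EssentialTermSet(np.arange(8), vocab.terms)
        model = refit_selected(ds.X, Y, "mlasso", PenaltyParams(lam=0.0), essential, vocab)
        Xi = np.column_stack([np.ones(50), ds.X])
        for m in range(2):
            ref = np.linalg.lstsq(Xi, Y[:, m], rcond=None)[0]
            np.testing.assert_allclose(model.weights[m], ref[1:], atol=1e-7)
            assert model.intercepts[m] == pytest.approx(ref[0], abs=1e-7)

    def test_refit_at_full_selection_equals_stage1(self, rng):
        ds, _ = sl.make_planted_dataset(N=60, T=10, M=2, k=2, n_corr_blocks=0, seed=9)
        Y = transform_labels(ds.label_sets, 2)
        vocab = make_vocab(10)
        params = PenaltyParams(lam=2.0)
        stage1 = fit_feature_selection(ds.X, Y, penalties=params)
        essential = EssentialTermSet(np.arange(10), vocab.terms)
        model = refit_selected(ds.X, Y, "mlasso", params, essential, vocab)
        for m in range(2):
            np.testing.assert_allclose(model.weights[m], stage1.fits[m].beta, atol=1e-12)

    def test_score_is_intercept_plus_dot(self, rng):
        vocab = make_vocab(3)
        essential = EssentialTermSet(np.arange(3), vocab.terms)
        model = sl.LocalizationModel(
            mode="mlasso", essential=essential,
            weights=np.array([[1.0, 0.0, 0.0], [0.2, -0.5, 1.5]]),
            intercepts=np.array([0.0, 2.0]),
            penalties=[PenaltyParams()] * 2, vocabulary=vocab,
        )
        np.testing.assert_allclose(score(model, np.zeros(3)), model.intercepts)
        xs = np.array([3.0, 1.0, 2.0])
        np.testing.assert_allclose(score(model, xs), [3.0, 2.0 + 0.6 - 0.5 + 3.0])


class TestDecide:
    def test_all_negative_single_argmax(self):
        # mirrors the single-location case: every score negative, the
        # location with the maximum score wins
        scores = -np.ones(14)
        scores[10] = -0.1
        assert decide(scores) == {11}

    def test_two_positive_scores_both_predicted(self):
        scores = -np.ones(14)
        scores[1], scores[10] = 0.8, 0.3
        assert decide(scores) == {2, 11}

    def test_mixed_example(self):
        assert decide(np.array([0.5, -0.2, 0.1])) == {1, 3}

    def test_tie_breaks_to_lowest_index(self):
        assert decide(np.array([-1.0, -1.0, -2.0])) == {1}

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            decide(np.array([np.nan, 1.0]))

    def test_never_empty_exhaustive_small_m(self):
        for M in range(1, 6):
            for mask in range(2 ** M):
                scores = np.array(
                    [0.5 if (mask >> m) & 1 else -0.5 for m in range(M)]
                )
                got = decide(scores)
                assert got, "decision must never be empty"
                if mask:
                    assert got == {m + 1 for m in range(M) if (mask >> m) & 1}
                else:
                    assert len(got) == 1


class TestPredictPipeline:
    def _trained(self, seed=21):
        ds, _ = sl.make_planted_dataset(N=80, T=30, M=3, k=3, n_corr_blocks=1, seed=seed)
        vocab = make_vocab(30)
        model = train(ds.X, ds.label_sets, 3, vocab,
                      penalties=PenaltyParams(lam=10.0), seed=0)
        return ds, vocab, model

    def test_prediction_consistent_with_score_decide(self):
        ds, vocab, model = self._trained()
        x = ds.X[5]
        result = predict(model, x)
        xs = project_features(x, model.essential)
        np.testing.assert_array_equal(result.scores, score(model, xs))
        assert result.labels == decide(result.scores)
        assert not result.used_hib

    def test_null_projection_without_fallback_raises(self):
        ds, vocab, model = self._trained()
        x = np.zeros(30)
        with pytest.raises(NullFeatureVector):
            predict(model, x)

    def test_null_projection_uses_hib_fallback(self):
        ds, vocab, model = self._trained()
        x = np.zeros(30)
        called = {}

        def fallback(query):
            called["yes"] = True
            return np.ones(model.S)

        result = predict(model, x, hib=fallback)
        assert called and result.used_hib

    def test_end_to_end_determinism(self):
        ds, vocab, m1 = self._trained(seed=33)
        _, _, m2 = self._trained(seed=33)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.intercepts, m2.intercepts)
        assert m1.indices_list() == m2.indices_list()

    def test_model_json_roundtrip(self):
        ds, vocab, model = self._trained()
        restored = sl.LocalizationModel.from_json(model.to_json())
        np.testing.assert_array_equal(restored.weights, model.weights)
        assert [t.id for t in restored.essential.terms] == [
            t.id for t in model.essential.terms
        ]
        x = ds.X[3]
        np.testing.assert_allclose(
            predict(restored, x).scores, predict(model, x).scores
        )
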