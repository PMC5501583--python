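import json
import warnings

import numpy as np
import pytest
from scipy import special

from virsign.evaluation import LabeledScores, auroc
from virsign.kmer_features import enumerate_canonical_kmers
from virsign.training import (
    ModelBundle,
    TrainedModel,
    TrainingSet,
    _fit_path,
    build_training_set,
    capture_null_scores,
    default_lambda_grid,
    fit_lasso_logistic,
    lambda_max,
    t_screen,
    train_bundle,
)


def dirichlet_training_set(
    n_per_class: int,
    planted: list[int] | None = None,
    shift: float = 0.0,
    k: int = 3,
    seed: int = 0,
) -> TrainingSet:
    """Rows drawn from a Dirichlet; optionally a mean shift planted in a
    few columns of the virus class (rows renormalized)."""
    space = enumerate_canonical_kmers(k)
    rng = np.random.default_rng(seed)
    X = rng.dirichlet([5.0] * space.size, size=2 * n_per_class)
    y = np.array([1] * n_per_class + [0] * n_per_class)
    if planted:
        X[: n_per_class, planted] += shift
        X /= X.sum(axis=1, keepdims=True)
    return TrainingSet(X=X, y=y, L=500, k=k, space=space)


class TestTScreen:
    def test_identical_means_give_t0_p1(self):
        space = enumerate_canonical_kmers(1)  # 2 words
        X = np.array([[0.4, 0.6], [0.6, 0.4], [0.4, 0.6], [0.6, 0.4]])
        y = np.array([1, 1, 0, 0])
        ts = TrainingSet(X=X, y=y, L=500, k=1, space=space)
        res = t_screen(ts)
        assert res.t_stats == pytest.approx([0.0, 0.0])
        assert res.p_values == pytest.approx([1.0, 1.0])

    def test_matches_pooled_variance_formula_by_hand(self):
        space = enumerate_canonical_kmers(1)
        a = np.array([0.52, 0.48, 0.55])
        b = np.array([0.40, 0.44, 0.42])
        X = np.column_stack([np.concatenate([a, b]), 1 - np.concatenate([a, b])])
        y = np.array([1, 1, 1, 0, 0, 0])
        ts = TrainingSet(X=X, y=y, L=500, k=1, space=space)
        res = t_screen(ts)
        # textbook pooled-variance two-sample t
        sp2 = ((a.var(ddof=1)) * 2 + (b.var(ddof=1)) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.t_stats[0] == pytest.approx(t_hand)

    def test_constant_column_is_removed(self):
        ts = dirichlet_training_set(20, planted=[0, 1], shift=0.05, seed=1)
        ts.X[:, 5] = 1.0 / ts.space.size  # zero variance everywhere
        res = t_screen(ts)
        assert res.removed_index == 5
        assert res.p_values[5] == 1.0

    def test_exactly_one_word_removed_and_collinearity_broken(self):
        ts = dirichlet_training_set(30, seed=2)
        res = t_screen(ts)
        keep = np.ones(ts.X.shape[1], dtype=bool)
        keep[res.removed_index] = False
        Xs = ts.X[:, keep]
        # with the unit-sum constraint intact, the intercept column is in
        # the span of the features; after screening it no longer is
        full = np.column_stack([ts.X, np.ones(len(ts.y))])
        screened = np.column_stack([Xs, np.ones(len(ts.y))])
        assert np.linalg.matrix_rank(full) < full.shape[1]
        assert np.linalg.matrix_rank(screened) == screened.shape[1]

    def test_requires_two_per_class(self):
        ts = dirichlet_training_set(10, seed=3)
        ts.y[:] = 1
        ts.y[0] = 0
        with pytest.raises(ValueError):
            t_screen(ts)


class TestLassoFit:
    def test_full_shrinkage_at_lambda_max(self):
        ts = dirichlet_training_set(40, planted=[0, 1, 2], shift=0.02, seed=4)
        sc = t_screen(ts)
        keep = np.ones(ts.X.shape[1], dtype=bool)
        keep[sc.removed_index] = False
        lmax = lambda_max(ts.X[:, keep], ts.y)
        model = fit_lasso_logistic(ts, lambda_grid=[lmax * 1.000001], folds=4, seed=0)
        assert model.beta == {}
        scores = model.score_matrix(ts.X)
        assert np.allclose(scores, special.expit(model.beta0))
        # balanced classes: intercept at logit(0.5) = 0
        assert model.beta0 == pytest.approx(0.0, abs=1e-6)

    def test_perfectly_separating_feature_gives_training_auroc_1(self):
        ts = dirichlet_training_set(25, seed=5)
        ts.X[ts.y == 1, 3] += 0.2
        ts.X /= ts.X.sum(axis=1, keepdims=True)
        sc = t_screen(ts)
        keep = np.ones(ts.X.shape[1], dtype=bool)
        keep[sc.removed_index] = False
        lmax = lambda_max(ts.X[:, keep], ts.y)
        model = fit_lasso_logistic(ts, lambda_grid=[lmax * 1e-4], folds=5, seed=0)
        assert auroc(LabeledScores(model.score_matrix(ts.X), ts.y)) == 1.0

    def test_planted_words_recovered_with_correct_sign(self):
        planted = [2, 7, 11, 19, 30]
        ts = dirichlet_training_set(150, planted=planted, shift=0.03, seed=6)
        model = fit_lasso_logistic(
            ts, lambda_grid=default_lambda_grid(ts.X, ts.y, n_lambda=20, min_ratio=1e-3),
            folds=5, seed=0,
        )
        planted_words = [ts.space.words[i] for i in planted]
        by_magnitude = sorted(model.beta, key=lambda w: abs(model.beta[w]), reverse=True)
        assert set(by_magnitude[:5]) == set(planted_words)
        assert all(model.beta[w] > 0 for w in planted_words)

    def test_nonzero_count_monotone_in_lambda(self):
        ts = dirichlet_training_set(60, planted=[0, 4, 8], shift=0.02, seed=7)
        grid = default_lambda_grid(ts.X, ts.y, n_lambda=10, min_ratio=1e-2)
        coefs, _, conv = _fit_path(ts.X, ts.y, np.sort(grid)[::-1], tol=1e-6, max_iter=5000)
        assert conv.all()
        nnz = (coefs != 0).sum(axis=1)
        assert (np.diff(nnz) >= 0).all()  # grid is descending in lambda

    def test_ties_break_toward_larger_lambda(self):
        # no signal at all: CV AUROC is flat noise around 0.5 and the
        # chosen lambda should sit at (or near) the sparse end
        ts = dirichlet_training_set(40, seed=8)
        model = fit_lasso_logistic(
            ts, lambda_grid=default_lambda_grid(ts.X, ts.y, n_lambda=6, min_ratio=1e-1),
            folds=4, seed=1,
        )
        assert model.lambda_ in model.metadata["lambda_grid"]
        assert model.metadata["lambda_grid"][0] >= model.lambda_


class TestNullCapture:
    def test_null_sorted_in_unit_interval(self, small_model):
        ns = small_model.null_scores
        assert len(ns) == small_model.metadata["n_null"]
        assert (np.diff(ns) >= 0).all()
        assert ns.min() >= 0 and ns.max() <= 1

    def test_capture_is_deterministic(self, small_model, small_fragments):
        _, hf = small_fragments
        a = capture_null_scores(_copy_model(small_model), hf[:120]).null_scores
        b = capture_null_scores(_copy_model(small_model), hf[:120]).null_scores
        assert (a == b).all()

    def test_small_null_warns_about_resolution(self, small_model):
        with pytest.warns(UserWarning, match="resolution"):
            capture_null_scores(_copy_model(small_model), [])


def _copy_model(model: TrainedModel) -> TrainedModel:
    return TrainedModel.from_json(model.to_json())


class TestSerialization:
    def test_json_roundtrip_preserves_scores(self, small_model):
        back = _copy_model(small_model)
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=500)) for _ in range(5)]
        assert np.allclose(back.score_sequences(seqs), small_model.score_sequences(seqs))
        assert back.lambda_ == small_model.lambda_
        assert back.removed_word == small_model.removed_word

    def test_version_mismatch_refused(self, small_model):
        payload = json.loads(small_model.to_json())
        payload["format_version"] = 99
        with pytest.raises(ValueError, match="version"):
            TrainedModel.from_json(json.dumps(payload))


class TestTrainBundle:
    @pytest.fixture(scope="class")
    def bundle(self, small_corpus, tmp_path_factory):
        virus, host = small_corpus
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return train_bundle(
                virus, host, k=4, seed=3, folds=4, n_lambda=5,
                lambda_min_ratio=1e-2, tol=1e-4,
            )

    def test_three_length_classes_share_k(self, bundle):
        assert sorted(bundle.models) == [500, 1000, 3000]
        assert {m.k for m in bundle.models.values()} == {4}

    def test_equal_class_counts_per_model(self, bundle):
        for model in bundle.models.values():
            assert model.metadata["n_virus"] == model.metadata["n_host"]

    def test_same_seed_gives_identical_serialized_bundle(self, small_corpus, tmp_path):
        virus, host = small_corpus
        kwargs = dict(k=4, seed=9, folds=4, n_lambda=4, lambda_min_ratio=1e-2, tol=1e-4,
                      lengths=(500, 1000, 3000))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = train_bundle(virus, host, **kwargs)
            b = train_bundle(virus, host, **kwargs)
        a.save(tmp_path / "a")
        b.save(tmp_path / "b")
        for L in (500, 1000, 3000):
            fa = (tmp_path / "a" / f"model_L{L}.json").read_bytes()
            fb = (tmp_path / "b" / f"model_L{L}.json").read_bytes()
            assert fa == fb

    def test_bundle_save_load_roundtrip(self, bundle, tmp_path):
        bundle.save(tmp_path / "bundle")
        back = ModelBundle.load(tmp_path / "bundle")
        assert sorted(back.models) == sorted(bundle.models)
        assert back.models[500].beta == bundle.models[500].beta

    def test_missing_length_class_rejected(self, bundle):
        with pytest.raises(ValueError, match="missing"):
            ModelBundle(models={500: bundle.models[500]})

    def test_empty_input_rejected(self, small_corpus):
        virus, _ = small_corpus
        with pytest.raises(ValueError):
            train_bundle(virus, [], k=4)


def test_build_training_set_shapes(small_fragments):
    vf, hf = small_fragments
    ts = build_training_set(vf[:10], hf[:10], k=4, L=500)
    assert ts.X.shape == (20, 136)
    assert ts.class_counts == (10, 10)
    assert np.allclose(ts.X.sum(axis=1), 1.0)
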