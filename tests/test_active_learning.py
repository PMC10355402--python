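"""Featurization, the linear classifier, uncertainty selection, and the loop."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from misinfowatch import active_learning as al
from misinfowatch.active_learning import (
    ALState,
    FeatureSpec,
    Featurizer,
    LinearModel,
    cross_validate,
    evaluate_predictions,
    predict_corpus,
    run_active_learning,
    select_uncertain,
    train_model,
)
from misinfowatch.synthetic import make_oracle


class TestFeaturize:
    def test_identical_texts_identical_rows(self):
        fz = Featurizer(FeatureSpec(ngram_range=(1, 1), min_df=1))
        X = fz.fit_transform(["the vaccine works", "the vaccine works", "other text here"])
        assert np.allclose(X[0].toarray(), X[1].toarray())

    def test_out_of_vocabulary_is_zero_row(self):
        fz = Featurizer(FeatureSpec(ngram_range=(1, 1), min_df=1))
        fz.fit(["alpha beta", "beta gamma"])
        X = fz.transform(["zeta theta iota"])
        assert X.nnz == 0

    def test_transform_before_fit_errors(self):
        with pytest.raises(RuntimeError, match="fitted"):
            Featurizer().transform(["x"])

    def test_tfidf_matches_hand_computation(self):
        """Weights on a 5-document toy corpus match an independently coded
        smoothed tf-idf with l2 row normalization."""
        docs = ["covid vaccine works",
                "vaccine hoax claim",
                "covid covid news",
                "news about vaccine",
                "hoax hoax hoax claim"]
        fz = Featurizer(FeatureSpec(ngram_range=(1, 1), min_df=1))
        X = fz.fit_transform(docs).toarray()
        vocab = fz.vocabulary

        # independent oracle: tf = raw count, idf = ln((1+n)/(1+df)) + 1, l2 norm
        terms = sorted(vocab, key=vocab.get)
        n = len(docs)
        tok_docs = [d.split() for d in docs]
        df = {t: sum(t in d for d in tok_docs) for t in terms}
        expected = np.zeros((n, len(terms)))
        for i, d in enumerate(tok_docs):
            for j, t in enumerate(terms):
                expected[i, j] = d.count(t) * (np.log((1 + n) / (1 + df[t])) + 1)
            norm = np.linalg.norm(expected[i])
            if norm:
                expected[i] /= norm
        assert np.allclose(X, expected)


TOY_X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [-1.0, -1.0]])
TOY_Y = np.array([0, 1, 1, 0])


class TestTrainModel:
    def test_separable_toy_perfect(self):
        model = train_model(TOY_X, TOY_Y)
        assert (model.predict(TOY_X) == TOY_Y).all()

    def test_duplicated_rows_same_sign_pattern(self):
        m1 = train_model(TOY_X, TOY_Y)
        m2 = train_model(np.vstack([TOY_X, TOY_X]), np.hstack([TOY_Y, TOY_Y]))
        assert (m1.predict(TOY_X) == m2.predict(TOY_X)).all()

    def test_single_class_error_names_missing_class(self):
        with pytest.raises(ValueError, match="misinformation"):
            train_model(TOY_X, np.zeros(4, dtype=int))

    def test_matches_grid_search_hinge_oracle(self):
        """Predictions agree with a brute-force grid minimizing the same
        regularized (squared) hinge objective, intercept regularized."""
        model = train_model(TOY_X, TOY_Y, C=1.0)
        ys = 2 * TOY_Y - 1
        grid = np.linspace(-3, 3, 61)
        best, best_obj = None, np.inf
        for w1, w2, b in product(grid, grid, grid):
            margins = ys * (TOY_X @ np.array([w1, w2]) + b)
            obj = 0.5 * (w1 ** 2 + w2 ** 2 + b ** 2) + np.sum(
                np.maximum(0.0, 1.0 - margins) ** 2)
            if obj < best_obj:
                best_obj, best = obj, (np.array([w1, w2]), b)
        oracle_pred = ((TOY_X @ best[0] + best[1]) > 0).astype(int)
        assert (model.predict(TOY_X) == oracle_pred).all()


class _ValueFeaturizer:
    """Stand-in featurizer mapping each 'text' (a number string) to itself."""

    spec = FeatureSpec()
    fitted = True

    def transform(self, texts):
        return np.array([[float(t)] for t in texts])


def _stub_state(values: dict[str, float], batch_size: int) -> ALState:
    state = ALState(labeled={}, pool=list(values), texts={k: str(v) for k, v in values.items()},
                    featurizer=_ValueFeaturizer(), batch_size=batch_size)
    state.model = LinearModel(weights=np.array([1.0]), bias=0.0)
    return state


class TestSelectUncertain:
    def test_smallest_absolute_values(self):
        state = _stub_state({"a": 2.0, "b": -0.1, "c": 0.5, "d": -3.0}, batch_size=2)
        assert select_uncertain(state) == ["b", "c"]

    def test_batch_larger_than_pool_returns_all(self):
        state = _stub_state({"a": 1.0, "b": 2.0}, batch_size=100)
        assert set(select_uncertain(state)) == {"a", "b"}

    def test_ties_break_by_ascending_id(self):
        state = _stub_state({"z": 1.0, "a": -1.0, "m": 1.0}, batch_size=2)
        assert select_uncertain(state) == ["a", "m"]

    def test_empty_pool_stop_signal(self):
        state = _stub_state({}, batch_size=5)
        assert select_uncertain(state) == []
        assert state.stopped

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_matches_exhaustive_sort_oracle(self, seed):
        """Selection equals a brute-force sort by (|decision|, id)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 300))
        ids = [f"t{i:04d}" for i in rng.choice(10_000, size=n, replace=False)]
        vals = rng.normal(scale=3.0, size=n)
        k = int(rng.integers(1, 50))
        state = _stub_state(dict(zip(ids, vals)), batch_size=k)
        expected = [i for i, _ in sorted(zip(ids, np.abs(vals)),
                                         key=lambda p: (p[1], p[0]))][:min(k, n)]
        assert select_uncertain(state) == expected


def _separable_world(n=600, seed=0):
    """Tiny synthetic text world with clean class vocabulary."""
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < 0.3).astype(int)
    pos_vocab = ["hoax", "microchip", "plandemic"]
    neg_vocab = ["dose", "appointment", "relieved"]
    shared = ["vaccine", "covid", "news", "today"]
    texts = {}
    truth = {}
    for i, y in enumerate(labels):
        tid = f"t{i:05d}"
        words = list(rng.choice(shared, 4)) + list(
            rng.choice(pos_vocab if y else neg_vocab, 3))
        rng.shuffle(words)
        texts[tid] = " ".join(words)
        truth[tid] = int(y)
    return texts, truth


class TestLoop:
    def test_step_bookkeeping_and_budget_conservation(self):
        texts, truth = _separable_world()
        ids = sorted(texts)
        initial = {t: truth[t] for t in ids[:60]}
        pool = ids[60:]
        oracle = make_oracle(truth)
        state, hist = run_active_learning(initial, pool, texts, oracle, batch_size=50,
                                          max_iterations=3, eval_mode="none", seed=0)
        assert state.iteration == 3
        assert oracle.query_count == 150
        assert len(state.labeled) == 60 + 150
        assert len(state.labeled) + len(state.pool) == len(ids)
        assert not set(state.labeled) & set(state.pool)
        assert len(hist) == 3

    def test_pool_exhaustion_stops_early(self):
        texts, truth = _separable_world(n=120)
        ids = sorted(texts)
        initial = {t: truth[t] for t in ids[:90]}
        pool = ids[90:]  # 30 < batch_size
        oracle = make_oracle(truth)
        state, hist = run_active_learning(initial, pool, texts, oracle, batch_size=100,
                                          max_iterations=50, eval_mode="none", seed=0)
        assert state.stopped
        assert state.iteration == 1
        assert len(state.labeled) == 120 and not state.pool

    def test_zero_iterations_returns_initial_model(self):
        texts, truth = _separable_world(n=200)
        ids = sorted(texts)
        initial = {t: truth[t] for t in ids[:80]}
        oracle = make_oracle(truth)
        state, hist = run_active_learning(initial, ids[80:], texts, oracle,
                                          max_iterations=0, eval_mode="none", seed=0)
        assert state.model is not None
        assert hist.empty
        assert oracle.query_count == 0

    def test_oracle_failure_leaves_state_unchanged(self):
        texts, truth = _separable_world(n=200)
        ids = sorted(texts)
        initial = {t: truth[t] for t in ids[:80]}
        partial_truth = {t: truth[t] for t in ids[:100]}  # oracle missing most pool ids
        oracle = make_oracle(partial_truth)
        state = ALState(labeled=dict(initial), pool=ids[80:], texts=texts,
                        featurizer=Featurizer(), batch_size=50, eval_mode="none")
        al._retrain(state)
        before = (dict(state.labeled), list(state.pool), state.iteration)
        with pytest.raises(KeyError):
            al.al_step(state, oracle)
        assert (dict(state.labeled), list(state.pool), state.iteration) == before

    def test_indicator_terms_among_top_positive_weights(self, medium_world):
        corpus, truth = medium_world
        texts = dict(zip(corpus.tweets["id"], corpus.tweets["text"]))
        ids = sorted(texts)[:4000]
        initial = {t: truth[t] for t in ids}
        state, _ = run_active_learning(initial, [], texts, make_oracle(truth),
                                       max_iterations=0, eval_mode="none", seed=0)
        top = al.top_positive_terms(state.featurizer, state.model, 25)
        assert {"hoax", "microchip", "5g"} & set(top)

    def test_learning_curve_non_decreasing_within_noise(self):
        """Held-out accuracy grows (within tolerance) with labeled-set size on
        separable data, averaged over seeds."""
        deltas = []
        for seed in range(6):
            texts, truth = _separable_world(n=500, seed=seed)
            ids = sorted(texts)
            initial = {t: truth[t] for t in ids[:30]}
            hold = ids[30:130]
            pool = ids[130:]
            holdout = ([texts[t] for t in hold], [truth[t] for t in hold])
            oracle = make_oracle(truth)
            _, hist = run_active_learning(initial, pool, texts, oracle, batch_size=30,
                                          max_iterations=5, eval_mode="holdout",
                                          holdout=holdout, seed=seed)
            deltas.append(hist["accuracy"].iloc[-1] - hist["accuracy"].iloc[0])
        assert np.mean(deltas) >= -0.01


class TestEvaluation:
    def test_perfect_predictor_leaked_label(self):
        rng = np.random.default_rng(0)
        y = (rng.random(200) < 0.5).astype(int)
        X = np.column_stack([2.0 * y - 1.0, rng.normal(size=200)])
        res = cross_validate(X, y, k=5, seed=0)
        assert res["mean"]["accuracy"] == 1.0
        assert res["mean"]["f_score"] == 1.0

    def test_constant_predict_one_closed_form(self):
        """Predicting all 1 on a balanced set: accuracy 0.5, precision 0.5,
        recall 1.0, F-score 2/3."""
        y_true = np.array([0, 1] * 50)
        y_pred = np.ones(100, dtype=int)
        m = evaluate_predictions(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(0.5)
        assert m["precision"] == pytest.approx(0.5)
        assert m["recall"] == pytest.approx(1.0)
        assert m["f_score"] == pytest.approx(2 / 3)

    def test_metrics_match_hand_confusion_matrix(self):
        """10 fixed items: TP=3, FP=1, FN=2, TN=4."""
        y_true = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        m = evaluate_predictions(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(7 / 10)
        assert m["precision"] == pytest.approx(3 / 4)
        assert m["recall"] == pytest.approx(3 / 5)
        assert m["f_score"] == pytest.approx(2 * (3 / 4) * (3 / 5) / (3 / 4 + 3 / 5))

    def test_unstratifiable_class_errors(self):
        y = np.array([0] * 20 + [1] * 2)
        X = np.random.default_rng(0).normal(size=(22, 3))
        with pytest.raises(ValueError, match="stratify"):
            cross_validate(X, y, k=5)


class TestPredictCorpus:
    def test_sign_rule(self):
        model = LinearModel(weights=np.array([1.0]), bias=0.0)
        X = np.array([[1.7], [-0.3]])
        assert model.predict(X).tolist() == [1, 0]

    def test_every_tweet_labeled_and_prevalence_close(self, medium_world):
        corpus, truth = medium_world
        texts = dict(zip(corpus.tweets["id"], corpus.tweets["text"]))
        ids = sorted(texts)
        initial = {t: truth[t] for t in ids[:3000]}
        state, _ = run_active_learning(initial, [], texts, make_oracle(truth),
                                       max_iterations=0, eval_mode="none", seed=0)
        pred = predict_corpus(state.featurizer, state.model, corpus)
        assert len(pred) == len(corpus.tweets)
        assert set(pred["source"]) == {"predicted"}
        assert ((pred["confidence"] > 0).astype(int) == pred["label"]).all()
        truth_prev = np.mean(list(truth.values()))
        assert abs(pred["label"].mean() - truth_prev) < 0.02


def test_model_round_trip(tmp_path, medium_world):
    corpus, truth = medium_world
    texts = corpus.tweets["text"].tolist()[:1500]
    labels = [truth[t] for t in corpus.tweets["id"][:1500]]
    fz = Featurizer()
    X = fz.fit_transform(texts)
    model = train_model(X, labels)
    al.save_model(tmp_path / "m.json", fz, model)
    fz2, m2 = al.load_model(tmp_path / "m.json")
    probe = corpus.tweets["text"].tolist()[1500:1600]
    assert np.allclose(model.decision(fz.transform(probe)),
                       m2.decision(fz2.transform(probe)))
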