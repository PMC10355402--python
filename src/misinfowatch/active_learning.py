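"""Pool-based active learning with a linear margin classifier.

A LinearSVC-style classifier (regularized hinge loss) is trained on an
initial labeled set, then repeatedly augmented: at each iteration the
``batch_size`` (default 100) unlabeled tweets with the smallest absolute
decision-function value — the distance to the separating hyperplane, i.e.
the samples the model is least confident about — are sent to an oracle
(human expert, or simulated truth), moved from the pool into the training
set, and the model is retrained and re-evaluated. The loop stops after
``max_iterations`` (default 50) or when the pool is exhausted.

Featurization is lowercase word unigrams+bigrams with tf-idf weighting and
min document frequency 2; the vocabulary is fitted once on the initial
labeled set and frozen so decision values stay comparable across iterations
(refit per iteration is available via :class:`FeatureSpec`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from misinfowatch.data_model import LABEL_COLUMNS, Corpus


@dataclass
class FeatureSpec:
    """Tokenization and weighting choices for the tf-idf featurizer."""

    ngram_range: tuple[int, int] = (1, 2)
    min_df: int = 2
    lowercase: bool = True
    refit_per_iteration: bool = False


class Featurizer:
    """tf-idf featurizer; must be fitted before transform."""

    def __init__(self, spec: Optional[FeatureSpec] = None):
        self.spec = spec or FeatureSpec()
        self._vectorizer: Optional[TfidfVectorizer] = None

    @property
    def fitted(self) -> bool:
        return self._vectorizer is not None

    def fit(self, texts: Sequence[str]) -> "Featurizer":
        self._vectorizer = TfidfVectorizer(
            lowercase=self.spec.lowercase, ngram_range=self.spec.ngram_range,
            min_df=self.spec.min_df)
        self._vectorizer.fit(texts)
        return self

    def transform(self, texts: Sequence[str]) -> sp.csr_matrix:
        if not self.fitted:
            raise RuntimeError("featurizer must be fitted before transform")
        return self._vectorizer.transform(texts)

    def fit_transform(self, texts: Sequence[str]) -> sp.csr_matrix:
        return self.fit(texts).transform(texts)

    @property
    def vocabulary(self) -> dict[str, int]:
        if not self.fitted:
            raise RuntimeError("featurizer not fitted")
        return {t: int(i) for t, i in self._vectorizer.vocabulary_.items()}

    @property
    def idf(self) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("featurizer not fitted")
        return self._vectorizer.idf_


def featurize(texts: Sequence[str], featurizer: Featurizer,
              fit: bool = False) -> sp.csr_matrix:
    """Encode texts as tf-idf rows; out-of-vocabulary terms are ignored."""
    return featurizer.fit_transform(texts) if fit else featurizer.transform(texts)


@dataclass
class LinearModel:
    """A linear decision function: decision(x) = w.x + b, label 1 iff > 0."""

    weights: np.ndarray
    bias: float
    hyperparams: dict = field(default_factory=dict)

    def decision(self, X) -> np.ndarray:
        return np.asarray(X @ self.weights).ravel() + self.bias

    def predict(self, X) -> np.ndarray:
        return (self.decision(X) > 0).astype(np.int64)


def train_model(X, y, C: float = 1.0, max_iter: int = 5000, seed: int = 0) -> LinearModel:
    """Fit the regularized-hinge linear classifier (LinearSVC)."""
    y = np.asarray(y, dtype=np.int64)
    present = set(np.unique(y).tolist())
    missing = {0, 1} - present
    if missing:
        name = {0: "fact (0)", 1: "misinformation (1)"}[missing.pop()]
        raise ValueError(f"training data contains a single class; missing class: {name}")
    clf = LinearSVC(C=C, max_iter=max_iter, random_state=seed)
    clf.fit(X, y)
    return LinearModel(weights=np.asarray(clf.coef_).ravel(), bias=float(clf.intercept_[0]),
                       hyperparams={"C": C, "max_iter": max_iter, "seed": seed})


@dataclass
class ALState:
    """Mutable state of one active-learning run.

    ``labeled`` maps tweet id -> label; ``pool`` is the unlabeled id set kept
    in sorted order for deterministic tie-breaking; ``texts`` maps every id
    (labeled and pooled) to its text.
    """

    labeled: dict[str, int]
    pool: list[str]
    texts: dict[str, str]
    featurizer: Featurizer
    model: Optional[LinearModel] = None
    iteration: int = 0
    batch_size: int = 100
    max_iterations: int = 50
    history: list[dict] = field(default_factory=list)
    stopped: bool = False
    uncertainty_mode: Literal["single", "cv_average"] = "single"
    eval_mode: Literal["cv", "holdout", "none"] = "cv"
    cv_folds: int = 5
    seed: int = 0
    holdout: Optional[tuple[Sequence[str], Sequence[int]]] = None  # (texts, labels)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.pool = sorted(self.pool)
        overlap = set(self.labeled) & set(self.pool)
        if overlap:
            raise ValueError(f"labeled and pool overlap: {sorted(overlap)[:5]}")

    @property
    def budget(self) -> int:
        return len(self.labeled) + len(self.pool)


def _pool_uncertainty(state: ALState) -> np.ndarray:
    """|decision| for every pool id, in pool order."""
    X = state.featurizer.transform([state.texts[t] for t in state.pool])
    if state.uncertainty_mode == "single":
        return np.abs(state.model.decision(X))
    # cv_average: average |decision| over k models trained on CV folds of the
    # labeled set (one reading of "lowest average absolute confidence")
    ids = sorted(state.labeled)
    y = np.array([state.labeled[t] for t in ids])
    Xl = state.featurizer.transform([state.texts[t] for t in ids])
    skf = StratifiedKFold(n_splits=state.cv_folds, shuffle=True, random_state=state.seed)
    acc = np.zeros(X.shape[0])
    for train_idx, _ in skf.split(Xl, y):
        m = train_model(Xl[train_idx], y[train_idx],
                        seed=state.seed, **_strip_seed(state.model.hyperparams))
        acc += np.abs(m.decision(X))
    return acc / state.cv_folds


def _strip_seed(hp: dict) -> dict:
    return {k: v for k, v in hp.items() if k != "seed"}


def select_uncertain(state: ALState) -> list[str]:
    """The min(batch_size, |pool|) pool ids with smallest |decision value|.

    Ties break by ascending tweet id. Returns an empty list (and sets the
    stop signal) on an empty pool. Selected ids stay in the pool until
    :func:`al_step` moves them.
    """
    if state.model is None:
        raise RuntimeError("model not trained; call al_step / run_active_learning")
    if not state.pool:
        state.stopped = True
        return []
    conf = _pool_uncertainty(state)
    # pool is kept sorted by id, so a stable sort on confidence breaks ties
    # by ascending tweet id
    order = np.argsort(conf, kind="stable")
    k = min(state.batch_size, len(state.pool))
    return [state.pool[i] for i in order[:k]]


def _evaluate(state: ALState) -> dict:
    rec = {"iteration": state.iteration, "n_labeled": len(state.labeled)}
    if state.eval_mode == "none":
        return rec
    if state.eval_mode == "holdout":
        if state.holdout is None:
            raise ValueError("eval_mode='holdout' requires state.holdout")
        ht, hy = state.holdout
        pred = state.model.predict(state.featurizer.transform(list(ht)))
        rec.update(_metric_dict(np.asarray(hy), pred))
        return rec
    ids = sorted(state.labeled)
    X = state.featurizer.transform([state.texts[t] for t in ids])
    y = np.array([state.labeled[t] for t in ids])
    cv = cross_validate(X, y, k=state.cv_folds, seed=state.seed,
                        C=state.model.hyperparams.get("C", 1.0))
    rec.update(cv["mean"])
    return rec


def _retrain(state: ALState) -> None:
    ids = sorted(state.labeled)
    texts = [state.texts[t] for t in ids]
    y = [state.labeled[t] for t in ids]
    if state.featurizer.spec.refit_per_iteration or not state.featurizer.fitted:
        state.featurizer.fit(texts)
    X = state.featurizer.transform(texts)
    state.model = train_model(X, y, seed=state.seed)


def al_step(state: ALState, oracle: Callable[[str], int]) -> ALState:
    """One iteration: select an uncertain batch, query the oracle, retrain, evaluate.

    If the oracle fails on any id the step aborts and the state is unchanged.
    """
    if state.model is None:
        _retrain(state)
    batch = select_uncertain(state)
    if not batch:
        state.stopped = True
        return state
    # query the whole batch before mutating: an oracle failure on any id
    # leaves the state unchanged
    new_labels = {tid: int(oracle(tid)) for tid in batch}
    batch_set = set(batch)
    state.pool = [t for t in state.pool if t not in batch_set]
    state.labeled.update(new_labels)
    _retrain(state)
    state.iteration += 1
    state.history.append(_evaluate(state))
    if not state.pool or state.iteration >= state.max_iterations:
        state.stopped = True
    return state


def run_active_learning(
    initial_labeled: dict[str, int],
    pool: Sequence[str],
    texts: dict[str, str],
    oracle: Callable[[str], int],
    batch_size: int = 100,
    max_iterations: int = 50,
    feature_spec: Optional[FeatureSpec] = None,
    uncertainty_mode: Literal["single", "cv_average"] = "single",
    eval_mode: Literal["cv", "holdout", "none"] = "cv",
    cv_folds: int = 5,
    seed: int = 0,
    holdout: Optional[tuple[Sequence[str], Sequence[int]]] = None,
    selection: Literal["uncertainty", "random"] = "uncertainty",
) -> tuple[ALState, pd.DataFrame]:
    """Run the full loop; returns the final state and a per-iteration history table.

    The initial labeled set must contain both classes. ``selection="random"``
    replaces uncertainty sampling with a seeded random batch — the baseline
    used in sample-efficiency comparisons.
    """
    state = ALState(labeled=dict(initial_labeled), pool=list(pool), texts=texts,
                    featurizer=Featurizer(feature_spec), batch_size=batch_size,
                    max_iterations=max_iterations, uncertainty_mode=uncertainty_mode,
                    eval_mode=eval_mode, cv_folds=cv_folds, seed=seed, holdout=holdout)
    _retrain(state)
    if max_iterations == 0:
        return state, pd.DataFrame(state.history)
    rng = np.random.default_rng(seed)
    while not state.stopped and state.iteration < state.max_iterations:
        if selection == "random":
            if not state.pool:
                state.stopped = True
                break
            k = min(state.batch_size, len(state.pool))
            batch = [state.pool[i] for i in sorted(rng.choice(len(state.pool), size=k,
                                                              replace=False))]
            new_labels = {tid: int(oracle(tid)) for tid in batch}
            batch_set = set(batch)
            state.pool = [t for t in state.pool if t not in batch_set]
            state.labeled.update(new_labels)
            _retrain(state)
            state.iteration += 1
            state.history.append(_evaluate(state))
            if not state.pool or state.iteration >= state.max_iterations:
                state.stopped = True
        else:
            al_step(state, oracle)
    return state, pd.DataFrame(state.history)


def _metric_dict(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, pos_label=1, zero_division=0)),
        "f_score": float(f1_score(y_true, y_pred, pos_label=1, zero_division=0)),
    }


def cross_validate(X, y, k: int = 5, seed: int = 0, C: float = 1.0) -> dict:
    """Seeded stratified k-fold CV of the linear classifier.

    Returns ``{"folds": [per-fold metric dicts], "mean": averaged metrics}``.
    The F-score is the harmonic mean of precision and recall for the
    misinformation class (label 1).
    """
    y = np.asarray(y, dtype=np.int64)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"class too small to stratify into {k} folds "
                         f"(class counts: {counts.tolist()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(X, y):
        model = train_model(X[train_idx], y[train_idx], C=C, seed=seed)
        pred = model.predict(X[test_idx])
        folds.append(_metric_dict(y[test_idx], pred))
    mean = {m: float(np.mean([f[m] for f in folds])) for m in folds[0]}
    return {"folds": folds, "mean": mean}


def evaluate_predictions(y_true, y_pred) -> dict:
    """Accuracy / precision / recall / F-score for the misinformation class."""
    return _metric_dict(np.asarray(y_true), np.asarray(y_pred))


def predict_corpus(featurizer: Featurizer, model: LinearModel, corpus: Corpus) -> pd.DataFrame:
    """Predict every tweet in a corpus; label 1 iff decision value > 0.

    Returns a label table with source="predicted" and confidence = signed
    decision value.
    """
    X = featurizer.transform(corpus.tweets["text"].tolist())
    decision = model.decision(X)
    return pd.DataFrame({
        "tweet_id": corpus.tweets["id"].to_numpy(),
        "label": (decision > 0).astype(np.int64),
        "source": "predicted",
        "confidence": decision,
    }, columns=LABEL_COLUMNS)


def top_positive_terms(featurizer: Featurizer, model: LinearModel, n: int = 20) -> list[str]:
    """Terms with the largest positive weights (misinformation-indicative)."""
    inv = {i: t for t, i in featurizer.vocabulary.items()}
    order = np.argsort(model.weights)[::-1][:n]
    return [inv[int(i)] for i in order]


def save_model(path, featurizer: Featurizer, model: LinearModel) -> None:
    """Persist vocabulary, idf, weights, bias, and hyperparameters as JSON."""
    payload = {
        "feature_spec": {"ngram_range": list(featurizer.spec.ngram_range),
                         "min_df": featurizer.spec.min_df,
                         "lowercase": featurizer.spec.lowercase},
        "vocabulary": featurizer.vocabulary,
        "idf": featurizer.idf.tolist(),
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "hyperparams": model.hyperparams,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> tuple[Featurizer, LinearModel]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    spec = FeatureSpec(ngram_range=tuple(payload["feature_spec"]["ngram_range"]),
                       min_df=payload["feature_spec"]["min_df"],
                       lowercase=payload["feature_spec"]["lowercase"])
    fz = Featurizer(spec)
    vec = TfidfVectorizer(lowercase=spec.lowercase, ngram_range=spec.ngram_range,
                          min_df=spec.min_df, vocabulary=payload["vocabulary"])
    vec.idf_ = np.asarray(payload["idf"], dtype=float)
    # touching idf_ requires the internal flag sklearn sets during fit
    vec._tfidf._idf_diag = sp.diags(vec.idf_, offsets=0,
                                    shape=(len(vec.idf_), len(vec.idf_)),
                                    format="csr", dtype=np.float64)
    fz._vectorizer = vec
    model = LinearModel(weights=np.asarray(payload["weights"], dtype=float),
                        bias=float(payload["bias"]), hyperparams=payload["hyperparams"])
    return fz, model
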