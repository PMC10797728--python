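"""RUSBoost: boosting with per-round random undersampling.

A small sklearn-style estimator: each boosting round draws a random
subsample in which every class is cut down to the minority-class count,
fits a shallow decision tree on it (carrying the boosting weights), and
updates the weights SAMME-style on the full training set.  Undersampling
inside the boosting loop counters class imbalance without discarding data
permanently.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int = 3,
        learning_rate: float = 0.1,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.estimator_weights_: list[float] = []
        base = DecisionTreeClassifier(max_depth=self.max_depth)
        min_count = np.bincount(y_enc).min()
        for _ in range(self.n_estimators):
            idx = self._undersample(y_enc, min_count, rng)
            tree = clone(base)
            tree.set_params(random_state=int(rng.integers(2**31 - 1)))
            sw = w[idx]
            tree.fit(X[idx], y_enc[idx], sample_weight=sw / sw.sum())
            pred = tree.predict(X)
            err = float(w[pred != y_enc].sum() / w.sum())
            if err >= 1.0 - 1.0 / K:
                continue  # worse than chance on weighted data: discard round
            err = max(err, 1e-12)
            alpha = self.learning_rate * (np.log((1 - err) / err) + np.log(K - 1))
            w = w * np.exp(alpha * (pred != y_enc))
            w = w / w.sum()
            self.estimators_.append(tree)
            self.estimator_weights_.append(alpha)
            if err <= 1e-12:
                break
        if not self.estimators_:  # degenerate data: keep one unweighted tree
            tree = clone(base)
            tree.set_params(random_state=int(rng.integers(2**31 - 1)))
            tree.fit(X, y_enc)
            self.estimators_.append(tree)
            self.estimator_weights_.append(1.0)
        return self

    @staticmethod
    def _undersample(y_enc, min_count, rng):
        idx = []
        for c in np.unique(y_enc):
            members = np.flatnonzero(y_enc == c)
            if members.size > min_count:
                members = rng.choice(members, size=min_count, replace=False)
            idx.append(members)
        return np.sort(np.concatenate(idx))

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        K = len(self.classes_)
        votes = np.zeros((X.shape[0], K))
        for tree, alpha in zip(self.estimators_, self.estimator_weights_):
            pred = tree.predict(X)
            votes[np.arange(X.shape[0]), pred] += alpha
        total = votes.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return votes / total

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
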