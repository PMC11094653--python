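"""Random forest with out-of-bag error and permutation importance.

A thin bagging layer over scikit-learn decision trees that exposes the
out-of-bag machinery the selection and modeling stages are built on:

* OOB predictions / OOB error (training accuracy is reported as 1 - OOB
  error, with an exact binomial CI on the OOB-correct counts);
* permutation importance computed on each tree's OOB samples - mean
  decrease in accuracy (MDA) for classification, percent increase in MSE
  (%IncMSE) for regression;
* class scores for ROC analysis as the fraction of trees voting the
  positive class.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor


class OobRandomForest:
    """Bagged decision trees with OOB bookkeeping.

    Parameters
    ----------
    task : {"classification", "regression"}
    n_trees : forest size.
    mtry : number of candidate variables per split; default ceil(sqrt(p))
        for classification and max(1, p//3) for regression.
    min_samples_leaf : terminal node size.
    seed : governs bootstrap draws, tree randomness and importance permutations.
    """

    def __init__(self, task="classification", n_trees=500, mtry=None,
                 min_samples_leaf=None, seed=0):
        if task not in ("classification", "regression"):
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.n_trees = int(n_trees)
        self.mtry = mtry
        if min_samples_leaf is None:
            min_samples_leaf = 1 if task == "classification" else 5
        self.min_samples_leaf = int(min_samples_leaf)
        self.seed = int(seed)

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        n, p = X.shape
        if self.task == "classification":
            self.classes_, y_enc = np.unique(y, return_inverse=True)
            if len(self.classes_) < 2:
                raise ValueError("classification requires at least two classes")
        else:
            y_enc = np.asarray(y, dtype=float)
        mtry = self.mtry
        if mtry is None:
            mtry = int(np.ceil(np.sqrt(p))) if self.task == "classification" else max(1, p // 3)
        if mtry > p:
            raise ValueError(f"mtry={mtry} exceeds number of predictors ({p})")
        self._mtry = mtry
        rng = np.random.default_rng(self.seed)
        Tree = DecisionTreeClassifier if self.task == "classification" else DecisionTreeRegressor
        self.trees_, self._boot_idx, self._oob_masks = [], [], []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = Tree(
                max_features=mtry,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y_enc[idx])
            self.trees_.append(tree)
            self._boot_idx.append(idx)
            self._oob_masks.append(oob)
        self._X = X
        self._y = y_enc
        self._rng = rng
        self._compute_oob()
        return self

    def _compute_oob(self):
        n = self._X.shape[0]
        if self.task == "classification":
            votes = np.zeros((n, len(self.classes_)))
            for tree, oob in zip(self.trees_, self._oob_masks):
                if oob.any():
                    pred = tree.predict(self._X[oob], check_input=False).astype(int)
                    votes[np.flatnonzero(oob), pred] += 1
            covered = votes.sum(axis=1) > 0
            self.oob_votes_ = votes
            self.oob_covered_ = covered
            self.oob_pred_ = np.where(covered, votes.argmax(axis=1), -1)
            correct = (self.oob_pred_ == self._y) & covered
            self.oob_n_correct_ = int(correct.sum())
            self.oob_n_ = int(covered.sum())
            self.oob_error_ = 1.0 - self.oob_n_correct_ / self.oob_n_
        else:
            total = np.zeros(n)
            count = np.zeros(n)
            for tree, oob in zip(self.trees_, self._oob_masks):
                if oob.any():
                    total[oob] += tree.predict(self._X[oob], check_input=False)
                    count[oob] += 1
            covered = count > 0
            self.oob_covered_ = covered
            self.oob_pred_ = np.where(covered, total / np.maximum(count, 1), np.nan)
            resid = self.oob_pred_[covered] - self._y[covered]
            self.oob_mse_ = float(np.mean(resid**2))
            self.oob_error_ = self.oob_mse_
            var = float(np.var(self._y[covered]))
            self.oob_r2_ = 1.0 - self.oob_mse_ / var if var > 0 else np.nan
            self.oob_n_ = int(covered.sum())

    # ------------------------------------------------------------- predict

    def predict(self, X):
        X = np.asarray(X, dtype=np.float32)
        if self.task == "classification":
            votes = np.zeros((X.shape[0], len(self.classes_)))
            for tree in self.trees_:
                pred = tree.predict(X, check_input=False).astype(int)
                votes[np.arange(X.shape[0]), pred] += 1
            return self.classes_[votes.argmax(axis=1)]
        preds = np.zeros(X.shape[0])
        for tree in self.trees_:
            preds += tree.predict(X, check_input=False)
        return preds / self.n_trees

    def predict_score(self, X, positive_class=None):
        """Fraction of trees voting *positive_class* (default: last class)."""
        if self.task != "classification":
            raise ValueError("scores are defined for classification forests")
        X = np.asarray(X, dtype=np.float32)
        if positive_class is None:
            positive_class = self.classes_[-1]
        pos = int(np.flatnonzero(self.classes_ == positive_class)[0])
        votes = np.zeros(X.shape[0])
        for tree in self.trees_:
            votes += tree.predict(X, check_input=False).astype(int) == pos
        return votes / self.n_trees

    # ---------------------------------------------------------- importance

    def permutation_importance(self):
        """Per-variable OOB permutation importance.

        Classification: mean over trees of (OOB error with the variable
        permuted - OOB error), i.e. mean decrease in accuracy.  Regression:
        mean percent increase in OOB MSE.
        """
        p = self._X.shape[1]
        imp = np.zeros(p)
        rng = self._rng
        for tree, oob in zip(self.trees_, self._oob_masks):
            n_oob = int(oob.sum())
            if n_oob == 0:
                continue
            Xo = self._X[oob]
            yo = self._y[oob]
            base_pred = tree.predict(Xo, check_input=False)
            if self.task == "classification":
                base = np.mean(base_pred.astype(int) != yo)
            else:
                base_mse = np.mean((base_pred - yo) ** 2)
            for j in range(p):
                perm = rng.permutation(n_oob)
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                pred = tree.predict(Xp, check_input=False)
                if self.task == "classification":
                    imp[j] += np.mean(pred.astype(int) != yo) - base
                else:
                    if base_mse > 0:
                        imp[j] += (np.mean((pred - yo) ** 2) - base_mse) / base_mse * 100
                    else:
                        imp[j] += np.mean((pred - yo) ** 2) * 100
        return imp / self.n_trees
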