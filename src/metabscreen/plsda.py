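"""Partial least squares discriminant analysis.

A two-class PLS-DA built on NIPALS partial least squares regression of a
single centred class-indicator column on the (autoscaled) feature matrix.
Exposes the classical diagnostics used in metabolomics: R2 (fit), Q2
(cross-validated analogue), VIP scores, cross-validated component
selection, and a label-permutation test of the classifier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_is_fitted
from sklearn.utils.multiclass import unique_labels


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS-DA for two classes.

    The second of ``classes_`` (sorted; e.g. CRC after CTRL) is coded 1 and
    the first 0; the indicator is centred, so the decision function is the
    continuous PLS prediction and the class boundary sits at 0.

    Fitted attributes
    -----------------
    x_weights_ : (p, A) W
    x_scores_ : (n, A) T, mutually orthogonal columns
    x_loadings_ : (p, A) P
    y_loadings_ : (A,) q
    r2_ : fraction of indicator variance explained on the training data
    vip_ : (p,) variable importance in projection;  mean(VIP^2) = 1
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X_arr = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValueError(f"PLS-DA here is binary; got classes {self.classes_}")
        n, p = X_arr.shape
        max_rank = min(n - 1, p)
        if self.n_components > max_rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds rank bound {max_rank}"
            )
        y01 = (y == self.classes_[1]).astype(float)
        self._y_mean = y01.mean()
        yc = y01 - self._y_mean

        pls = PLSRegression(n_components=self.n_components, scale=False)
        pls.fit(X_arr, yc)
        self._pls = pls
        self.x_weights_ = pls.x_weights_
        self.x_scores_ = pls.x_scores_
        self.x_loadings_ = pls.x_loadings_
        self.y_loadings_ = pls.y_loadings_.ravel()
        self.n_features_in_ = p
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)

        y_hat = pls.predict(X_arr).ravel()
        ss_res = float(((yc - y_hat) ** 2).sum())
        ss_tot = float((yc**2).sum())
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self.vip_ = self._vip()

        # Platt-style mapping of the decision value to a class-1 probability
        d_train = y_hat
        from sklearn.linear_model import LogisticRegression

        self._platt = LogisticRegression(C=1e6)
        self._platt.fit(d_train.reshape(-1, 1), (yc > 0).astype(int))
        return self

    def _vip(self) -> np.ndarray:
        W = self.x_weights_
        T = self.x_scores_
        q = self.y_loadings_
        p = W.shape[0]
        # class variance explained by component a
        ssy = (q**2) * (T**2).sum(axis=0)
        if ssy.sum() <= 0:
            raise ValueError("zero explained class variance; VIP undefined")
        w_norm2 = (W**2).sum(axis=0)
        w_norm2[w_norm2 == 0] = 1.0
        return np.sqrt(p * ((W**2 / w_norm2) @ ssy) / ssy.sum())

    def decision_function(self, X):
        check_is_fitted(self, "x_weights_")
        return self._pls.predict(np.asarray(X, dtype=float)).ravel()

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])

    def predict_proba(self, X):
        d = self.decision_function(X)
        p1 = self._platt.predict_proba(d.reshape(-1, 1))[:, 1]
        return np.column_stack([1.0 - p1, p1])


def q2_score(
    X, y, n_components: int, folds: int = 7, seed: int = 0
) -> float:
    """Cross-validated fraction of class-indicator variance explained.

    Q2 = 1 - PRESS/TSS over a seeded stratified k-fold; the held-out
    predictions come from models fit on the remaining folds only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = unique_labels(y)
    y01 = (y == classes[1]).astype(float)
    press = 0.0
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in cv.split(X, y):
        yc_tr = y01[tr] - y01[tr].mean()
        pls = PLSRegression(
            n_components=min(n_components, min(len(tr) - 1, X.shape[1])), scale=False
        )
        pls.fit(X[tr], yc_tr)
        pred = pls.predict(X[te]).ravel() + y01[tr].mean()
        press += float(((y01[te] - pred) ** 2).sum())
    tss = float(((y01 - y01.mean()) ** 2).sum())
    return 1.0 - press / tss


def select_components(
    X, y, max_c: int = 8, folds: int = 7, seed: int = 0
) -> tuple[int, pd.Series]:
    """Pick the number of latent components by cross-validated accuracy.

    Returns the argmax; ties favour the smaller (more parsimonious) count.
    """
    if max_c < 1:
        raise ValueError("max_c must be >= 1")
    y_arr = np.asarray(y)
    _, counts = np.unique(y_arr, return_counts=True)
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds smallest class size {counts.min()}")
    X_arr = np.asarray(X, dtype=float)
    max_c = max(1, min(max_c, X_arr.shape[0] - int(np.ceil(X_arr.shape[0] / folds)) - 1,
                       X_arr.shape[1]))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = {}
    for a in range(1, max_c + 1):
        accs[a] = float(
            cross_val_score(PLSDAClassifier(n_components=a), X_arr, y_arr, cv=cv).mean()
        )
    acc = pd.Series(accs, name="cv_accuracy")
    best = int(acc.index[np.argmax(acc.to_numpy())])  # argmax -> first max -> smallest n
    return best, acc


def cv_accuracy(X, y, n_components: int, folds: int = 7, seed: int = 0) -> float:
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return float(
        cross_val_score(PLSDAClassifier(n_components=n_components), X, np.asarray(y), cv=cv).mean()
    )


def permutation_test(
    X,
    y,
    n_perm: int = 2000,
    seed: int = 0,
    n_components: int = 2,
    folds: int = 7,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation test of the PLS-DA classifier.

    The statistic is the seeded cross-validated accuracy; the null refits the
    model on randomly relabelled data. Returns
    ``(p, observed_accuracy, null_accuracies)`` with
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    X_arr = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    observed = cv_accuracy(X_arr, y_arr, n_components, folds=folds, seed=seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y_arr)
        null[i] = cv_accuracy(X_arr, y_perm, n_components, folds=folds, seed=seed)
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return p, observed, null
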