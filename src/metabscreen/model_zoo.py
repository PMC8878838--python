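"""The ten-classifier zoo with feature screening, GA subset selection,
nested cross-validation and per-model feature weights.

Model kinds (the field's usual abbreviations): NB naive Bayes, GLM
L2-regularised logistic regression, LR unpenalised logistic regression,
FLM fast large margin (linear hinge-loss classifier, Platt-calibrated),
DL a small fully-connected network, DT decision tree, RF random forest,
GBT gradient-boosted trees, SVM RBF support vector machine
(Platt-calibrated), PLSDA partial least squares discriminant analysis.

Each trained model is reduced to a standard record: the selected features,
tuned hyperparameters, outer-CV accuracy, per-sample (class, confidence)
predictions with confidence = winning-class probability in [0.5, 1], and a
per-feature weight vector whose scree-plot elbow defines the model's
"relevant" metabolites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from metabscreen.plsda import PLSDAClassifier

#: kinds whose fit is deterministic given (data, hyperparameters)
DETERMINISTIC_KINDS = ("NB", "GLM", "LR", "DT", "PLSDA")


def _builders(seed: int) -> dict[str, tuple[object, dict, bool]]:
    """kind -> (estimator, hyperparameter grid, needs margin calibration)."""
    return {
        "NB": (GaussianNB(), {"var_smoothing": [1e-9, 1e-6]}, False),
        "GLM": (
            LogisticRegression(max_iter=2000),
            {"C": [0.1, 1.0, 10.0]},
            False,
        ),
        "LR": (LogisticRegression(C=np.inf, max_iter=2000), {}, False),
        "FLM": (
            LinearSVC(loss="hinge", C=1.0, max_iter=20000),
            {"C": [0.1, 1.0, 10.0]},
            True,
        ),
        "DL": (
            MLPClassifier(
                hidden_layer_sizes=(64, 32),
                max_iter=400,
                random_state=seed,
            ),
            {"alpha": [1e-4, 1e-2]},
            False,
        ),
        "DT": (
            DecisionTreeClassifier(random_state=seed),
            {"max_depth": [3, 5, None]},
            False,
        ),
        "RF": (
            RandomForestClassifier(n_estimators=100, random_state=seed),
            {"max_features": ["sqrt", 0.3]},
            False,
        ),
        "GBT": (
            GradientBoostingClassifier(n_estimators=100, random_state=seed),
            {"max_depth": [2, 3]},
            False,
        ),
        "SVM": (
            SVC(kernel="rbf", gamma="scale"),
            {"C": [0.1, 1.0, 10.0]},
            True,
        ),
        "PLSDA": (PLSDAClassifier(), {"n_components": [2, 3, 4]}, False),
    }


MODEL_KINDS = tuple(_builders(0).keys())


@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm settings for feature-subset selection."""

    population: int = 20
    generations: int = 40
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/p
    elitism: int = 1
    folds: int = 5
    tournament: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate outside [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate outside [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population:
            raise ValueError("elitism must be in [0, population)")


@dataclass
class TrainedModel:
    """A fitted classifier reduced to the ensemble's standard record."""

    kind: str
    features: list[str]
    hyperparameters: dict
    cv_accuracy: float
    classes: list  # [negative, positive]
    estimator: object = None
    feature_weights: pd.Series | None = None
    predictions: pd.DataFrame | None = None  # sample_id, class, confidence

    def predict_samples(self, X: pd.DataFrame) -> pd.DataFrame:
        """Predict class and confidence (winning-class probability) per row."""
        Xs = X[self.features]
        proba = self.estimator.predict_proba(np.asarray(Xs, dtype=float))
        win = proba.argmax(axis=1)
        classes = np.asarray(self.estimator.classes_)
        out = pd.DataFrame(
            {
                "sample_id": Xs.index,
                "class": classes[win],
                "confidence": proba[np.arange(len(Xs)), win],
            }
        ).set_index("sample_id")
        self.predictions = out
        return out

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "features": list(self.features),
            "hyperparameters": {k: repr(v) for k, v in self.hyperparameters.items()},
            "cv_accuracy": self.cv_accuracy,
            "classes": [str(c) for c in self.classes],
            "feature_weights": (
                None
                if self.feature_weights is None
                else self.feature_weights.to_dict()
            ),
            "predictions": (
                None if self.predictions is None else self.predictions.reset_index().to_dict("records")
            ),
        }


def prescreen_features(
    X: pd.DataFrame,
    y,
    corr_max: float = 0.95,
    corr_tol: float = 1e-12,
    modal_max: float = 0.95,
    max_missing: float = 0.2,
) -> list[str]:
    """Screen out features that mirror the diagnosis too closely or not at
    all (|point-biserial r| > corr_max or < corr_tol), unstable features
    (modal value frequency > modal_max) and features with too much
    missingness."""
    y01 = (np.asarray(y) == np.unique(np.asarray(y))[-1]).astype(float)
    keep = []
    for col in X.columns:
        v = X[col]
        miss = float(v.isna().mean())
        if miss > max_missing:
            continue
        vv = v.dropna()
        if len(vv) == 0:
            continue
        modal = float(vv.value_counts().iloc[0] / len(vv))
        if modal > modal_max:
            continue
        if vv.nunique() == 1:
            continue
        r = abs(float(stats.pearsonr(vv, y01[v.notna().to_numpy()])[0]))
        if np.isnan(r) or r > corr_max or r < corr_tol:
            continue
        keep.append(col)
    if not keep:
        raise ValueError("feature pre-screen removed every feature")
    return keep


@dataclass
class GaResult:
    features: list[str]
    fitness: float
    trace: list[float]  # best-ever fitness per generation, non-decreasing
    n_evaluated: int


def _subset_fitness(estimator, X, y, mask, folds, seed) -> float:
    cols = np.flatnonzero(mask)
    if len(cols) == 0:
        return 0.0
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return float(
        cross_val_score(clone(estimator), X[:, cols], y, cv=cv, error_score=0.0).mean()
    )


def ga_select(
    X: pd.DataFrame,
    y,
    kind: str = "NB",
    ga: GaConfig | None = None,
    estimator=None,
) -> GaResult:
    """Bit-mask genetic algorithm for feature-subset selection.

    Tournament selection, uniform crossover, bit-flip mutation and elitism;
    the fitness of a chromosome is the seeded inner-CV accuracy of the wrapped
    classifier on the masked features. Returns the best subset ever seen.
    """
    ga = ga or GaConfig()
    ga.validate()
    feats = list(X.columns)
    p = len(feats)
    if p < 1:
        raise ValueError("no features to select from")
    X_arr = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    if estimator is None:
        estimator = _builders(ga.seed)[kind][0]
    if p == 1:
        fit = _subset_fitness(estimator, X_arr, y_arr, np.ones(1, bool), ga.folds, ga.seed)
        return GaResult(features=feats, fitness=fit, trace=[fit], n_evaluated=1)

    rng = np.random.default_rng(ga.seed)
    mut = ga.mutation_rate if ga.mutation_rate is not None else 1.0 / p
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = _subset_fitness(estimator, X_arr, y_arr, mask, ga.folds, ga.seed)
        return cache[key]

    pop = rng.random((ga.population, p)) < 0.5
    for row in pop:  # no empty chromosomes
        if not row.any():
            row[rng.integers(p)] = True
    fits = np.array([fitness(m) for m in pop])
    best_mask, best_fit = pop[fits.argmax()].copy(), float(fits.max())
    trace = [best_fit]

    for _ in range(ga.generations):
        order = np.argsort(-fits)
        new = [pop[i].copy() for i in order[: ga.elitism]]
        while len(new) < ga.population:
            # tournament pick of two parents
            parents = []
            for _ in range(2):
                cand = rng.integers(0, ga.population, size=ga.tournament)
                parents.append(pop[cand[np.argmax(fits[cand])]])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < ga.crossover_rate:
                swap = rng.random(p) < 0.5
                a[swap], b[swap] = b[swap], a[swap].copy()
            for child in (a, b):
                flip = rng.random(p) < mut
                child[flip] = ~child[flip]
                if not child.any():
                    child[rng.integers(p)] = True
                if len(new) < ga.population:
                    new.append(child)
        pop = np.array(new)
        fits = np.array([fitness(m) for m in pop])
        if fits.max() > best_fit:
            best_fit = float(fits.max())
            best_mask = pop[fits.argmax()].copy()
        trace.append(best_fit)

    return GaResult(
        features=[feats[i] for i in np.flatnonzero(best_mask)],
        fitness=best_fit,
        trace=trace,
        n_evaluated=len(cache),
    )


def _model_feature_weights(kind, est, X, y, seed) -> pd.Series:
    """Per-feature importance on the training split.

    Linear kinds use |coefficients|, tree ensembles their impurity
    importances, PLS-DA its VIP scores; kinds without an intrinsic weight
    (NB, DL, calibrated margins) fall back to permutation importance.
    """
    inner = est
    if isinstance(est, CalibratedClassifierCV):
        inner = est.calibrated_classifiers_[0].estimator
    if isinstance(inner, PLSDAClassifier):
        w = inner.vip_
    elif hasattr(inner, "coef_") and not isinstance(inner, GaussianNB):
        w = np.abs(np.asarray(inner.coef_)).ravel()
    elif hasattr(inner, "feature_importances_"):
        w = np.asarray(inner.feature_importances_)
    else:
        r = permutation_importance(
            est, np.asarray(X, float), y, n_repeats=5, random_state=seed
        )
        w = np.maximum(r.importances_mean, 0.0)
    return pd.Series(w, index=X.columns, name=f"{kind}_weight")


def train_model(
    kind: str,
    X: pd.DataFrame,
    y,
    ga: GaConfig | None = None,
    grid: dict | None = None,
    outer_folds: int = 5,
    inner_folds: int = 5,
    seed: int = 0,
) -> TrainedModel:
    """Train one classifier kind on the training split under nested CV.

    If a GA config is given the subset search (fitness = inner-CV accuracy)
    runs first; hyperparameters are then tuned by an inner CV within each
    outer fold, and ``cv_accuracy`` is the mean outer-fold accuracy — the
    test split never enters. The final model refits on the full training
    split with the settings chosen by inner CV on all of it.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; known: {MODEL_KINDS}")
    y_arr = np.asarray(y)
    classes, counts = np.unique(y_arr, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need two classes, got {classes}")
    if counts.min() < max(outer_folds, inner_folds):
        raise ValueError("fold count exceeds smallest class size")

    base, default_grid, calibrate = _builders(seed)[kind]
    grid = default_grid if grid is None else grid

    feats = list(X.columns)
    if ga is not None:
        res = ga_select(X, y_arr, kind=kind, ga=ga, estimator=clone(base))
        feats = res.features
    Xs = X[feats]

    est = clone(base)
    if calibrate:
        grid = {f"estimator__{k}": v for k, v in grid.items()}
        est = CalibratedClassifierCV(est, method="sigmoid", cv=3)

    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed + 1)
    if grid:
        search = GridSearchCV(est, grid, cv=inner, scoring="accuracy")
    else:
        search = est

    cv_acc = float(
        cross_val_score(clone(search), np.asarray(Xs, float), y_arr, cv=outer).mean()
    )

    final = clone(search).fit(np.asarray(Xs, float), y_arr)
    if grid:
        hyper = final.best_params_
        fitted = final.best_estimator_
    else:
        hyper = {}
        fitted = final

    weights = _model_feature_weights(kind, fitted, Xs, y_arr, seed)
    return TrainedModel(
        kind=kind,
        features=feats,
        hyperparameters=hyper,
        cv_accuracy=cv_acc,
        classes=list(classes),
        estimator=fitted,
        feature_weights=weights,
    )


def feature_weight_elbow(weights: pd.Series, tol: float = 1e-12) -> list[str]:
    """Features above the scree-plot elbow of the sorted weight curve.

    The elbow is the interior point of maximum perpendicular distance to the
    chord joining the first and last sorted weights (ties broken toward
    fewer features); the features strictly above the elbow are returned.
    With fewer than 3 features, or all weights equal, every feature is
    returned.
    """
    w = weights.sort_values(ascending=False, kind="mergesort")
    n = len(w)
    if n < 3 or float(w.iloc[0] - w.iloc[-1]) <= tol:
        return list(w.index)
    x = np.linspace(0.0, 1.0, n)
    yv = (w.to_numpy() - w.iloc[-1]) / (w.iloc[0] - w.iloc[-1])
    # chord from (0,1) to (1,0): distance proportional to |x + y - 1|
    d = np.abs(x + yv - 1.0)
    interior = d[1 : n - 1]
    # first point within tol of the maximum distance: ties -> fewer features
    elbow = 1 + int(np.argmax(interior >= interior.max() - tol))
    return list(w.index[:elbow])


def upset_intersections(sets: dict[str, set]) -> pd.Series:
    """Exclusive membership-pattern cardinalities over the model sets.

    For every non-empty combination of models, counts the elements belonging
    to exactly that combination (the bars of an UpSet diagram), sorted by
    decreasing count.
    """
    if not sets:
        raise ValueError("need at least one set")
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {
        combo: 0
        for r in range(1, len(names) + 1)
        for combo in itertools.combinations(names, r)
    }
    universe = set().union(*sets.values())
    for el in universe:
        combo = tuple(n for n in names if el in sets[n])
        counts[combo] += 1
    out = pd.Series(
        list(counts.values()),
        index=pd.Index(list(counts.keys()), tupleize_cols=False),
        name="count",
    )
    return out.sort_values(ascending=False, kind="mergesort")
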