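"""Model-family registry: construction, tuning, scoring, importance.

Five families are supported: lasso-penalised logistic regression, linear
SVM, a small feed-forward neural network, random forest, and
gradient-boosted trees. Linear families and the neural net are tuned by
5-fold grid-search cross-validation; the tree ensembles by a seeded
randomized search over their hyperparameter space (a stochastic search in
the same spirit as Bayesian optimisation, kept fully deterministic given
the seed). AUC is the tuning metric throughout.

Importance semantics per family: absolute coefficients for the linear
models, impurity/gain feature importances for the tree ensembles, and for
the neural net the mean absolute change in predicted probability under
per-feature permutation on the held-out split (a model-agnostic stand-in
for Shapley attributions; `ann_attribution` is a hook for plugging an
exact-SHAP callable).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, RandomizedSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

FAMILIES = (
    "lasso_logistic",
    "linear_svm",
    "ann",
    "random_forest",
    "xgboost_tree",
)

LINEAR_FAMILIES = ("lasso_logistic", "linear_svm")

#: optional override: family -> callable(model, X_test, y_test, seed) -> importances
ann_attribution: Callable | None = None


def _cv(seed: int) -> StratifiedKFold:
    return StratifiedKFold(n_splits=5, shuffle=True, random_state=seed % 2**31)


def tune_and_fit(family: str, X: np.ndarray, y: np.ndarray, seed: int):
    """Tune hyperparameters on (X, y) only and return the refit estimator."""
    seed = int(seed) % 2**31
    if family == "lasso_logistic":
        est = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", max_iter=5000, random_state=seed
        )
        search = GridSearchCV(
            est, {"C": [0.01, 0.1, 1.0]}, scoring="roc_auc", cv=_cv(seed)
        )
    elif family == "linear_svm":
        est = LinearSVC(dual=False, max_iter=10000)
        search = GridSearchCV(
            est, {"C": [0.01, 0.1, 1.0]}, scoring="roc_auc", cv=_cv(seed)
        )
    elif family == "ann":
        est = MLPClassifier(
            hidden_layer_sizes=(16,),
            solver="lbfgs",
            max_iter=400,
            random_state=seed,
        )
        search = GridSearchCV(
            est, {"alpha": [1e-4, 1e-1]}, scoring="roc_auc", cv=_cv(seed)
        )
    elif family == "random_forest":
        est = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        space = {
            "max_depth": [3, 5, None],
            "max_features": ["sqrt", 0.2],
            "min_samples_leaf": [1, 3],
        }
        search = RandomizedSearchCV(
            est, space, n_iter=4, scoring="roc_auc", cv=_cv(seed), random_state=seed
        )
    elif family == "xgboost_tree":
        est = XGBClassifier(
            n_estimators=100,
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
        )
        space = {
            "max_depth": [2, 3, 4],
            "learning_rate": [0.1, 0.3],
            "subsample": [0.8, 1.0],
        }
        search = RandomizedSearchCV(
            est, space, n_iter=4, scoring="roc_auc", cv=_cv(seed), random_state=seed
        )
    else:
        raise ValueError(f"unknown model family {family!r}")
    search.fit(X, y)
    return search.best_estimator_


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores ordering samples by predicted nonresponse risk."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def extract_importance(
    model,
    family: str,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Nonnegative per-feature importance for a fitted model.

    Linear families return |coefficient|; tree ensembles their native
    feature importance; the neural net the mean absolute prediction change
    under per-feature permutation on the held-out split (requires
    ``X_test``). An all-zero vector is a degenerate fit and raises.
    """
    if family in LINEAR_FAMILIES:
        imp = np.abs(np.ravel(model.coef_))
    elif family in ("random_forest", "xgboost_tree"):
        imp = np.asarray(model.feature_importances_, dtype=float)
    elif family == "ann":
        if X_test is None or y_test is None:
            raise ValueError("ann importance needs the held-out split")
        if ann_attribution is not None:
            imp = np.abs(np.asarray(ann_attribution(model, X_test, y_test, seed)))
        else:
            imp = _permutation_attribution(model, X_test, seed)
    else:
        raise ValueError(f"unknown model family {family!r}")
    if not np.isfinite(imp).all():
        raise ValueError("non-finite importance values")
    if (imp == 0).all():
        raise ValueError(f"degenerate {family} fit: all importances are zero")
    return imp


def _permutation_attribution(
    model, X: np.ndarray, seed: int, n_repeats: int = 5
) -> np.ndarray:
    """Mean absolute change in predicted class-1 probability when one
    feature is permuted across the held-out samples.

    More sensitive than score-drop permutation importance: a feature the
    model uses moves individual predictions even when redundant features
    keep the ranking (and hence AUC) unchanged. A feature the model
    provably ignores scores exactly zero.
    """
    rng = np.random.default_rng(int(seed) % 2**31)
    base = model.predict_proba(X)[:, 1]
    imp = np.zeros(X.shape[1])
    for _ in range(n_repeats):
        for j in range(X.shape[1]):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            imp[j] += np.abs(model.predict_proba(Xp)[:, 1] - base).mean()
    return imp / n_repeats


def rank_importance(importance: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Ranks 1..G, 1 = most important; ties broken by gene id ascending."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-importance[i], gene_ids[i]))
    ranks = np.empty(len(gene_ids), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks
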