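"""Linear gene signature: model comparison, final fit and calibrated calls.

After stability selection reduces the gene universe to a short candidate
list, the candidate families are re-trained and compared over seeded 80/20
rounds; per-metric averages decide the winner by mean AUC. The final model
is a linear classifier fitted on the full development cohort, exposing one
weight per gene (positive = pushes toward nonresponse) plus an intercept,
with a Platt-style sigmoid mapping the margin to a probability so external
samples can be called at a fixed 0.5 threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import _models
from .io import ExpressionMatrix
from .metrics import metrics_from_predictions
from .stability import stratified_split

logger = logging.getLogger(__name__)

__all__ = ["SignatureModel", "compare_models", "fit_final", "predict_cohort"]

_METRICS = ("auc", "f1", "accuracy", "youden", "sensitivity", "specificity", "ppv", "npv")


@dataclass
class SignatureModel:
    """A fitted linear signature with probability calibration.

    ``probability(x) = sigmoid(a * (intercept + sum_g w_g x_g) + b)`` and a
    sample is called nonresponse when the probability exceeds ``threshold``.
    ``a > 0`` is enforced so the probability is strictly monotone in each
    gene with the sign of its weight.
    """

    genes: list[str]
    weights: pd.Series  # gene -> weight; positive = toward nonresponse
    intercept: float
    calib_a: float
    calib_b: float
    threshold: float = 0.5
    family: str = "linear_svm"
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.weights.index) != list(self.genes):
            raise ValueError("weights must be indexed by the signature genes")
        if self.calib_a <= 0:
            raise ValueError("calibrator slope must be positive (monotone map)")

    def margin(self, m: ExpressionMatrix) -> pd.Series:
        X = m.subset_genes(self.genes).values.to_numpy(float).T
        return pd.Series(
            self.intercept + X @ self.weights.to_numpy(), index=m.sample_ids
        )

    def probability(self, m: ExpressionMatrix) -> pd.Series:
        z = self.calib_a * self.margin(m) + self.calib_b
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "weights": {g: float(w) for g, w in self.weights.items()},
            "intercept": self.intercept,
            "calib_a": self.calib_a,
            "calib_b": self.calib_b,
            "threshold": self.threshold,
            "family": self.family,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        weights = pd.Series({g: d["weights"][g] for g in d["genes"]}, name="weight")
        return cls(
            genes=d["genes"],
            weights=weights,
            intercept=d["intercept"],
            calib_a=d["calib_a"],
            calib_b=d["calib_b"],
            threshold=d["threshold"],
            family=d["family"],
            seed=d["seed"],
        )


def compare_models(
    m: ExpressionMatrix,
    labels: pd.Series,
    genes: list[str],
    families: tuple[str, ...] = _models.FAMILIES,
    rounds: int = 10,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, str]:
    """Average metrics per family over seeded 80/20 rounds; pick by mean AUC.

    Returns the per-family table of averaged metrics (PPV/NPV averages skip
    rounds where they were undefined, with a logged count) and the winning
    family (ties resolved by the order of ``families``).
    """
    sub = m.subset_genes(genes)
    labels = labels.reindex(sub.sample_ids)
    X_all = sub.values.to_numpy(float).T
    rows = []
    for family in families:
        per_metric: dict[str, list[float]] = {k: [] for k in _METRICS}
        n_undefined = 0
        for i in range(rounds):
            seed = base_seed + i
            train, test = stratified_split(labels, 0.2, seed)
            tr = [sub.sample_ids.index(s) for s in train]
            te = [sub.sample_ids.index(s) for s in test]
            model = _models.tune_and_fit(
                family, X_all[tr], labels.loc[train].to_numpy(int), seed
            )
            score = _models.decision_scores(model, X_all[te])
            row = metrics_from_predictions(
                labels.loc[test].to_numpy(int), score, model.predict(X_all[te])
            )
            for k in _METRICS:
                v = getattr(row, k)
                if v is None:
                    n_undefined += 1
                else:
                    per_metric[k].append(float(v))
        if n_undefined:
            logger.info(
                "compare_models: %s had %d undefined PPV/NPV value(s) excluded "
                "from averaging",
                family,
                n_undefined,
            )
        rows.append(
            {"family": family}
            | {k: float(np.mean(v)) if v else float("nan") for k, v in per_metric.items()}
        )
    table = pd.DataFrame(rows)
    winner = table.loc[table["auc"].idxmax(), "family"]
    return table, str(winner)


def fit_final(
    m: ExpressionMatrix,
    labels: pd.Series,
    genes: list[str],
    family: str = "linear_svm",
    seed: int = 0,
) -> SignatureModel:
    """Fit the final linear signature on the full development cohort.

    Hyperparameters are tuned by the family's usual 5-fold search; the
    margin-to-probability calibrator is a logistic (Platt-style) sigmoid
    fitted on the development margins. Only linear families expose weights;
    requesting a non-linear family raises.
    """
    if family not in _models.LINEAR_FAMILIES:
        raise ValueError(
            f"{family!r} has no linear weights; export feature importances via "
            "stability.run_iterations instead"
        )
    sub = m.subset_genes(genes)
    labels = labels.reindex(sub.sample_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    X = sub.values.to_numpy(float).T
    y = labels.to_numpy(int)
    model = _models.tune_and_fit(family, X, y, seed)
    weights = pd.Series(np.ravel(model.coef_), index=genes, name="weight")
    intercept = float(np.ravel(model.intercept_)[0])
    margins = intercept + X @ weights.to_numpy()
    calib = LogisticRegression(C=1e6, max_iter=5000)
    calib.fit(margins.reshape(-1, 1), y)
    a = float(calib.coef_[0, 0])
    b = float(calib.intercept_[0])
    if a <= 0:
        raise ValueError("degenerate calibration: margin anti-correlated with label")
    return SignatureModel(
        genes=list(genes),
        weights=weights,
        intercept=intercept,
        calib_a=a,
        calib_b=b,
        family=family,
        seed=seed,
    )


def predict_cohort(model: SignatureModel, m_external: ExpressionMatrix) -> pd.DataFrame:
    """Score an external cohort and call response groups at the threshold.

    Every signature gene must be present in the external matrix; missing
    genes raise with the full list (no silent imputation). Returns a
    DataFrame with columns sample, probability, call (1 = predicted
    nonresponse when probability > threshold).
    """
    missing = [g for g in model.genes if g not in m_external.values.index]
    if missing:
        raise KeyError(f"signature genes missing from external matrix: {missing}")
    prob = model.probability(m_external)
    return pd.DataFrame(
        {
            "sample": m_external.sample_ids,
            "probability": prob.to_numpy(),
            "call": (prob.to_numpy() > model.threshold).astype(int),
        }
    )
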