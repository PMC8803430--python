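"""Occurrence-based stability selection over repeated train/test splits.

The procedure: restrict the expression matrix to the differential-gene
universe, repeatedly split the cohort 80/20 (stratified by response
label), tune and fit a model family on the training 80% only, rank every
gene by the fitted model's importance, and flag the genes ranked in the
top fraction (default 20%, i.e. floor(0.2*G) genes). A gene's occurrence
is the number of iterations in which it was flagged; genes whose
occurrence reaches a threshold (default 8 of 10) — and which are present
in the external validation cohort — form the signature candidate list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _models
from .io import ExpressionMatrix
from .metrics import MetricsRow, metrics_from_predictions

__all__ = [
    "IterationResult",
    "stratified_split",
    "run_iterations",
    "accumulate_occurrence",
    "select_genes",
]


@dataclass
class IterationResult:
    """One resampling iteration: the split, fitted importances and metrics."""

    index: int
    seed: int
    family: str
    train_ids: list[str]
    test_ids: list[str]
    importance: pd.Series  # gene -> nonnegative importance
    ranks: pd.Series  # gene -> 1..G, 1 = most important
    metrics: MetricsRow


def stratified_split(
    labels: pd.Series, test_frac: float, seed: int
) -> tuple[list[str], list[str]]:
    """Deterministic stratified split; |test| = round(test_frac * n).

    Test seats are allocated to classes proportionally (largest-remainder
    rounding) so neither side of the split can lose a class, provided each
    class has at least two members.
    """
    n = len(labels)
    n_test = int(round(test_frac * n))
    if not 0 < n_test < n:
        raise ValueError("test fraction leaves an empty side")
    rng = np.random.default_rng(seed)
    classes = sorted(labels.unique())
    quotas = {c: n_test * (labels == c).sum() / n for c in classes}
    base = {c: int(math.floor(quotas[c])) for c in classes}
    short = n_test - sum(base.values())
    for c in sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True)[:short]:
        base[c] += 1
    test: list[str] = []
    for c in classes:
        members = list(labels.index[labels == c])
        if base[c] < 1 or len(members) - base[c] < 1:
            raise ValueError(f"class {c!r} would vanish from one side of the split")
        take = rng.choice(len(members), size=base[c], replace=False)
        test.extend(members[i] for i in sorted(take))
    train = [s for s in labels.index if s not in set(test)]
    return train, test


def run_iterations(
    m: ExpressionMatrix,
    labels: pd.Series,
    family: str,
    rounds: int = 10,
    test_frac: float = 0.2,
    base_seed: int = 0,
) -> list[IterationResult]:
    """Run the resampling loop for one model family.

    Iteration ``i`` draws its split and all model randomness from
    ``base_seed + i``, so the whole loop is a pure function of
    ``(inputs, family, base_seed)``.
    """
    if family not in _models.FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    labels = labels.reindex(m.sample_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    genes = m.gene_ids
    X_all = m.values.to_numpy(float).T  # samples x genes
    sample_pos = {s: i for i, s in enumerate(m.sample_ids)}
    results: list[IterationResult] = []
    for i in range(rounds):
        seed = base_seed + i
        train, test = stratified_split(labels, test_frac, seed)
        tr = [sample_pos[s] for s in train]
        te = [sample_pos[s] for s in test]
        model = _models.tune_and_fit(
            family, X_all[tr], labels.loc[train].to_numpy(int), seed
        )
        imp = _models.extract_importance(
            model, family, X_all[te], labels.loc[test].to_numpy(int), seed
        )
        ranks = _models.rank_importance(imp, genes)
        score = _models.decision_scores(model, X_all[te])
        row = metrics_from_predictions(
            labels.loc[test].to_numpy(int), score, model.predict(X_all[te])
        )
        results.append(
            IterationResult(
                index=i,
                seed=seed,
                family=family,
                train_ids=train,
                test_ids=test,
                importance=pd.Series(imp, index=genes, name="importance"),
                ranks=pd.Series(ranks, index=genes, name="rank"),
                metrics=row,
            )
        )
    return results


def accumulate_occurrence(
    results: list[IterationResult],
    top_frac: float = 0.2,
    ranking_over: str = "flagged",
) -> pd.DataFrame:
    """Build the occurrence ledger from iteration results.

    A gene is flagged in an iteration when its full-universe rank is at
    most ``floor(top_frac * G)``. ``occurrence`` counts flagged iterations.
    ``ranking_over`` picks the ranking-sum accounting:

    - ``"flagged"`` (default): ranking_sum adds the gene's rank only over
      iterations where it was flagged;
    - ``"all"``: ranking_sum adds its rank over every iteration (reported
      alongside occurrence, which is unchanged).

    ``average_rank`` is ranking_sum over the contributing iterations,
    reported to one decimal; blank (NaN) when a gene was never flagged.
    """
    if not results:
        raise ValueError("no iteration results")
    genes = list(results[0].ranks.index)
    for r in results:
        if list(r.ranks.index) != genes:
            raise ValueError("iterations disagree on the gene universe")
    if ranking_over not in ("flagged", "all"):
        raise ValueError(f"unknown ranking_over mode {ranking_over!r}")
    G = len(genes)
    cutoff = math.floor(top_frac * G)
    ranks = np.vstack([r.ranks.to_numpy() for r in results])  # R x G
    flagged = ranks <= cutoff
    occurrence = flagged.sum(axis=0)
    if ranking_over == "flagged":
        ranking_sum = np.where(flagged, ranks, 0).sum(axis=0)
        denom = occurrence
    else:
        ranking_sum = ranks.sum(axis=0)
        denom = np.full(G, len(results))
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(occurrence > 0, ranking_sum / np.maximum(denom, 1), np.nan)
    table = pd.DataFrame(
        {
            "gene": genes,
            "occurrence": occurrence,
            "ranking_sum": ranking_sum,
            "average_rank": np.round(avg, 1),
        }
    )
    return table.sort_values(
        ["occurrence", "average_rank", "gene"],
        ascending=[False, True, True],
        na_position="last",
    ).reset_index(drop=True)


def select_genes(
    table: pd.DataFrame,
    min_occurrence: int = 8,
    allowed: set[str] | None = None,
) -> list[str]:
    """Genes with occurrence >= ``min_occurrence`` that are also in
    ``allowed`` (the external cohort's gene universe; ``None`` = no
    restriction), ordered by (occurrence desc, average_rank asc, gene asc).
    """
    occ_ok = table["occurrence"] >= min_occurrence
    if allowed is not None:
        allowed = set(allowed)
        if not allowed:
            raise ValueError("allowed gene set is empty")
        keep = occ_ok & table["gene"].isin(allowed)
    else:
        keep = occ_ok
    sel = table.loc[keep]
    if sel.empty:
        n_occ = int(occ_ok.sum())
        raise ValueError(
            "no gene selected: "
            f"{n_occ} gene(s) pass occurrence >= {min_occurrence}"
            + (
                f", 0 of those are in the allowed set of {len(allowed)}"
                if allowed is not None and n_occ
                else ""
            )
        )
    sel = sel.sort_values(
        ["occurrence", "average_rank", "gene"], ascending=[False, True, True]
    )
    return list(sel["gene"])
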