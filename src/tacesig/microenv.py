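"""Bulk cell-fraction deconvolution and the mRNA stemness index.

Deconvolution regresses each bulk profile on a marker-genes x cell-types
signature matrix by nonnegative least squares and renormalises the
coefficients to the simplex; mixing is linear in intensity, so log-scale
bulk matrices are de-logged (2**x) first and z-scored matrices are
rejected. The stemness index of a sample is the Spearman correlation
between its expression over the weighted genes and a stem-cell-derived
weight vector, min-max scaled to [0, 1] within the scored cohort.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .diffexpr import bh_adjust
from .io import ExpressionMatrix

__all__ = ["deconvolve", "compare_fractions", "stemness_index"]


def deconvolve(
    bulk: ExpressionMatrix,
    signature: pd.DataFrame,
    min_gene_coverage: float = 0.5,
) -> pd.DataFrame:
    """Estimate cell-type fractions per bulk sample by NNLS.

    Returns a samples x cell-types DataFrame on the simplex (rows sum to
    1). Requires at least ``min_gene_coverage`` of the signature's marker
    genes to be present in the bulk matrix. Samples whose NNLS solution is
    all-zero are returned as NaN rows with a warning.
    """
    if bulk.scale_tag == "zscore":
        raise ValueError(
            "deconvolution needs intensities, not z-scores (mixing is linear)"
        )
    shared = [g for g in signature.index if g in bulk.values.index]
    if len(shared) < min_gene_coverage * len(signature.index):
        raise ValueError(
            f"only {len(shared)}/{len(signature.index)} signature genes in bulk "
            f"matrix (need >= {min_gene_coverage:.0%})"
        )
    B = bulk.values.loc[shared].to_numpy(float)
    if bulk.scale_tag == "raw_log":
        B = np.power(2.0, B)
    S = signature.loc[shared].to_numpy(float)
    fracs = np.empty((B.shape[1], S.shape[1]))
    degenerate = []
    for j in range(B.shape[1]):
        coef, _ = nnls(S, B[:, j])
        total = coef.sum()
        if total == 0:
            degenerate.append(bulk.sample_ids[j])
            fracs[j] = np.nan
        else:
            fracs[j] = coef / total
    if degenerate:
        warnings.warn(
            f"all-zero deconvolution for sample(s) {degenerate[:5]}", stacklevel=2
        )
    return pd.DataFrame(fracs, index=bulk.sample_ids, columns=signature.columns)


def compare_fractions(fractions: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Independent t-test of each cell type's fraction between groups.

    Sign convention: mean(nonresponders=1) minus mean(responders=0).
    Returns cell_type, mean_resp, mean_nonresp, t, p, q.
    """
    labels = labels.reindex(fractions.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    y = labels.to_numpy(int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = fractions.to_numpy(float)[y == 1]
    b = fractions.to_numpy(float)[y == 0]
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {
            "cell_type": fractions.columns,
            "mean_resp": b.mean(axis=0),
            "mean_nonresp": a.mean(axis=0),
            "t": t,
            "p": p,
            "q": bh_adjust(p),
        }
    ).reset_index(drop=True)


def stemness_index(m: ExpressionMatrix, weights: pd.Series) -> pd.DataFrame:
    """Per-sample stemness: Spearman rho against the weight vector, then
    min-max scaled to [0, 1] within the cohort.

    Returns a DataFrame indexed by sample with columns ``rho`` and
    ``mRNAsi``. Needs at least 10 weighted genes present in the matrix;
    warns below 50% coverage. A cohort with constant rho maps to all-zero
    mRNAsi with a warning.
    """
    if m.shape[1] < 2:
        raise ValueError("min-max scaling needs at least 2 samples")
    shared = [g for g in weights.index if g in m.values.index]
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} weighted genes in matrix; need at least 10"
        )
    if len(shared) < 0.5 * len(weights):
        warnings.warn(
            f"stemness weights coverage is low: {len(shared)}/{len(weights)} genes",
            stacklevel=2,
        )
    w = weights.loc[shared].to_numpy(float)
    X = m.values.loc[shared].to_numpy(float)
    rho = np.array(
        [stats.spearmanr(X[:, j], w).statistic for j in range(X.shape[1])]
    )
    lo, hi = rho.min(), rho.max()
    if hi == lo:
        warnings.warn("constant stemness correlation across cohort", stacklevel=2)
        msi = np.zeros_like(rho)
    else:
        msi = (rho - lo) / (hi - lo)
    return pd.DataFrame({"rho": rho, "mRNAsi": msi}, index=m.sample_ids)
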