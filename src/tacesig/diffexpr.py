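"""Moderated-t differential expression between responders and nonresponders.

Per-gene two-group comparison with empirical-Bayes variance shrinkage: the
pooled per-gene variance s2_g (d_g = n1 + n2 - 2 df) is squeezed toward a
common prior s0^2 with d0 prior degrees of freedom, estimated from the
distribution of log sample variances by moment matching on the scaled-F
model (the same moment equations the limma family of methods uses). The
moderated statistic

    t_g = log2FC_g / (s_tilde_g * sqrt(1/n1 + 1/n2)),
    s_tilde_g^2 = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

is referred to a t distribution with d0 + d_g degrees of freedom.

Sign convention: log2FC = mean(nonresponders) - mean(responders), so a
positive fold change means upregulated in nonresponders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = ["moderated_t", "bh_adjust", "filter_degs", "DEGResult"]


@dataclass
class DEGResult:
    """Filtered differential-expression table plus bookkeeping counts."""

    table: pd.DataFrame  # gene, log2FC, s2_g, t_mod, df_total, p, q, direction
    n_total: int
    n_up: int
    n_down: int

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) for s2_g ~ s0^2 * F(d_g, d0).

    Works on z = log(s2): var(z) - trigamma(d_g/2) = trigamma(d0/2), then
    s0^2 from the mean of z. Returns d0 = inf when the observed spread of
    log-variances is no larger than sampling noise alone.
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(emean))

    def f(d0: float) -> float:
        return float(special.polygamma(1, d0 / 2.0)) - excess

    # trigamma(d0/2) is decreasing in d0; bracket and solve
    lo, hi = 1e-6, 1e6
    d0 = float(optimize.brentq(f, lo, hi, maxiter=200))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    m: ExpressionMatrix,
    labels: pd.Series,
    force_d0: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test of nonresponders (1) versus responders (0).

    Parameters
    ----------
    m : ExpressionMatrix
        Genes x samples on a consistent scale (log2 intensities in the
        standard workflow).
    labels : pandas.Series
        Sample -> {0, 1}; both groups need at least two samples.
    force_d0 : float, optional
        Override the estimated prior degrees of freedom; ``0`` reduces to
        the ordinary pooled two-sample t-test, ``numpy.inf`` to the fixed
        prior-variance statistic. Used for limit checks.

    Returns
    -------
    pandas.DataFrame
        One row per gene: gene, log2FC, s2_g, t_mod, df_total, p, q,
        direction; q is the Benjamini-Hochberg adjusted p.
    """
    labels = labels.reindex(m.sample_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    y = labels.to_numpy(int)
    n1 = int((y == 1).sum())  # nonresponders
    n0 = int((y == 0).sum())
    if min(n0, n1) < 2:
        raise ValueError("each group needs at least 2 samples")

    x = m.values.to_numpy(float)
    g1 = x[:, y == 1]
    g0 = x[:, y == 0]
    lfc = g1.mean(axis=1) - g0.mean(axis=1)
    df_resid = n0 + n1 - 2
    ss = ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (g0 - g0.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if force_d0 is not None:
        d0 = float(force_d0)
        _, s0_sq = _fit_f_dist(np.maximum(s2, 1e-300), df_resid)
        if d0 == 0:
            s0_sq = 0.0  # unused
    else:
        d0, s0_sq = _fit_f_dist(np.maximum(s2, 1e-300), df_resid)

    if np.isinf(d0):
        s_tilde_sq = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s_tilde_sq = s2
        df_total = float(df_resid)
    else:
        s_tilde_sq = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s_tilde_sq * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    if not np.isfinite(t).all():
        raise ValueError(
            "non-finite moderated t (zero residual and prior variance); "
            "check for constant genes"
        )
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": m.gene_ids,
            "log2FC": lfc,
            "s2_g": s2,
            "t_mod": t,
            "df_total": df_total,
            "p": p,
            "q": q,
            "direction": np.where(lfc >= 0, "up", "down"),
        }
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(
    records: pd.DataFrame,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
) -> DEGResult:
    """Keep genes with |log2FC| strictly above ``lfc_min`` and q strictly
    below ``q_max``; both thresholds are strict inequalities.
    """
    keep = (records["log2FC"].abs() > lfc_min) & (records["q"] < q_max)
    table = records.loc[keep].reset_index(drop=True)
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    return DEGResult(table=table, n_total=len(table), n_up=n_up, n_down=n_down)
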