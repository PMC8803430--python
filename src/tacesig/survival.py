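"""Survival comparison of predicted response groups.

Kaplan–Meier curves with the log-rank test for the group contrast, Cox
proportional-hazards regression (uni- and multivariate, reporting hazard
ratios with Wald 95% intervals), and time-dependent ROC at fixed horizons
using the IPCW cumulative-cases / dynamic-controls estimator. Times are in
months throughout; event = 1 means the event was observed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.metrics import cumulative_dynamic_auc

__all__ = ["km_estimate", "logrank", "cox_fit", "time_dependent_roc"]


def _check_times(t: np.ndarray) -> None:
    if (t <= 0).any():
        raise ValueError("survival times must be positive")


def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit survival curve.

    Returns a DataFrame with columns ``time`` and ``survival`` giving the
    step function S(t) at each distinct observed time (S(0) = 1 implicitly;
    S is nonincreasing).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    _check_times(t)
    if len(t) == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    out = sf.reset_index()
    out.columns = ["time", "survival"]
    return out[out["time"] > 0].reset_index(drop=True)


def logrank(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, two-sided p)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    _check_times(t)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    if e.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    mask = g == levels[0]
    res = logrank_test(t[mask], t[~mask], e[mask], e[~mask])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    table: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit over the given covariates.

    Returns one row per covariate: covariate, coef, HR, ci_low, ci_high, p
    (Wald). Passing a single covariate gives the univariate analysis; a
    list gives the multivariate model. Warns when events are scarce
    relative to the number of covariates (rule of thumb: 5 events each).
    """
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise KeyError(f"covariates absent from table: {missing}")
    _check_times(table[time_col].to_numpy(float))
    n_events = int(table[event_col].sum())
    if n_events < 5 * len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} covariate(s); "
            "hazard ratios may be unstable",
            stacklevel=2,
        )
    cph = CoxPHFitter()
    cph.fit(
        table[[time_col, event_col, *covariates]],
        duration_col=time_col,
        event_col=event_col,
    )
    summ = cph.summary
    return pd.DataFrame(
        {
            "covariate": summ.index,
            "coef": summ["coef"].to_numpy(),
            "HR": summ["exp(coef)"].to_numpy(),
            "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
            "p": summ["p"].to_numpy(),
        }
    ).reset_index(drop=True)


def time_dependent_roc(
    score,
    time,
    event,
    horizons: tuple[float, ...] = (12.0, 36.0, 60.0),
) -> dict[float, float]:
    """AUC(t) for event-by-horizon prediction at each horizon (months).

    Cumulative-cases / dynamic-controls estimator with inverse-probability-
    of-censoring weights from the Kaplan–Meier censoring distribution. A
    horizon with no case or no control under follow-up is reported as NaN
    rather than raising.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int).astype(bool)
    s = np.asarray(score, dtype=float)
    _check_times(t)
    y = np.array(list(zip(e, t)), dtype=[("event", "?"), ("time", "<f8")])
    out: dict[float, float] = {}
    for h in horizons:
        has_case = bool(((t <= h) & e).any())
        has_control = bool((t > h).any())
        if not has_case or not has_control or h >= t.max():
            out[float(h)] = float("nan")
            continue
        auc, _ = cumulative_dynamic_auc(y, y, s, [h])
        out[float(h)] = float(auc[0])
    return out
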