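"""Synthetic cohorts with planted ground truth.

Every generator here is a pure function of its parameters and seed, and
emulates the statistical structure the analysis pipeline assumes: two-group
log2 expression with planted fold changes, labels driven by a small set of
informative genes, survival times whose hazard depends on a signature
score, bulk mixtures of known cell-type proportions, and a stemness
gradient tied to nonresponse.

Label model. Groups have fixed sizes (responders = 0, nonresponders = 1)
and planted differential genes are shifted by +-``effect`` log2 units in
nonresponders on a Normal(baseline, noise_sd) background. Because the two
class-conditional distributions are equal-variance Gaussians, the posterior
probability of nonresponse given the informative genes is exactly a
logistic function of a linear score with weight ``+-effect / noise_sd**2``
per informative gene; those weights are recorded as the planted linear
truth. Class overlap (hence attainable accuracy) is controlled by
``effect / noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "CohortTruth",
    "generate_cohort",
    "generate_survival",
    "generate_mixtures",
    "write_demo_inputs",
]


@dataclass
class CohortTruth:
    """Planted ground truth accompanying a synthetic cohort."""

    deg_genes: dict[str, float]  # gene -> planted log2 fold change (nonresp - resp)
    informative_genes: dict[str, float]  # gene -> planted linear weight
    labels: pd.Series  # sample -> 0 (responder) / 1 (nonresponder)
    survival_beta: float | None = None
    censor_rate: float | None = None
    mix_proportions: pd.DataFrame | None = None  # samples x cell types, rows sum to 1
    stemness_shift: float = 0.0
    stemness_weights: pd.Series | None = None  # gene -> weight used for the gradient

    def __post_init__(self) -> None:
        if any(lfc == 0 for lfc in self.deg_genes.values()):
            raise ValueError("planted log2FC values must be nonzero")
        if self.mix_proportions is not None:
            sums = self.mix_proportions.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("mix_proportions rows must sum to 1")


def generate_cohort(
    n_resp: int,
    n_nonresp: int,
    n_genes: int,
    n_deg: int,
    effect: float,
    n_informative: int | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline_range: tuple[float, float] = (6.0, 10.0),
    n_stemness_genes: int = 0,
    stemness_shift: float = 0.0,
) -> tuple[ExpressionMatrix, pd.Series, CohortTruth]:
    """Simulate a two-group expression cohort with planted differential genes.

    Parameters
    ----------
    n_resp, n_nonresp : int
        Group sizes (responders are labelled 0, nonresponders 1).
    n_genes : int
        Total genes; per-gene baselines are drawn uniformly from
        ``baseline_range`` (log2 intensity units).
    n_deg : int
        Number of genes shifted between groups; half up and half down in
        nonresponders (the extra gene of an odd count goes up).
    effect : float
        Absolute planted log2 fold change of each shifted gene.
    n_informative : int, optional
        How many of the shifted genes are recorded as the label-driving
        truth (defaults to all of them); must not exceed ``n_deg``.
    noise_sd : float
        Within-group SD of every gene (log2 units).
    n_stemness_genes, stemness_shift : int, float
        When positive, that many additional genes receive a nonresponder
        offset of ``stemness_shift * w_g`` where the ``w_g`` are positive
        weights emitted in the truth object, creating a stemness-like
        gradient correlated with nonresponse.

    Returns
    -------
    (ExpressionMatrix, labels, CohortTruth)
        Matrix is genes x samples on the raw log scale; identical arguments
        and seed give an identical matrix.
    """
    if min(n_resp, n_nonresp, n_genes) <= 0:
        raise ValueError("n_resp, n_nonresp and n_genes must be positive")
    if n_deg < 0 or n_deg > n_genes:
        raise ValueError("need 0 <= n_deg <= n_genes")
    if n_informative is None:
        n_informative = n_deg
    if n_informative > n_deg:
        raise ValueError("n_informative cannot exceed n_deg")
    if n_deg and effect <= 0:
        raise ValueError("effect must be positive when planting DEGs")
    if n_stemness_genes + n_deg > n_genes:
        raise ValueError("not enough genes for DEGs plus stemness genes")

    rng = np.random.default_rng(seed)
    n = n_resp + n_nonresp
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n)]
    labels = pd.Series(
        np.r_[np.zeros(n_resp, int), np.ones(n_nonresp, int)],
        index=samples,
        name="label",
    )

    baseline = rng.uniform(*baseline_range, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n))

    n_up = (n_deg + 1) // 2
    deg_lfc = np.r_[np.full(n_up, effect), np.full(n_deg - n_up, -effect)]
    nonresp_mask = labels.to_numpy() == 1
    values[:n_deg, nonresp_mask] += deg_lfc[:, None]

    deg_genes = {genes[i]: float(deg_lfc[i]) for i in range(n_deg)}
    # equal-variance Gaussian classes => logistic posterior with these weights
    informative = {
        genes[i]: float(deg_lfc[i] / noise_sd**2) for i in range(n_informative)
    }

    stem_weights = None
    if n_stemness_genes > 0:
        stem_idx = np.arange(n_deg, n_deg + n_stemness_genes)
        w = rng.uniform(0.5, 1.5, size=n_stemness_genes)
        values[stem_idx[:, None], np.where(nonresp_mask)[0][None, :]] += (
            stemness_shift * w[:, None]
        )
        stem_weights = pd.Series(w, index=[genes[i] for i in stem_idx], name="weight")

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale_tag="raw_log"
    )
    truth = CohortTruth(
        deg_genes=deg_genes,
        informative_genes=informative,
        labels=labels,
        stemness_shift=stemness_shift,
        stemness_weights=stem_weights,
    )
    return matrix, labels, truth


def generate_survival(
    scores: pd.Series,
    beta: float,
    base_hazard: float = 0.05,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw exponential event times whose hazard scales with a sample score.

    Event times are ``Exponential(base_hazard * exp(beta * score))`` (months);
    censoring is independent ``Uniform(0, c)`` with ``c`` calibrated by
    bisection so the expected censored fraction matches ``censor_rate``.

    Returns a DataFrame indexed by sample with columns ``time`` and
    ``event`` (1 = event observed, 0 = censored).
    """
    if base_hazard <= 0:
        raise ValueError("base_hazard must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    s = scores.to_numpy(float)
    hazard = base_hazard * np.exp(beta * s)
    times = rng.exponential(1.0 / hazard)

    event = np.ones(len(times), dtype=int)
    obs = times.copy()
    if censor_rate > 0:
        u = rng.uniform(size=len(times))
        # P(censored | c) = mean_i min(t_i, c*u_i ... ) — with C_i = c*u_i,
        # sample i is censored iff c*u_i < t_i; solve for c by bisection.
        lo, hi = 1e-12, float(times.max()) / max(u.min(), 1e-12) + 1.0

        def frac_censored(c: float) -> float:
            return float(np.mean(c * u < times))

        # frac is nonincreasing in c; find c with frac ~ censor_rate
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if frac_censored(mid) > censor_rate:
                lo = mid
            else:
                hi = mid
        c = hi
        cens_times = c * u
        censored = cens_times < times
        obs = np.where(censored, cens_times, times)
        event = (~censored).astype(int)
    if (obs <= 0).any():
        raise ValueError("degenerate survival draw: nonpositive observed time")
    return pd.DataFrame({"time": obs, "event": event}, index=scores.index)


def generate_mixtures(
    signature: pd.DataFrame,
    proportions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Mix signature-matrix columns into bulk profiles with known proportions.

    ``bulk = signature @ proportions.T + Normal(0, noise_sd)``, truncated at
    zero. ``proportions`` is samples x cell types and every row must lie on
    the simplex. Mixing is linear in intensity, so the returned matrix is
    tagged ``linear`` and feeds straight into deconvolution.
    """
    if list(proportions.columns) != list(signature.columns):
        raise ValueError("proportions columns must match signature cell types")
    p = proportions.to_numpy(float)
    if (p < 0).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("proportion rows must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    bulk = signature.to_numpy(float) @ p.T
    if noise_sd > 0:
        bulk = bulk + rng.normal(0.0, noise_sd, size=bulk.shape)
    bulk = np.clip(bulk, 0.0, None)
    df = pd.DataFrame(bulk, index=signature.index, columns=proportions.index)
    return ExpressionMatrix(df, scale_tag="linear")


def write_demo_inputs(
    out_dir,
    seed: int = 42,
    n_resp: int = 60,
    n_nonresp: int = 48,
    n_genes: int = 300,
    n_deg: int = 20,
    effect: float = 2.0,
    survival_beta: float = 1.5,
) -> dict:
    """Write a complete on-disk input set for a pipeline run.

    Generates a development cohort, an external cohort sharing the gene
    universe (with its own labels and survival times whose hazard follows
    the true label), a small GMT with one planted and one random set, a
    toy cell-type signature matrix over a gene subset, and a synthetic
    stemness weight vector. Returns a dict with the written paths, the
    development truth and the external truth.
    """
    from pathlib import Path

    from .io import GeneSetCollection, write_gmt, write_labels, write_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m, labels, truth = generate_cohort(
        n_resp, n_nonresp, n_genes, n_deg, effect,
        seed=seed, n_stemness_genes=min(30, n_genes - n_deg), stemness_shift=0.5,
    )
    ext, ext_labels, ext_truth = generate_cohort(
        n_resp, n_nonresp, n_genes, n_deg, effect,
        seed=seed + 1, n_stemness_genes=min(30, n_genes - n_deg), stemness_shift=0.5,
    )
    ext.values.columns = [f"E{i:03d}" for i in range(ext.shape[1])]
    ext_labels.index = ext.values.columns
    surv = generate_survival(
        ext_labels.astype(float), beta=survival_beta,
        base_hazard=1.0 / 40.0, censor_rate=0.2, seed=seed + 2,
    )
    surv_table = surv.reset_index(names="sample")
    up = [g for g, lfc in truth.deg_genes.items() if lfc > 0]
    rng = np.random.default_rng(seed + 3)
    rand = list(rng.choice(m.gene_ids, size=max(10, len(up)), replace=False))
    sets = GeneSetCollection({"PLANTED_UP": up, "RANDOM_SET": rand})
    sig_genes = list(rng.choice(m.gene_ids, size=40, replace=False))
    sig = pd.DataFrame(
        rng.uniform(1.0, 10.0, size=(40, 3)),
        index=sig_genes,
        columns=["cellA", "cellB", "cellC"],
    )
    paths = {
        "matrix": out / "matrix.tsv",
        "labels": out / "labels.tsv",
        "external_matrix": out / "external_matrix.tsv",
        "external_labels": out / "external_labels.tsv",
        "survival_table": out / "survival.tsv",
        "gmt": out / "sets.gmt",
        "signature_matrix": out / "cell_signature.tsv",
        "stemness_weights": out / "stemness_weights.tsv",
    }
    write_matrix(m, paths["matrix"])
    write_labels(labels, paths["labels"])
    write_matrix(ext, paths["external_matrix"])
    write_labels(ext_labels, paths["external_labels"])
    surv_table.to_csv(paths["survival_table"], sep="\t", index=False)
    write_gmt(sets, paths["gmt"])
    sig.to_csv(paths["signature_matrix"], sep="\t")
    truth.stemness_weights.to_csv(
        paths["stemness_weights"], sep="\t", header=False
    )
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "truth": truth,
        "external_truth": ext_truth,
        "external_labels": ext_labels,
    }
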