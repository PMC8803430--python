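# Methods

This note documents the models behind each `tacesig` module, the
parameters that matter, the choices made where the design was open, and
what the synthetic cohorts do and do not establish about real data.

## Synthetic cohorts

`simulate.generate_cohort(n_resp, n_nonresp, n_genes, n_deg, effect,
n_informative, noise_sd, seed)` emulates a two-group bulk expression
cohort on the log2 scale. Per-gene baselines are uniform on [6, 10]
(log2 intensity units); within-group variation is iid
Normal(0, `noise_sd`) with `noise_sd = 1` by default. `n_deg` genes are
shifted by ±`effect` log2 units in nonresponders, half up and half down
(the near-balanced split seen in real response cohorts). Group sizes are
fixed; the default development-scale configuration is 81 responders vs
66 nonresponders (n = 147).

Because the two class-conditional distributions are equal-variance
Gaussians, the posterior P(nonresponse | informative genes) is exactly a
logistic function of a linear score whose per-gene weight is
±`effect`/`noise_sd`²; these weights are recorded as the planted linear
truth, and `effect`/`noise_sd` controls class overlap. At the calibrating
configuration (effect 2, noise 1, n = 147) a linear read-out of the
informative genes reaches AUC > 0.9, i.e. the label is learnable but not
trivially separable.

`generate_survival` draws event times from
Exponential(h₀ · exp(β · score)) in months (h₀ default 0.05 ≈ 20-month
mean); censoring is independent Uniform(0, c) with c calibrated by
bisection so the realized censored fraction matches the requested rate.
`generate_mixtures` forms bulk = S·pᵀ + Normal(0, σ) truncated at zero,
with p on the simplex. An optional stemness gradient adds
`stemness_shift · w_g` to nonresponders for a block of positive-weight
genes, creating a higher stemness index in the nonresponse group.

What the simulator does **not** emulate: probe-level microarray
artifacts, batch effects, correlated gene modules, heavy-tailed
intensity distributions, or informative censoring. Passing tests
therefore demonstrate correctness of the machinery and recoverability
under the stated generative model, not performance on any particular
real cohort.

## Preprocessing

Probes mapping to several genes or lacking a gene annotation are
discarded; among a gene's remaining probes the one with maximal mean
expression across all samples is kept (ties broken toward the
lexicographically smallest probe id, for determinism). Z-scores use the
sample SD (denominator n − 1); constant genes are dropped with a warning
rather than imputed, since a z-score is undefined and downstream models
must never see NaN. Each cohort is z-scored separately — development and
validation matrices are normalized within themselves.

## Moderated t differential expression

The per-gene pooled two-group variance s²_g (d_g = n₁ + n₂ − 2 df) is
shrunk toward a common prior s₀² with d₀ prior df:
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), and
t_g = log2FC_g / (s̃_g √(1/n₁ + 1/n₂)) is referred to t(d₀ + d_g).
(d₀, s₀²) are estimated by moment matching on log s²_g under the scaled-F
model: var(log s²_g) − ψ′(d_g/2) = ψ′(d₀/2) (solved by bracketed root
finding) and s₀² from the mean. When the spread of log-variances does not
exceed sampling noise, d₀ = ∞ and the statistic uses the common prior
variance with a normal reference. A `force_d0` flag exposes both limits
(d₀ = 0: ordinary pooled t; d₀ = ∞: fixed-denominator statistic) for
verification; the suite cross-checks the full estimator against the
reference empirical-Bayes implementation in R on a heteroscedastic
fixture (agreement ~1e-10 in p-values).

Conventions: log2FC = mean(nonresponders) − mean(responders), so "up"
means upregulated in nonresponders (stated in the output header). DEG
thresholds are strict: |log2FC| > 1 and BH q < 0.05. Differential
expression runs on log intensities (not z-scores), the scale on which a
log fold change is meaningful; the pipeline keeps both matrices.

## Single-sample gene-set scores

Within each sample, genes receive ascending expression ranks (average on
ties). Walking the genes in descending expression order, in-set genes
advance a running statistic by rank^τ normalized by total in-set weight
and out-of-set genes retreat it by rank^τ normalized by total out-of-set
weight; the score is the mean running difference over all positions.
Defaults: τ = 0.25, minimum mapped set size 5.

Weighting *both* step types is deliberate: with unweighted out-steps the
statistic has a positive null mean for random sets (≈ +0.055, SD 0.063,
at N = 300, k = 20, τ = 0.25, measured by simulation), because high-rank
weights make the in-set walk lead systematically. The symmetric weighting
centres the null (≈ −0.004) so group contrasts of random sets are
unbiased. The statistic is rank-based, hence invariant to any strictly
monotone per-sample transform. This scorer is a deliberately simple
single-sample enrichment statistic: group contrasts of per-sample pathway
activity are its tested use; it does not reproduce kernel-CDF-based
enrichment scores numerically.

## Stability selection

R = 10 iterations; each draws a stratified 80/20 split (test size =
round(0.2·n), seats allocated to classes by largest-remainder rounding so
neither side loses a class — plain random splits can produce degenerate
folds at n = 147). Hyperparameters are tuned on the training 80% only:
5-fold grid-search CV (AUC) for the linear models and the neural net, and
a seeded randomized search over the space for the tree ensembles — a
deterministic stochastic search playing the role usually given to
Bayesian optimisation. Search spaces are small, fixed and
version-controlled in `_models.py`.

Importances: |coefficient| for lasso-logistic and linear SVM; native
impurity/gain importances for random forest and XGBoost; for the neural
net, the mean absolute change in predicted nonresponse probability when
a feature is permuted across the held-out 20% (5 repeats, seeded) — a
model-agnostic stand-in for Shapley attributions, chosen over score-drop
permutation importance because redundant informative features can leave
the test AUC unchanged (an all-zero score-drop vector) while still
moving individual predictions. `_models.ann_attribution` is a hook for
plugging an exact-SHAP callable. Ranks are 1..G with ties broken by (importance desc, gene id
asc). A gene is flagged when its rank ≤ ⌊top_frac·G⌋ (⌊0.2·373⌋ = 74 at
the reference universe size).

The ledger records, per gene: occurrence (flagged iterations),
ranking_sum, and average_rank = ranking_sum/occurrence to one decimal.
Two ranking-sum accountings are provided because the definition is
genuinely ambiguous: the default sums full-universe ranks over flagged
iterations only; `ranking_over="all"` sums over every iteration. Genes
with occurrence ≥ 8 (of 10) that are present in the external cohort's
gene universe are selected, ordered by (occurrence desc, average_rank
asc, gene id asc). The ≥ 8 reading (rather than strictly > 8) is used
throughout.

## Signature fitting and calibration

Candidate families are re-trained over 10 seeded 80/20 rounds on the
selected genes; the eight metrics (AUC, F1, accuracy, Youden J,
sensitivity, specificity, PPV, NPV) are averaged per metric and the
family with the highest mean AUC wins. AUC uses the Mann–Whitney rank
form with half credit for ties (verified against all-pairs concordance
to 1e-12); undefined PPV/NPV (empty predicted class) are excluded from
averaging with a logged count, never coerced to 0. Since averaging is per
metric, mean Youden = mean sensitivity + mean specificity − 1 holds
exactly for the reported averages.

The final model is a linear classifier fitted on the full development
cohort (default linear SVM, squared-hinge, C tuned by the usual 5-fold
search). A margin threshold of 0 has no probabilistic meaning, so a
Platt-style sigmoid P = σ(a·margin + b) is fitted to the development
margins by logistic regression (near-unpenalized); a > 0 is required,
making P strictly monotone in each gene with the sign of its weight.
External samples are called nonresponse when P > 0.5. Missing signature
genes in an external matrix are an error, never silently imputed.

## Survival analysis

Kaplan–Meier estimation, the two-group log-rank test and Cox
proportional-hazards regression are delegated to lifelines behind the
module interface; hazard ratios are exp(coef) with Wald 95% intervals.
Simulated event times are continuous, so tie-handling variants coincide.
A warning fires when events < 5 per covariate. Time-dependent ROC uses
the IPCW cumulative-cases/dynamic-controls estimator
(scikit-survival's implementation) at 12/36/60-month horizons; a horizon
with no case, no control, or beyond follow-up reports NaN rather than
raising. Calibration is established by simulation: the Cox fit recovers
a planted log-HR of 0.7 within 3·SE at n = 300, and the null (β = 0)
95% CI covers HR = 1 at the nominal rate over seeded repeats.

## Deconvolution and stemness

Cell fractions come from nonnegative least squares of each bulk profile
on the marker-gene signature matrix, renormalized to the simplex. Mixing
is linear in intensity, so raw_log matrices are de-logged (2^x) first and
z-scored matrices are rejected outright. At least 50% of signature genes
must be present (configurable). NNLS with sum-normalization is a
transparent convex stand-in for support-vector regression deconvolution;
no permutation p-values are computed, and group contrasts of the
fractions (independent t-tests with BH adjustment) are the tested
surface.

The stemness index of a sample is the Spearman correlation ρ between its
expression over the weighted genes and a stem-cell-derived weight vector
(consumed as input; training such weights is out of scope), min-max
scaled to [0, 1] **within the scored cohort** — the index is relative to
the cohort being scored, and cohorts scored jointly vs separately will
differ by a monotone rescaling. A constant-ρ cohort maps to all zeros
with a warning.

## Pipeline

One master seed derives per-stage seeds as
(seed + crc32(stage_name)) mod 2³¹, giving independent reproducible
streams. Every stage writes its artifact with fixed float formatting and
records a fingerprint (upstream checksums + parameters) plus output
checksums in `run_manifest.json`; two runs with identical inputs,
config and seed are byte-identical, and `resume=True` skips stages whose
fingerprint and outputs are intact. Filtered entities (dropped probes,
constant genes, undersized gene sets, undefined metrics) are always
counted in logs or warnings, never silently discarded.

## Problem sizes used in the shipped checks

The test suite and acceptance script use development-scale cohorts
(n = 147; 400 genes with 10 informative for selection, 2 000 genes with
100 planted for differential expression), 10 resampling rounds per
family, 150 repeats for CI coverage, and n = 300 for Cox recovery —
sizes at which the targeted statistical properties are identifiable and
the whole suite runs on a laptop.

## Known limitations

- The gene-set scorer and the deconvolution are deliberate stand-ins for
  heavier kernel-CDF and ν-SVR methods; their group-contrast directions,
  not their numeric scores, are the supported output.
- The neural-net importance is permutation-based, which underestimates
  the importance of correlated features relative to Shapley values.
- Exponential survival with uniform censoring is the simplest model with
  a known Cox answer; real cohorts violate proportional hazards in ways
  the simulator does not probe.
- Cross-cohort prediction assumes the external matrix is z-scored within
  itself; strong cohort-level shifts in gene variance will distort
  calibrated probabilities even when ranking is preserved.
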