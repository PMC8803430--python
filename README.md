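# tacesig

Gene-expression signatures for predicting response to transarterial
chemoembolization (TACE) in hepatocellular carcinoma, built by
occurrence-based stability selection, plus the surrounding transcriptomic
analysis stages — all runnable and testable on synthetic cohorts with
planted ground truth.

## Who this is for

Computational biologists building treatment-response classifiers from
bulk expression cohorts (typically microarray log2 intensities with a
binary clinical label), and anyone who wants a tested, deterministic
implementation of the resampling-based gene-selection procedure at the
core of such signatures.

## What it does

Given a genes × samples matrix with responder/nonresponder labels, the
package chains:

1. **Preprocessing** (`tacesig.io`) — probe→gene collapsing (keep the
   probe with maximal mean expression), per-gene z-scoring
   (sample SD, n−1), GMT gene sets, signature matrices, weight vectors.
2. **Differential expression** (`tacesig.diffexpr`) — empirical-Bayes
   moderated t: pooled per-gene variance s²_g shrunk toward a prior s₀²
   with d₀ df estimated by moment matching on log s²_g;
   t_g = log2FC_g / (s̃_g · √(1/n₁ + 1/n₂)) referred to t(d₀ + d_g).
   DEGs are |log2FC| > 1 and Benjamini–Hochberg q < 0.05 (both strict);
   log2FC is mean(nonresponders) − mean(responders).
3. **Gene-set scoring** (`tacesig.gsea`) — single-sample, rank-based
   enrichment via a weighted Kolmogorov–Smirnov random walk
   (in/out steps weighted by rank^τ, τ = 0.25), with Welch-t group
   contrasts.
4. **Stability selection** (`tacesig.stability`) — R = 10 stratified
   80/20 splits; per split a model family (lasso-logistic, linear SVM,
   neural net, random forest, gradient-boosted trees) is tuned on the
   training 80% and every gene ranked by its importance; genes ranked in
   the top 20% (⌊0.2·G⌋) earn an *occurrence*; genes with occurrence ≥ 8
   that are present in the external cohort become signature candidates.
5. **Signature** (`tacesig.signature`) — families re-compared over seeded
   rounds by mean AUC; the final linear model is fit on the full cohort,
   exposing per-gene weights w_g (positive ⇒ toward nonresponse), an
   intercept, and a Platt-style sigmoid calibrator so external samples
   are called nonresponse when P(nonresponse) > 0.5.
6. **Survival** (`tacesig.survival`) — Kaplan–Meier curves, log-rank
   test, Cox proportional hazards (HR with Wald 95% CI), and IPCW
   time-dependent ROC at 12/36/60 months for the predicted groups.
7. **Microenvironment** (`tacesig.microenv`) — NNLS cell-fraction
   deconvolution against a marker signature matrix, group t-tests, and
   the mRNA stemness index (Spearman ρ against stem-cell-derived weights,
   min-max scaled to [0,1] within the cohort).
8. **Pipeline** (`tacesig.pipeline`) — config-driven orchestration with
   one master seed, checksummed per-stage artifacts and byte-identical
   reruns.

`tacesig.simulate` generates all of the above's inputs with known truth:
planted log2 fold changes, labels driven by informative genes through a
logistic posterior, exponential survival with hazard exp(β·score), bulk
mixtures on the simplex, and a stemness gradient tied to nonresponse.

## Worked example

```bash
python examples/03_stability_selection.py
```

```
  gene  occurrence  ranking_sum  average_rank
G00008          10           23           2.3
G00001          10           30           3.0
G00005          10           34           3.4
...
selected (occurrence >= 8): 34 genes
planted genes among them:   10/10
```

Each row is one gene's ledger over 10 resampling rounds: `occurrence` is
how often it ranked in the top 20% of all genes by linear-SVM weight,
`ranking_sum` adds its full-universe ranks over those flagged rounds, and
`average_rank = ranking_sum / occurrence` (one decimal). All ten planted
informative genes are flagged in every round and pass the occurrence ≥ 8
filter. Continuing with `examples/04_signature_and_survival.py`:

```
development AUC 1.000  accuracy 1.000
external log-rank p = 5.33e-16
predicted nonresponse HR = 4.82 (3.20-7.24)
12-month time-dependent AUC = 0.771
```

The fitted signature separates the development cohort, and the groups it
predicts in an unseen external cohort have sharply different survival —
the hazard ratio of predicted nonresponse is well above 1 because the
signature tracks the label that drives the simulated hazard.

## Layout

```
src/tacesig/      library modules (io, simulate, diffexpr, gsea,
                  stability, signature, metrics, survival, microenv,
                  pipeline)
examples/         narrative scripts, one per capability
tests/            pytest suite incl. end-to-end acceptance checks
docs/methods.md   models, assumptions, parameter choices, limitations
```
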