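"""Fit the final linear signature, predict an external cohort, and
stratify its survival.

The linear SVM is refit on the full development cohort over the selected
genes; its calibrated probabilities call each external sample response or
nonresponse at 0.5, and the predicted groups are compared with a log-rank
test, a Cox model and a 12-month time-dependent AUC.
"""

from tacesig import io, signature, stability, survival
from tacesig.metrics import compute_metrics
from tacesig.simulate import generate_cohort, generate_survival

# development cohort and candidate genes
m, labels, truth = generate_cohort(81, 66, 400, 10, 2.0, seed=7)
mz = io.zscore(m)
res = stability.run_iterations(mz, labels, "linear_svm", rounds=10, base_seed=42)
selected = stability.select_genes(stability.accumulate_occurrence(res))

model = signature.fit_final(mz, labels, selected, family="linear_svm", seed=5)
dev_row = compute_metrics(
    labels.to_numpy(), signature.predict_cohort(model, mz)["probability"].to_numpy()
)
print(f"development AUC {dev_row.auc:.3f}  accuracy {dev_row.accuracy:.3f}")

# external cohort: same generative truth, fresh draws; survival hazard
# follows the true label (beta = 1.5 per unit)
ext, ext_labels, _ = generate_cohort(81, 66, 400, 10, 2.0, seed=8)
preds = signature.predict_cohort(model, io.zscore(ext))
sv = generate_survival(
    ext_labels.astype(float), beta=1.5, base_hazard=1 / 40, censor_rate=0.2, seed=9
)
chi2, p = survival.logrank(sv["time"], sv["event"], preds["call"].to_numpy())
cox = survival.cox_fit(
    sv.assign(predicted_nonresponse=preds["call"].to_numpy()),
    ["predicted_nonresponse"],
)
roc = survival.time_dependent_roc(
    preds["probability"], sv["time"], sv["event"], horizons=(12.0,)
)
print(f"external log-rank p = {p:.2e}")
hr = cox.loc[0, "HR"]
print(f"predicted nonresponse HR = {hr:.2f} "
      f"({cox.loc[0, 'ci_low']:.2f}-{cox.loc[0, 'ci_high']:.2f})")
print(f"12-month time-dependent AUC = {roc[12.0]:.3f}")
# predicted nonresponders should die faster: HR well above 1 and a tiny
# log-rank p, because the signature tracks the label driving the hazard.
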