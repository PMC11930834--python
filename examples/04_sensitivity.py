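"""E-value for unmeasured confounding and in-sample ROC/AUC of the model.

The E-value says how strong an unmeasured confounder would have to be, on
the risk-ratio scale, to explain away the adjusted association; the AUC
summarises how well the fitted probabilities separate the outcome classes.
"""

from pharmepi.sensitivity import evalue, predicted_scores, roc_auc
from pharmepi.surveystats import ModelSpec, SurveyDesign, fit_weighted_logistic
from pharmepi.synthdata import SurveyGenParams, gen_survey_cohort

cohort, _ = gen_survey_cohort(SurveyGenParams(n_participants=20_000, seed=11))
design = SurveyDesign.from_frame(cohort)
fit = fit_weighted_logistic(cohort, design, ModelSpec(tier="model3"))
row = fit.summary.loc["exposure"]
print(f"adjusted exposure OR {row['odds_ratio']:.2f} "
      f"({row['ci_low']:.2f}, {row['ci_high']:.2f})")

ev = evalue(row["odds_ratio"], (row["ci_low"], row["ci_high"]))
print(f"E-value: point {ev.evalue_point:.2f}, CI limit {ev.evalue_ci:.2f} "
      f"({ev.conversion} conversion)")
# A confounder would need risk ratios of that size with BOTH exposure and
# outcome to fully explain the association.

scores = predicted_scores(fit, cohort)
labels = (cohort["outcome"] == "memory_loss").astype(int).to_numpy()
roc = roc_auc(scores, labels)
print(f"AUC {roc.auc:.3f} (95% CI {roc.ci[0]:.3f}-{roc.ci[1]:.3f}), "
      f"{roc.n_pos} cases vs {roc.n_neg} non-cases")
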