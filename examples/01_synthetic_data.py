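"""Generate both synthetic datasets and inspect their planted ground truth.

The survey generator plants a conditional odds ratio of 0.47 for exposure on
the memory outcome behind positive confounding; the report generator plants
over-reporting of two adverse-event terms among target-drug reports.
"""

from pharmepi.synthdata import (
    ReportGenParams,
    SurveyGenParams,
    analytic_ror,
    gen_reports,
    gen_survey_cohort,
)

cohort, truth = gen_survey_cohort(SurveyGenParams(n_participants=10_000, seed=1))
print(cohort[["exposure", "outcome", "age", "race", "survey_weight", "stratum", "psu"]].head())
print(f"\nexposure prevalence: {(cohort.exposure == 'exposed').mean():.3f} (target 0.11)")
print(f"outcome prevalence:  {(cohort.outcome == 'memory_loss').mean():.3f} (target 0.043)")
print(f"planted conditional OR: {2.718281828459045 ** truth.realized['log_conditional_or']:.2f}")

params = ReportGenParams(
    n_reports=100_000, planted_signals=(("PT_010", 5.0),), seed=2
)
reports, rtruth = gen_reports(params)
print(f"\n{len(reports)} spontaneous reports, "
      f"{reports.is_target_drug.sum()} for the target drug")
print(f"analytic ROR implied by the generator for PT_010: "
      f"{analytic_ror(params, 'PT_010'):.2f}")
# The analytic ROR is the value disproportionality analysis should recover
# as the report stream grows.
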