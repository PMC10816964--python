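"""Score a single respondent with every screening instrument.

Builds one fictitious middle-aged male driver and prints his BAMSA,
STOP-BANG (both neck-circumference variants), NoSAS, Berlin and ESS
results, plus the questionnaire-to-visit BMI calibration.
"""

from bamsa import (
    RespondentRecord,
    calibrate_questionnaire_measurement,
    score_bamsa,
    score_berlin,
    score_ess,
    score_nosas,
    score_stop_bang,
)

driver = RespondentRecord(
    id="example-1",
    sex="male",
    age_years=52.0,
    bmi_visit=31.5,
    neck_cm_visit=42.0,
    snoring_freq=4,        # snores 3-5 nights per week
    apnea_freq=2,          # witnessed pauses less than once per week
    tiredness_freq=3,
    hypertension=True,
    ess_items=(2, 1, 1, 0, 2, 1, 0, 1),
    berlin_cat1_positive_items=2,
    berlin_cat2_positive_items=1,
    ahi=18.0,
)

print(f"BAMSA (0-5):          {score_bamsa(driver)}   (>=4 flags moderate-severe OSA risk)")
print(f"STOP-BANG original:   {score_stop_bang(driver, 'original')}   (neck > 40 cm item)")
print(f"STOP-BANG new:        {score_stop_bang(driver, 'new')}   (male neck > 43 cm item)")
print(f"NoSAS (0-17):         {score_nosas(driver)}   (>=8 is high risk)")
berlin = score_berlin(driver)
print(f"Berlin:               {'high' if berlin.high_risk else 'low'} risk "
      f"({berlin.n_positive_categories} positive categories)")
print(f"ESS (0-24):           {score_ess(driver)}   (>10 is excessive sleepiness)")

bmi_self_report = 30.0
print(f"\nself-reported BMI {bmi_self_report:.1f} -> expected measured BMI "
      f"{calibrate_questionnaire_measurement(bmi_self_report, 'bmi'):.2f}")
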