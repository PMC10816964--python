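"""Regenerate every published accuracy row from its reconstructed table.

Each printed row (sensitivity/specificity rounded to the printed decimals,
with cohort size and reference-positive count) determines a unique integer
2x2 table; all derived statistics — PPV, NPV, likelihood ratios, odds
ratio and the dichotomized ROC area — are then recomputed and compared
with the printed cells after identical rounding.
"""

from bamsa import reproduce_paper_tables

report = reproduce_paper_tables()
df = report.summary_frame()
print(df[["table", "label", "tp", "fp", "fn", "tn", "n_matched", "pass"]].to_string(index=False))
print(f"\n{report.n_pass}/{report.n_rows} rows fully reproduced "
      "(every printed statistic matches after rounding)")
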