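"""Compare screening instruments' overall AUCs with the DeLong test.

On a large calibrated synthetic cohort, computes each instrument's
multi-cutoff AUC for moderate-severe OSA (AHI >= 15) and tests BAMSA
against each comparator.  The ESS is generated independent of AHI, so its
AUC sits at chance and the contrast with BAMSA is decisive; the
anthropometric instruments share BAMSA's risk factors and sit closer.
"""

from bamsa import calibrate_defaults, evaluate, generate_cohort

cohort = generate_cohort(calibrate_defaults(n=20_000, seed=42))
report = evaluate(
    cohort,
    ["bamsa:4", "stopbang:3", "stopbang_new:3", "nosas:8", "berlin:1", "ess:11"],
    "AHI>=15",
)

print(f"n = {report.n}, AHI>=15 in {100 * report.n_pos / report.n:.1f}%\n")
print("overall AUC (AHI >= 15):")
for name, value in sorted(report.overall_auc.items(), key=lambda kv: -kv[1]):
    print(f"  {name:<14s} {value:.3f}")

print("\nDeLong comparisons vs BAMSA:")
for (a, b), res in report.delong.items():
    if "bamsa" in (a, b):
        other = b if a == "bamsa" else a
        print(f"  bamsa vs {other:<14s} z = {res.z:+6.2f}   p = {res.p_value:.2e}")
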