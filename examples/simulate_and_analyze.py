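"""Simulate one fed-vs-fasted 2x2 crossover trial and run the full analysis.

The default design: 24 subjects (12 per sequence), single 4 mg doses in two
periods, 17 samples over 72 h, food raising the absorption rate (ka x2) and
bioavailability (x1.08).  The printed ratio table is the study's headline
output: geometric-mean-ratio point estimates with 90% CIs judged against the
80.00-125.00% average-bioequivalence window, and the distribution-free
Hodges-Lehmann shift for tmax (negative = earlier peak after food).
"""

from bectoss import default_config, run_analyze, simulate_trial, true_schedule_ratios

config = default_config(seed=42)
trial = simulate_trial(config)
bundle = run_analyze(trial)

truth = true_schedule_ratios(config)
print("configured (noise-free) fed/fasted ratios:",
      f"Cmax {100 * truth['cmax_ratio']:.1f}%,",
      f"AUC(0-72h) {100 * truth['auc_ratio']:.1f}%")

print("\nPer-arm summary statistics:")
print(bundle.descriptive_frame().to_string(index=False))

print("\nRatio table (ANOVA-log, 90% CI vs 80.00-125.00%):")
print(bundle.ratio_frame().to_string(index=False))

hl = bundle.tmax_nonparametric
print(f"\ntmax shift A-B (Hodges-Lehmann): {hl.hl_estimate:.2f} h, "
      f"{hl.achieved_confidence:.1%} CI [{hl.ci_lower:.2f}, {hl.ci_upper:.2f}] h")
print("A negative shift means the peak arrives earlier under fed conditions;")
print("an AUC CI inside the window with a Cmax CI above it is the signature")
print("of a rate-only food effect.")
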