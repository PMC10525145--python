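"""Train the seven classifiers (three single-feature, four composite) on a
scaled `combined` cohort and print the final validation accuracies.

Composites are transfer-initialized from the trained single-feature models
and start as their ensemble; the accuracy ordering (composites at or above
their constituents) quantifies how much non-redundant condition information
each feature family contributes.  Takes a couple of minutes on one CPU.
"""

from erpfuse import SamplingPlan, TrainingConfig, WaveletSpec, aggregate, \
    make_scenario, run_procedure, simulate_cohort

cohort = simulate_cohort(make_scenario("combined", n_participants=12,
                                       n_channels=8, seed=11))
wavelet = WaveletSpec(freqs=(4.0, 6.0, 8.0, 10.0, 12.0, 14.0))
plan = SamplingPlan(mode="trial_average", n_iterations=5, seed=42)
training = TrainingConfig(learning_rate=1e-4, momentum=0.9,
                          batch_size=50, n_epochs=200)

results = run_procedure(cohort, plan, wavelet, training)
summary = aggregate(results, final_window=plan.final_window)

print(f"{'model':>28s}  final accuracy (mean +/- SEM over "
      f"{plan.n_iterations} iterations)")
for name, stats in sorted(summary.items(), key=lambda kv: (kv[0].count('+'), kv[0])):
    print(f"{name:>28s}  {stats['mean']:.3f} +/- {stats['sem']:.3f}")
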