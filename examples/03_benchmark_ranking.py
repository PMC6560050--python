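"""Score synthetic density-functional predictions against references.

Generates a benchmark dataset with known per-functional biases, computes
signed errors and MSE/MUE/MaxE, classifies accuracy groups and prints the
ranking table.
"""

from redoxbench import (
    SyntheticBenchmarkSpec,
    format_report,
    gen_benchmark_dataset,
    report_table,
    signed_errors,
    summarize,
)

spec = SyntheticBenchmarkSpec(
    n_complexes=12,
    biases={"sharp": 0.5, "biased": 3.0, "noisy-neutral": 0.0},
    noise_sd=1.0,
    seed=42,
)
references, predictions, truth = gen_benchmark_dataset(spec)
errors = signed_errors(predictions, references)
summaries = summarize(errors)

print(format_report(report_table(summaries)))
print()
for s in summaries:
    print(f"{s.functional}: planted bias {truth.biases[s.functional]:+.1f}, "
          f"estimated MSE {s.mse:+.2f} kcal/mol, group {s.group}")
# MSE estimates each planted bias to within the sampling error
# (sd/sqrt(12) ~ 0.3 kcal/mol); the MUE-based groups separate the heavily
# biased functional (group II) from the accurate ones (group I, MUE below
# 2.31 kcal/mol = 0.1 V per electron).
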