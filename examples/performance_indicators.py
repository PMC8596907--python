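"""Score a quantification run with the six dilution-series indicators.

Simulates a biomarker-style experiment (20 genes x 5 levels x 3 replicates),
quantifies every curve, and computes: bias (extreme-ratio and log-log slope
forms), mean |relative error|, coefficient of variation, within-group
precision, and resolution (fold-width of the 95% prediction band).
All six are lower-is-better; resolution's optimum is 1.
"""

from cqman import (
    BIOMARKER_LEVELS,
    DilutionDesign,
    SimulationConfig,
    analyze_plate,
    build_f0_table,
    compute_indicators,
    simulate_dilution_plate,
)

config = SimulationConfig(efficiency=1.85, noise_sd=0.01, seed=11)
plate, _ = simulate_dilution_plate(BIOMARKER_LEVELS, 3, 20, config)
table = build_f0_table(analyze_plate(plate), plate)
design = DilutionDesign.from_levels(BIOMARKER_LEVELS, replicates_per_level=3)
report = compute_indicators(table, design)

print(f"bias |ratio - 10000|     : {report.bias_ratio_dev:10.1f}")
print(f"bias |slope - 1|         : {report.bias_slope_dev:10.4f}")
print(f"mean |relative error|    : {report.mean_relative_error:10.4f}")
print(f"coefficient of variation : {report.mean_cv_pct:9.2f}%")
print(f"precision (within-group) : {report.mean_precision:10.5f}")
print(f"resolution (fold)        : {report.resolution_fold:10.4f}")
print()
print("The ratio-form bias is amplified by the 10^4 dynamic range: a few")
print("percent of efficiency error compounds over ~26 cycles at the lowest")
print("input.  The slope, CV and resolution views are scale-robust.")
print()
print("Per-gene detail (first rows):")
print(report.per_gene.head(3).to_string(index=False))
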