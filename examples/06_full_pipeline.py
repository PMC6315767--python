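"""The whole workflow in one call: filters, models, validation, cascades.

run_pipeline fits one OPLS-DA model per group pair, validates each with a
permutation test and CV-ANOVA, and runs the marker cascade only for pairs
whose model is both valid and significant — here that should single out the
comparisons involving the effect-carrying PA group.
"""

from metabomark import PipelineConfig, SyntheticConfig, generate_dataset, run_pipeline

table, truth = generate_dataset(
    SyntheticConfig(
        n_features=150,
        groups=(("HC", 11), ("PA", 11), ("PE", 11)),
        n_differential=8,
        seed=2,
    )
)

config = PipelineConfig(n_perm=199, seed=5)
bundle = run_pipeline(table, config)

print("verdict table (one row per pairwise model):")
print(bundle.verdicts.round(3).to_string(index=False))

for pair, report in bundle.markers.items():
    ids = [r.feature_id for r in report.selected]
    print(f"\nmarker cascade ran for {pair}: {len(ids)} markers -> {ids}")
print(f"\nplanted truth: {sorted(truth.feature_id)} (affected group: PA)")
print("pairs without a valid + significant model get no marker list.")
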