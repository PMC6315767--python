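"""Generate a synthetic faecal-metabolomics study with known ground truth.

Draws a feature table at the reference design size — six groups (healthy
controls plus five Crohn's-disease timepoints), ~600 features, five pooled-QC
injections — with eight differential features planted in the pre-treatment
group at the published marker fold changes.
"""

from metabomark import SyntheticConfig, generate_dataset

config = SyntheticConfig(seed=1)
table, truth = generate_dataset(config)

bio = table.biological()
print(f"samples: {bio.n_samples} biological + {table.qc().n_samples} QC pools")
print(f"features: {table.n_features}")
print(f"groups: {sorted(set(bio.groups))}")
print(f"missing fraction: {bio.values.isna().to_numpy().mean():.3f}")
print("\nplanted markers (fold change applied to the PA group):")
print(truth.to_string(index=False))

# The fold changes span 0.15x (depleted, like the ornithine isomer) to 20x
# (enriched, like docosatetraenoic acid); downstream examples try to find
# exactly these features with no knowledge of the truth table.
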