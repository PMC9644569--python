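"""Generate a complete synthetic methylation study with known truth.

Builds a purified-cell reference panel, tumor/normal training matrices
and a bulk mixture cohort that share one latent set of archetypes, then
prints their shapes and one ground-truth composition row.
"""
from tmedecon import (
    SimulationConfig,
    simulate_mixtures,
    simulate_reference_panel,
    simulate_tumor_normal,
)

cfg = SimulationConfig(seed=17)

panel, archetypes = simulate_reference_panel(cfg)
tumor, normal, differential = simulate_tumor_normal(cfg)
mixtures, truth = simulate_mixtures(cfg)

print(f"reference panel : {panel.betas.shape[0]} CpGs x {panel.betas.shape[1]} samples "
      f"({len(panel.classes)} cell classes)")
print(f"tumor training  : {tumor.shape[1]} samples; normal: {normal.shape[1]}")
print(f"truly differential CpGs: {len(differential)}")
print(f"mixture cohort  : {mixtures.shape[1]} bulk samples")
print("\nground truth of the first mixture (leaf proportions):")
row = truth.proportions.iloc[0]
print(row[row > 0.01].round(3).to_string())
print(f"row sum = {row.sum():.1f} (exact by construction)")
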